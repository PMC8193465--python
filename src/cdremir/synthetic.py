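"""Synthetic expression cohorts with planted commodore structure.

The generator emulates the ingredients the downstream pipeline is designed
to detect, without any download:

* a planted *driver* miR sharing a latent factor with a disjoint set of
  target genes (the commodore ground truth: high degree, low redundancy),
* planted *redundant hub groups* — several miRs loaded on one latent factor
  together with a single shared target set, so every member's neighbor
  pairs are covered by its group mates (redundancy coefficient -> 1),
* independent log-normal background noise for everything else,
* a toy rooted ontology DAG whose designated "true" terms annotate exactly
  the planted neighborhoods.

Expression is built on the log scale as ``s * factor + (1 - s) * noise``
(with driver strength ``s``) and exponentiated, giving FPKM-like skewed,
strictly positive values. The monotone link means the rank-based MI
estimator sees the full dependence. Subtype labels are assigned
round-robin, and each synthetic subtype carries its own planted structure,
active only in that subtype's samples.

Default dimensions (6000 genes x 1000 miRs x 100 samples per subtype) put
the 0.9999-quantile network at ~600 edges, comfortably above the planted
signal of 480 driver+trio pairs — the same edges-to-pairs regime (about
1e-4) as the breast-cancer networks this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationDB
from .io import ExpressionMatrix, SubtypeAssignment
from .semantic import DEFAULT_EDGE_WEIGHTS, OntologyDAG

DEFAULT_N_GENES = 6000
DEFAULT_N_MIRS = 1000
DEFAULT_N_SAMPLES = 100  # per subtype
DEFAULT_DRIVER_TARGETS = 120
DEFAULT_TRIO_TARGETS = 120
DEFAULT_DRIVER_STRENGTH = 0.9


def gene_id(i: int) -> str:
    return f"g{i:05d}"


def mir_id(i: int) -> str:
    return f"mir-{i:04d}"


@dataclass(frozen=True)
class PlantedStructure:
    """Ground truth planted into one synthetic subtype.

    ``commodore_targets`` maps each planted commodore miR to its target
    gene set (pairwise disjoint across commodores). Each redundant hub
    group is a (members, shared target set) pair with >= 2 members.
    ``driver_strength`` in [0, 1] is the latent-factor loading on the log
    scale; 0 means everything is independent background noise.
    """

    commodore_mirs: tuple[str, ...] = ()
    commodore_targets: Mapping[str, frozenset[str]] = field(default_factory=dict)
    redundant_hub_groups: tuple[tuple[tuple[str, ...], frozenset[str]], ...] = ()
    driver_strength: float = DEFAULT_DRIVER_STRENGTH
    noise_location: float = 2.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.driver_strength <= 1.0:
            raise ValueError(
                f"driver_strength must be in [0, 1], got {self.driver_strength}"
            )
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if set(self.commodore_mirs) != set(self.commodore_targets):
            raise ValueError("commodore_mirs and commodore_targets must agree")
        target_sets = [self.commodore_targets[m] for m in self.commodore_mirs]
        for i in range(len(target_sets)):
            for j in range(i + 1, len(target_sets)):
                if target_sets[i] & target_sets[j]:
                    raise ValueError("commodore target sets must be pairwise disjoint")
        for members, shared in self.redundant_hub_groups:
            if len(members) < 2:
                raise ValueError("redundant hub groups need >= 2 miRs")
            if not shared:
                raise ValueError("redundant hub groups need a nonempty shared target set")

    @property
    def planted_mirs(self) -> frozenset[str]:
        out = set(self.commodore_mirs)
        for members, _ in self.redundant_hub_groups:
            out |= set(members)
        return frozenset(out)

    @property
    def max_target_set_size(self) -> int:
        sizes = [len(s) for s in self.commodore_targets.values()]
        sizes += [len(s) for _, s in self.redundant_hub_groups]
        return max(sizes, default=0)


def default_planted(
    seed: int,
    driver_strength: float = DEFAULT_DRIVER_STRENGTH,
    n_driver_targets: int = DEFAULT_DRIVER_TARGETS,
    n_trio_targets: int = DEFAULT_TRIO_TARGETS,
    mir_offset: int = 0,
    gene_offset: int = 0,
) -> PlantedStructure:
    """One planted driver plus one redundant trio on disjoint gene blocks.

    Offsets shift the miR/gene id blocks so several subtypes can carry
    non-overlapping structures in the same cohort.
    """
    driver = mir_id(mir_offset + 1)
    targets = frozenset(
        gene_id(i) for i in range(gene_offset + 1, gene_offset + 1 + n_driver_targets)
    )
    trio = tuple(mir_id(mir_offset + i) for i in (2, 3, 4))
    shared = frozenset(
        gene_id(i)
        for i in range(
            gene_offset + 1 + n_driver_targets,
            gene_offset + 1 + n_driver_targets + n_trio_targets,
        )
    )
    return PlantedStructure(
        commodore_mirs=(driver,),
        commodore_targets={driver: targets},
        redundant_hub_groups=((trio, shared),),
        driver_strength=driver_strength,
        seed=seed,
    )


def noise_only(seed: int, **kwargs) -> PlantedStructure:
    """Pure background noise: no planted miR at all."""
    return PlantedStructure(driver_strength=0.0, seed=seed, **kwargs)


def _as_mapping(
    planted: PlantedStructure | Mapping[str, PlantedStructure],
) -> dict[str, PlantedStructure]:
    if isinstance(planted, PlantedStructure):
        return {"subtype1": planted}
    return dict(planted)


def generate_dataset(
    n_samples: int,
    n_genes: int,
    n_mirs: int,
    planted: PlantedStructure | Mapping[str, PlantedStructure],
) -> tuple[ExpressionMatrix, ExpressionMatrix, SubtypeAssignment, dict[str, PlantedStructure]]:
    """Generate gene and miR expression with the planted ground truth.

    ``n_samples`` counts samples per subtype; labels are assigned
    round-robin over the subtype keys. All randomness flows from the
    structures' seeds, so the same input reproduces bit-identical matrices.
    """
    structures = _as_mapping(planted)
    if n_samples < 4:
        raise ValueError(f"n_samples must be >= 4, got {n_samples}")
    if n_genes <= 0 or n_mirs <= 0:
        raise ValueError("n_genes and n_mirs must be positive")
    labels = list(structures)
    genes = [gene_id(i) for i in range(1, n_genes + 1)]
    mirs = [mir_id(i) for i in range(1, n_mirs + 1)]
    gene_set, mir_set = set(genes), set(mirs)
    for label, st in structures.items():
        if st.max_target_set_size > n_genes:
            raise ValueError(
                f"{label}: planted target set exceeds n_genes={n_genes}"
            )
        if len(st.planted_mirs) > n_mirs:
            raise ValueError(f"{label}: more planted miRs than n_mirs={n_mirs}")
        missing = (st.planted_mirs - mir_set) | (
            set().union(*st.commodore_targets.values(), *(s for _, s in st.redundant_hub_groups))
            - gene_set
            if (st.commodore_targets or st.redundant_hub_groups)
            else set()
        )
        if missing:
            raise ValueError(
                f"{label}: planted ids outside the generated id range: "
                f"{sorted(missing)[:5]}"
            )

    total = n_samples * len(labels)
    samples = [f"sample-{i:04d}" for i in range(1, total + 1)]
    subtype_of = {s: labels[i % len(labels)] for i, s in enumerate(samples)}

    rng = np.random.default_rng(
        np.random.SeedSequence([st.seed for st in structures.values()])
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    mir_index = {m: i for i, m in enumerate(mirs)}
    log_gene = rng.standard_normal((n_genes, total))
    log_mir = rng.standard_normal((n_mirs, total))

    for label in labels:
        st = structures[label]
        cols = np.array([i for i, s in enumerate(samples) if subtype_of[s] == label])
        s = st.driver_strength
        for mir in st.commodore_mirs:
            factor = rng.standard_normal(cols.size)
            rows = [mir_index[mir]]
            log_mir[rows[0], cols] = s * factor + (1 - s) * log_mir[rows[0], cols]
            for g in sorted(st.commodore_targets[mir]):
                gi = gene_index[g]
                log_gene[gi, cols] = s * factor + (1 - s) * log_gene[gi, cols]
        for members, shared in st.redundant_hub_groups:
            factor = rng.standard_normal(cols.size)
            for m in members:
                mi = mir_index[m]
                log_mir[mi, cols] = s * factor + (1 - s) * log_mir[mi, cols]
            for g in sorted(shared):
                gi = gene_index[g]
                log_gene[gi, cols] = s * factor + (1 - s) * log_gene[gi, cols]

    # per-subtype noise parameters only shift/scale the log values; the MI
    # estimator is rank-based so any single (location, scale) works per layer
    loc = next(iter(structures.values())).noise_location
    scale = next(iter(structures.values())).noise_scale
    gene_expr = ExpressionMatrix(
        layer="gene",
        data=pd.DataFrame(np.exp(loc + scale * log_gene), index=genes, columns=samples),
    )
    mir_expr = ExpressionMatrix(
        layer="miR",
        data=pd.DataFrame(np.exp(loc + scale * log_mir), index=mirs, columns=samples),
    )
    return gene_expr, mir_expr, SubtypeAssignment(labels=subtype_of), structures


ROOT_TERM = "BP:0000000"


def generate_ontology(
    n_terms: int,
    planted: PlantedStructure | Mapping[str, PlantedStructure],
    seed: int,
    universe: Sequence[str] | None = None,
) -> tuple[OntologyDAG, AnnotationDB]:
    """Toy rooted ontology whose "true" terms annotate planted neighborhoods.

    The DAG has a single root; every other term attaches to a previously
    created term (acyclic by construction) with an is_a or part_of edge.
    One true term per planted commodore annotates exactly that commodore's
    target set; the remaining terms annotate random gene sets drawn from
    ``universe`` (default: the genes appearing in the planted structures).
    """
    if n_terms < 2:
        raise ValueError(f"n_terms must be >= 2, got {n_terms}")
    structures = _as_mapping(planted)
    rng = np.random.default_rng(seed)

    true_terms: list[tuple[str, str, frozenset[str]]] = []  # (label, mir, targets)
    for label, st in structures.items():
        for mir in st.commodore_mirs:
            true_terms.append((label, mir, st.commodore_targets[mir]))
    if n_terms < 1 + len(true_terms):
        raise ValueError(
            f"n_terms={n_terms} cannot hold the root plus "
            f"{len(true_terms)} true terms"
        )
    if universe is None:
        pool: set[str] = set()
        for st in structures.values():
            for tset in st.commodore_targets.values():
                pool |= tset
            for _, shared in st.redundant_hub_groups:
                pool |= shared
        universe = sorted(pool)
    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe for annotations")

    parents: dict[str, tuple[tuple[str, str], ...]] = {ROOT_TERM: ()}
    names: dict[str, str] = {ROOT_TERM: "biological_process"}
    annotations: dict[str, frozenset[str]] = {}
    created = [ROOT_TERM]

    def _attach(term: str) -> None:
        parent = created[int(rng.integers(len(created)))]
        etype = "is_a" if rng.random() < 0.8 else "part_of"
        parents[term] = ((parent, etype),)
        created.append(term)

    idx = 1
    for label, mir, targets in true_terms:
        term = f"BP:{idx:07d}"
        idx += 1
        _attach(term)
        names[term] = f"planted neighborhood of {mir} ({label})"
        annotations[term] = frozenset(targets)
    while idx < n_terms:
        term = f"BP:{idx:07d}"
        idx += 1
        _attach(term)
        names[term] = f"synthetic process {term[3:]}"
        max_size = min(200, len(universe))
        min_size = min(5, max_size)
        size = int(rng.integers(min_size, max_size + 1))
        picks = rng.choice(len(universe), size=size, replace=False)
        annotations[term] = frozenset(universe[i] for i in picks)
    # the root annotates everything ever annotated (a catch-all ancestor)
    annotations[ROOT_TERM] = frozenset().union(*annotations.values())

    dag = OntologyDAG(parents=parents, weights=dict(DEFAULT_EDGE_WEIGHTS))
    db = AnnotationDB(terms=annotations, names=names)
    return dag, db


def true_term_ids(
    db: AnnotationDB, structures: Mapping[str, PlantedStructure]
) -> dict[tuple[str, str], str]:
    """Map (subtype label, commodore miR) -> its true annotating term."""
    by_targets = {genes: t for t, genes in db.terms.items() if t != ROOT_TERM}
    out = {}
    for label, st in structures.items():
        for mir in st.commodore_mirs:
            key = frozenset(st.commodore_targets[mir])
            if key in by_targets:
                out[(label, mir)] = by_targets[key]
    return out
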