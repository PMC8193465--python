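"""Wang semantic similarity over an ontology DAG and term aggregation.

The Wang measure scores two ontology terms by the edge-weighted
contributions of their shared ancestors. For a term A, every ancestor t
receives an S-value

    S_A(A) = 1,      S_A(t) = max_{t' child of t on a path from A} w_e(t'->t) * S_A(t'),

where w_e is a per-edge-type contribution factor (is_a: 0.8, part_of: 0.6
by convention). The similarity is

    sim(A, B) = sum_{t in T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)),

with SV(X) = sum_t S_X(t). Enriched terms are then clustered (average
linkage on 1 - sim) into up to ten functionally coherent groups, each
represented by its member with the lowest adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}
DEFAULT_N_GROUPS = 10


@dataclass(frozen=True)
class OntologyDAG:
    """Rooted DAG of terms with typed child->parent edges.

    ``parents`` maps each term to its (parent, edge_type) pairs; roots have
    an empty tuple. Edge contribution weights must lie strictly in (0, 1).
    """

    parents: Mapping[str, tuple[tuple[str, str], ...]]
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for etype, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"edge weight for {etype!r} must be in (0,1), got {w}")
        for child, plist in self.parents.items():
            for parent, etype in plist:
                if parent not in self.parents:
                    raise ValueError(f"parent {parent!r} of {child!r} is not a term")
                if etype not in self.weights:
                    raise ValueError(f"unknown edge type {etype!r}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")

    @property
    def terms(self) -> list[str]:
        return list(self.parents)

    @property
    def roots(self) -> list[str]:
        return [t for t, p in self.parents.items() if not p]

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, plist in self.parents.items():
            for parent, etype in plist:
                g.add_edge(child, parent, edge_type=etype)
        return g


def read_ontology(
    path: str | Path, weights: Mapping[str, float] | None = None
) -> OntologyDAG:
    """3-column TSV: child_id, parent_id, edge_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 3:
        raise ValueError(f"ontology table must have 3 columns, got {df.shape[1]}")
    child_col, parent_col, type_col = df.columns
    parents: dict[str, list[tuple[str, str]]] = {}
    for c, p, t in zip(df[child_col], df[parent_col], df[type_col]):
        parents.setdefault(c, []).append((p, t))
        parents.setdefault(p, [])
    return OntologyDAG(
        parents={t: tuple(pl) for t, pl in parents.items()},
        weights=dict(weights or DEFAULT_EDGE_WEIGHTS),
    )


def write_ontology(dag: OntologyDAG, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child_id\tparent_id\tedge_type\n")
        for child in sorted(dag.parents):
            for parent, etype in dag.parents[child]:
                fh.write(f"{child}\t{parent}\t{etype}\n")


def svalues(term: str, dag: OntologyDAG) -> dict[str, float]:
    """S-value of every ancestor of ``term`` (term itself included, S=1).

    Computed by dynamic programming in topological order over the ancestor
    closure: S(t) is the maximum over in-closure children t' of
    w(t'->t) * S(t').
    """
    if term not in dag:
        raise KeyError(f"term not in ontology: {term!r}")
    # ancestor closure by upward DFS
    closure = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for parent, _ in dag.parents[t]:
            if parent not in closure:
                closure.add(parent)
                stack.append(parent)
    sub = nx.DiGraph()
    sub.add_nodes_from(closure)
    for child in closure:
        for parent, etype in dag.parents[child]:
            if parent in closure:
                sub.add_edge(child, parent, w=dag.weights[etype])
    s: dict[str, float] = {term: 1.0}
    for t in nx.topological_sort(sub):  # children precede parents
        if t == term:
            continue
        s[t] = max(
            (sub.edges[child, t]["w"] * s[child] for child in sub.predecessors(t)),
            default=0.0,
        )
    return s


def wang_similarity(a: str, b: str, dag: OntologyDAG) -> float:
    """Wang similarity in [0, 1]; symmetric; sim(A, A) = 1.

    Terms in disconnected components share no ancestor and score 0.
    """
    if a == b:
        if a not in dag:
            raise KeyError(f"term not in ontology: {a!r}")
        return 1.0
    sa = svalues(a, dag)
    sb = svalues(b, dag)
    shared = sa.keys() & sb.keys()
    denom = sum(sa.values()) + sum(sb.values())
    if not shared or denom == 0.0:
        return 0.0
    return min(1.0, sum(sa[t] + sb[t] for t in shared) / denom)


def pairwise_similarity(terms: Sequence[str], dag: OntologyDAG) -> pd.DataFrame:
    """Symmetric unit-diagonal Wang similarity matrix for ``terms``."""
    terms = list(terms)
    cache = {t: svalues(t, dag) for t in terms}
    sv = {t: sum(cache[t].values()) for t in terms}
    n = len(terms)
    mat = np.ones((n, n))
    for i in range(n):
        sa = cache[terms[i]]
        for j in range(i + 1, n):
            sb = cache[terms[j]]
            shared = sa.keys() & sb.keys()
            denom = sv[terms[i]] + sv[terms[j]]
            sim = (
                min(1.0, sum(sa[t] + sb[t] for t in shared) / denom)
                if shared and denom
                else 0.0
            )
            mat[i, j] = mat[j, i] = sim
    return pd.DataFrame(mat, index=terms, columns=terms)


@dataclass(frozen=True)
class FunctionGroup:
    """A cluster of enriched terms with its representative (lowest adj. p)."""

    group_id: int
    members: tuple[str, ...]
    representative: str
    representative_p_adjusted: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a group member")


def cluster_terms(
    terms: Sequence[str],
    sim_matrix: pd.DataFrame | np.ndarray,
    n_groups: int = DEFAULT_N_GROUPS,
) -> list[list[str]]:
    """Average-linkage clustering on distance 1 - sim, cut into groups.

    The tree is cut into ``min(n_groups, len(terms))`` clusters; with fewer
    terms than requested groups every term is its own group. Deterministic
    given the input order (scipy's linkage has a fixed merge tie-break).
    """
    terms = list(terms)
    sim = (
        sim_matrix.loc[terms, terms].to_numpy()
        if isinstance(sim_matrix, pd.DataFrame)
        else np.asarray(sim_matrix, dtype=float)
    )
    if sim.shape != (len(terms), len(terms)):
        raise ValueError("similarity matrix shape does not match terms")
    if not np.allclose(sim, sim.T) or not np.allclose(np.diag(sim), 1.0):
        raise ValueError("similarity matrix must be symmetric with unit diagonal")
    k = min(n_groups, len(terms))
    if len(terms) == 1:
        return [[terms[0]]]
    if k == len(terms):
        return [[t] for t in terms]
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for t, lab in zip(terms, labels):
        groups.setdefault(int(lab), []).append(t)
    return [groups[lab] for lab in sorted(groups)]


def select_representative(members: Iterable[str], enrichment: pd.DataFrame) -> str:
    """Member with the lowest adjusted p; ties by raw p, then term id."""
    table = enrichment.set_index("term_id")
    keyed = []
    for t in members:
        if t not in table.index:
            raise KeyError(f"no enrichment result for term {t!r}")
        row = table.loc[t]
        keyed.append((float(row["p_adjusted"]), float(row["p"]), t))
    return min(keyed)[2]


def aggregate_function_groups(
    enrichment: pd.DataFrame,
    dag: OntologyDAG,
    n_groups: int = DEFAULT_N_GROUPS,
) -> list[FunctionGroup]:
    """Cluster the significant terms of one neighborhood into groups.

    Groups are numbered 1.. in ascending order of their representative's
    adjusted p-value (most significant function first).
    """
    sig = enrichment[enrichment["significant"]]
    terms = list(sig["term_id"])
    if not terms:
        return []
    sim = pairwise_similarity(terms, dag)
    raw_groups = cluster_terms(terms, sim, n_groups=n_groups)
    table = enrichment.set_index("term_id")
    annotated = []
    for members in raw_groups:
        rep = select_representative(members, enrichment)
        annotated.append((float(table.loc[rep, "p_adjusted"]), rep, members))
    annotated.sort(key=lambda x: (x[0], x[1]))
    return [
        FunctionGroup(
            group_id=i + 1,
            members=tuple(sorted(members)),
            representative=rep,
            representative_p_adjusted=p,
        )
        for i, (p, rep, members) in enumerate(annotated)
    ]


def groups_table(groups: list[FunctionGroup], db_names: Mapping[str, str]) -> pd.DataFrame:
    rows = [
        {
            "group": g.group_id,
            "representative_term": g.representative,
            "representative_name": db_names.get(g.representative, g.representative),
            "n_terms": len(g.members),
            "members": ";".join(g.members),
        }
        for g in groups
    ]
    return pd.DataFrame(
        rows,
        columns=["group", "representative_term", "representative_name", "n_terms", "members"],
    )


def write_groups(
    groups: list[FunctionGroup], db_names: Mapping[str, str], path: str | Path
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    groups_table(groups, db_names).to_csv(path, sep="\t", index=False)
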