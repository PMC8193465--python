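"""Per-subtype workflow orchestration: data -> network -> commodores ->
enrichment -> function groups, with a manifest for full reproducibility.

Defaults are the published analysis parameters: MI upper quantile 0.9999,
commodore gates k >= 100 and rc <= 0.5, adjusted-p significance 1e-3, ten
function groups. Every number in the report bundle is recomputable from the
manifest (parameters + seed + inputs); subtypes are processed independently
and identically.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .commodore import (
    DEFAULT_K_MIN,
    DEFAULT_RC_MAX,
    CommodoreRecord,
    classify_commodores,
    neighborhood_jaccard,
    write_commodore_table,
    write_neighborhoods,
)
from .enrichment import (
    DEFAULT_ALPHA,
    AnnotationDB,
    enrich_neighborhood,
    read_annotations,
    write_enrichment,
)
from .io import (
    ExpressionMatrix,
    SubtypeAssignment,
    common_samples,
    drop_zero_variance,
    read_expression_table,
    read_subtype_table,
    split_by_subtype,
)
from .metrics import network_summary, node_metrics, write_metrics_table
from .network import (
    DEFAULT_QUANTILE,
    score_all_pairs,
    threshold_by_quantile,
    write_edge_list,
    write_graphml,
)
from .semantic import (
    DEFAULT_N_GROUPS,
    OntologyDAG,
    aggregate_function_groups,
    groups_table,
    read_ontology,
)
from .synthetic import (
    DEFAULT_N_GENES,
    DEFAULT_N_MIRS,
    DEFAULT_N_SAMPLES,
    default_planted,
    generate_dataset,
    generate_ontology,
    noise_only,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort used when no input files are given.

    ``n_subtypes`` synthetic phenotypes are simulated; all but the last
    carry a planted driver and a redundant trio (the last is pure noise,
    mirroring a phenotype without commodores).
    """

    n_samples: int = DEFAULT_N_SAMPLES  # per subtype
    n_genes: int = DEFAULT_N_GENES
    n_mirs: int = DEFAULT_N_MIRS
    n_subtypes: int = 4
    n_terms: int = 150
    driver_strength: float = 0.9
    n_driver_targets: int = 120
    n_trio_targets: int = 120


@dataclass
class PipelineConfig:
    """Inputs (file paths or synthetic parameters) plus analysis knobs."""

    outdir: str = "cdremir-run"
    gene_table: str | None = None
    mir_table: str | None = None
    subtype_table: str | None = None
    ontology_table: str | None = None
    annotation_table: str | None = None
    names_table: str | None = None
    quantile: float = DEFAULT_QUANTILE
    n_bins: int | None = None
    k_min: int = DEFAULT_K_MIN
    rc_max: float = DEFAULT_RC_MAX
    alpha: float = DEFAULT_ALPHA
    n_groups: int = DEFAULT_N_GROUPS
    seed: int = 0
    synthetic: SyntheticConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def manifest(self) -> dict:
        out = asdict(self)
        out.pop("outdir", None)  # implied by the bundle's own location
        out["package_version"] = __version__
        return out


def build_synthetic_cohort(cfg: SyntheticConfig, seed: int):
    """Cohort of ``n_subtypes`` phenotypes, planted structure in all but one."""
    structures = {}
    for k in range(cfg.n_subtypes):
        label = f"subtype{k + 1}"
        sub_seed = seed * 1000 + k
        if k < cfg.n_subtypes - 1:
            structures[label] = default_planted(
                seed=sub_seed,
                driver_strength=cfg.driver_strength,
                n_driver_targets=cfg.n_driver_targets,
                n_trio_targets=cfg.n_trio_targets,
                mir_offset=k * 10,
                gene_offset=k * (cfg.n_driver_targets + cfg.n_trio_targets + 10),
            )
        else:
            structures[label] = noise_only(seed=sub_seed)
    gene, mir, assign, structures = generate_dataset(
        cfg.n_samples, cfg.n_genes, cfg.n_mirs, structures
    )
    dag, db = generate_ontology(
        cfg.n_terms, structures, seed=seed, universe=gene.transcript_ids
    )
    return gene, mir, assign, structures, dag, db


@dataclass
class SubtypeReport:
    subtype: str
    summary: pd.DataFrame
    commodores: list[CommodoreRecord]
    enrichments: dict[str, pd.DataFrame]
    groups: dict[str, pd.DataFrame]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s: start", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(name, exc) from exc
        logger.info("stage %s: done", name)
        return out

    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, SubtypeReport]:
    """Run the full per-subtype workflow and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def load_data():
        if config.synthetic is not None:
            return build_synthetic_cohort(config.synthetic, config.seed)
        needed = [config.gene_table, config.mir_table, config.subtype_table,
                  config.ontology_table, config.annotation_table]
        if any(p is None for p in needed):
            raise ValueError(
                "either synthetic parameters or all five input tables are required"
            )
        gene = read_expression_table(config.gene_table, layer="gene")
        mir = read_expression_table(config.mir_table, layer="miR")
        assign = read_subtype_table(config.subtype_table)
        dag = read_ontology(config.ontology_table)
        db = read_annotations(config.annotation_table, config.names_table)
        return gene, mir, assign, None, dag, db

    gene, mir, assign, _structures, dag, db = _stage("data")(load_data)

    reports: dict[str, SubtypeReport] = {}
    all_records: list[CommodoreRecord] = []
    for subtype in assign.subtypes:
        subdir = outdir / subtype
        report = _stage(f"subtype:{subtype}")(
            _run_subtype, subtype, gene, mir, assign, dag, db, config, subdir
        )
        reports[subtype] = report
        all_records.extend(report.commodores)

    if all_records:
        jac = _stage("jaccard")(neighborhood_jaccard, all_records)
        jac.round(10).to_csv(outdir / "neighborhood_jaccard.tsv", sep="\t")

    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.manifest(), fh, sort_keys=True)
    return reports


def _run_subtype(
    subtype: str,
    gene: ExpressionMatrix,
    mir: ExpressionMatrix,
    assign: SubtypeAssignment,
    dag: OntologyDAG,
    db: AnnotationDB,
    config: PipelineConfig,
    subdir: Path,
) -> SubtypeReport:
    subdir.mkdir(parents=True, exist_ok=True)
    gene_s = split_by_subtype(gene, assign, subtype)
    mir_s = split_by_subtype(mir, assign, subtype)
    mir_s, gene_s = common_samples(mir_s, gene_s)
    gene_s, _ = drop_zero_variance(gene_s)
    mir_s, _ = drop_zero_variance(mir_s)

    scores = score_all_pairs(mir_s, gene_s, n_bins=config.n_bins)
    net = threshold_by_quantile(scores, q=config.quantile)
    write_edge_list(net, subdir / "edges.tsv")
    write_graphml(net, subdir / "network.graphml")

    metrics = node_metrics(net)
    write_metrics_table(metrics, subdir / "node_metrics.tsv")
    summary = network_summary(net).to_frame()
    summary.to_csv(subdir / "summary.tsv", sep="\t", index=False)

    records = classify_commodores(
        net, subtype=subtype, k_min=config.k_min, rc_max=config.rc_max,
        metrics=metrics,
    )
    write_commodore_table(records, subdir / "commodores.tsv")
    write_neighborhoods(records, subdir / "neighborhoods")

    universe = sorted(set(gene_s.transcript_ids) & db.annotated_genes)
    enrichments: dict[str, pd.DataFrame] = {}
    groups: dict[str, pd.DataFrame] = {}
    for rec in records:
        result = enrich_neighborhood(
            rec.neighborhood & set(universe), universe, db, alpha=config.alpha
        )
        enrichments[rec.mir_id] = result
        write_enrichment(result, subdir / f"enrichment_{rec.mir_id}.tsv")
        fgroups = aggregate_function_groups(result, dag, n_groups=config.n_groups)
        gtab = groups_table(fgroups, db.names)
        groups[rec.mir_id] = gtab
        gtab.to_csv(subdir / f"function_groups_{rec.mir_id}.tsv", sep="\t", index=False)

    return SubtypeReport(
        subtype=subtype,
        summary=summary,
        commodores=records,
        enrichments=enrichments,
        groups=groups,
    )


def literature_queries(reports: dict[str, SubtypeReport]) -> list[str]:
    """Query strings of the form "mir + representative function".

    A stub for the downstream literature-validation step: the strings are
    returned for manual use, no external service is contacted.
    """
    queries = []
    for subtype, report in sorted(reports.items()):
        for mir, gtab in sorted(report.groups.items()):
            for _, row in gtab.iterrows():
                queries.append(f"{mir} + {row['representative_name']}")
    return queries
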