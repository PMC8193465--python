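"""Commodore-miR classification and neighborhood comparison.

A commodore miR is a miR node that is simultaneously highly connected
(degree k >= 100 by default) and non-redundant (redundancy coefficient
rc <= 0.5): removing it would disconnect many gene pairs, so it is a
candidate single-handed controller of the genes it co-expresses with.
Both comparisons are inclusive. A miR may be a commodore in more than one
phenotype, so records are keyed by (miR, subtype).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import degree, node_metrics, redundancy_coefficient
from .network import BipartiteNetwork

DEFAULT_K_MIN = 100
DEFAULT_RC_MAX = 0.5


@dataclass(frozen=True)
class CommodoreRecord:
    mir_id: str
    subtype: str
    degree: int
    redundancy: float
    neighborhood: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.neighborhood) != self.degree:
            raise ValueError("neighborhood size must equal degree")

    @property
    def key(self) -> str:
        return f"{self.subtype}:{self.mir_id}" if self.subtype else self.mir_id


def neighborhood(net: BipartiteNetwork, mir_id: str) -> frozenset[str]:
    """Gene nodes adjacent to the miR (empty for isolated miRs)."""
    if mir_id not in set(net.mir_nodes):
        raise KeyError(f"unknown miR: {mir_id!r}")
    return net.neighbors(mir_id)


def classify_commodores(
    net: BipartiteNetwork,
    subtype: str = "",
    k_min: int = DEFAULT_K_MIN,
    rc_max: float = DEFAULT_RC_MAX,
    metrics: pd.DataFrame | None = None,
) -> list[CommodoreRecord]:
    """miR-layer nodes with degree >= k_min and defined rc <= rc_max.

    Gene-layer nodes are never classified. An empty result is a valid
    outcome (some phenotypes simply have no commodore). A precomputed
    ``node_metrics`` table may be passed to avoid recomputation.
    """
    records = []
    if metrics is not None:
        mir_rows = metrics[metrics["layer"] == "miR"]
        for _, row in mir_rows.iterrows():
            k, rc = int(row["degree"]), row["redundancy"]
            if k >= k_min and not np.isnan(rc) and rc <= rc_max:
                records.append(
                    CommodoreRecord(
                        mir_id=row["node_id"],
                        subtype=subtype,
                        degree=k,
                        redundancy=float(rc),
                        neighborhood=neighborhood(net, row["node_id"]),
                    )
                )
        return records
    for mir in net.mir_nodes:
        k = degree(net, mir)
        if k < k_min:
            continue
        rc = redundancy_coefficient(net, mir)
        if rc is None or rc > rc_max:
            continue
        records.append(
            CommodoreRecord(
                mir_id=mir,
                subtype=subtype,
                degree=k,
                redundancy=rc,
                neighborhood=neighborhood(net, mir),
            )
        )
    return records


def neighborhood_jaccard(records: list[CommodoreRecord]) -> pd.DataFrame:
    """Pairwise Jaccard similarity |A∩B| / |A∪B| of commodore neighborhoods.

    Symmetric with unit diagonal; rows/columns labelled ``subtype:miR``.
    """
    if not records:
        raise ValueError("need at least one commodore record")
    keys = [r.key for r in records]
    n = len(records)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].neighborhood, records[j].neighborhood
            union = len(a | b)
            mat[i, j] = mat[j, i] = (len(a & b) / union) if union else 1.0
    return pd.DataFrame(mat, index=keys, columns=keys)


def commodore_table(records: list[CommodoreRecord]) -> pd.DataFrame:
    rows = [
        {
            "subtype": r.subtype,
            "mir_id": r.mir_id,
            "degree": r.degree,
            "redundancy": r.redundancy,
        }
        for r in sorted(records, key=lambda r: (r.subtype, r.mir_id))
    ]
    return pd.DataFrame(rows, columns=["subtype", "mir_id", "degree", "redundancy"])


def write_commodore_table(records: list[CommodoreRecord], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    commodore_table(records).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_neighborhoods(records: list[CommodoreRecord], outdir: str | Path) -> None:
    """One sorted gene list per record (per-commodore neighborhood export)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in records:
        name = r.key.replace(":", "_").replace("/", "_")
        with open(outdir / f"{name}.txt", "w", encoding="utf-8") as fh:
            for g in sorted(r.neighborhood):
                fh.write(g + "\n")
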