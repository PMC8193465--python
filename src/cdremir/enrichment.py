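"""Hypergeometric over-representation of gene neighborhoods.

Each commodore neighborhood (>= 100 genes by construction) is tested
against every term of an annotation database with the one-sided
hypergeometric (Fisher) tail, and p-values are adjusted across the terms
tested for that neighborhood with Benjamini-Hochberg. Terms at adjusted
p <= 1e-3 (default) are flagged significant.

Universe convention: annotated genes among those supplied by the caller
(typically the genes expressed in the subtype after the zero-variance
filter). Terms with no gene in the universe are skipped, not assigned
p = 1, and excluded from the adjustment family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-3


@dataclass(frozen=True)
class AnnotationDB:
    """term id -> annotated gene set, with optional human-readable names."""

    terms: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.terms.items() if not genes]
        if empty:
            raise ValueError(f"terms with no annotated gene: {sorted(empty)[:5]}")

    def name_of(self, term_id: str) -> str:
        return self.names.get(term_id, term_id)

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def read_annotations(
    path: str | Path, names_path: str | Path | None = None
) -> AnnotationDB:
    """2-column TSV (term_id, gene_id); optional names TSV (term_id, name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"annotation table must have 2 columns, got {df.shape[1]}")
    term_col, gene_col = df.columns
    terms: dict[str, set[str]] = {}
    for t, g in zip(df[term_col], df[gene_col]):
        terms.setdefault(t, set()).add(g)
    names: dict[str, str] = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", dtype=str)
        names = dict(zip(nd.iloc[:, 0], nd.iloc[:, 1]))
    return AnnotationDB(
        terms={t: frozenset(g) for t, g in terms.items()}, names=names
    )


def write_annotations(
    db: AnnotationDB, path: str | Path, names_path: str | Path | None = None
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tgene_id\n")
        for t in sorted(db.terms):
            for g in sorted(db.terms[t]):
                fh.write(f"{t}\t{g}\n")
    if names_path is not None:
        with open(names_path, "w", encoding="utf-8") as fh:
            fh.write("term_id\tname\n")
            for t in sorted(db.terms):
                fh.write(f"{t}\t{db.name_of(t)}\n")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), in log space.

    N: universe size, K: annotated genes in universe, n: query size,
    k: observed overlap. k = 0 gives exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:
        return 0.0
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def enrich_neighborhood(
    query: Iterable[str],
    universe: Iterable[str],
    db: AnnotationDB,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Over-representation of ``query`` against every term of ``db``.

    Returns one row per term with >= 1 universe gene: term_id, name,
    universe size N, term size K, query size n, overlap k, p, p_adjusted,
    significant (p_adjusted <= alpha). Query genes outside the universe are
    dropped with a warning; term sizes are computed after intersecting
    annotations with the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s%s",
            len(outside),
            ", ".join(sorted(outside)[:5]),
            "..." if len(outside) > 5 else "",
        )
    query &= universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(db.terms):
        annotated = db.terms[term_id] & universe
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & query)
        rows.append(
            {
                "term_id": term_id,
                "name": db.name_of(term_id),
                "universe_size": N,
                "term_size": K,
                "query_size": n,
                "overlap": k,
                "p": hypergeom_tail(N, K, n, k),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "universe_size", "term_size",
            "query_size", "overlap", "p",
        ],
    )
    if result.empty:
        return result.assign(p_adjusted=[], significant=[])
    result["p_adjusted"] = bh_adjust(result["p"])
    result["significant"] = result["p_adjusted"] <= alpha
    return result


def write_enrichment(result: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, sep="\t", index=False, float_format="%.10g")
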