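"""Mutual-information scoring of miR-gene pairs and quantile thresholding.

Every miR-gene pair is scored with a plug-in (histogram) mutual-information
estimate on equal-frequency bins, filling an incidence matrix. Pairs whose
MI reaches the global upper-quantile threshold (default 0.9999, i.e. the top
10^-4 of all possible links) become the edges of a bipartite co-expression
network. Ties at the threshold are all retained — no tie-breaking — so a
network may carry slightly more edges than the nominal count.

The estimator is deliberately rank-based: equal-frequency binning makes the
MI score invariant under strictly monotone transforms of either profile, so
FPKM versus log-FPKM is immaterial.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.9999


def default_bin_count(n_samples: int) -> int:
    """Default number of equal-frequency bins: floor(sqrt(n)), at least 2."""
    return max(2, int(math.floor(math.sqrt(n_samples))))


def discretize_equal_frequency(x, n_bins: int) -> np.ndarray:
    """Assign equal-frequency bin labels in ``0..n_bins-1``.

    Bin sizes differ by at most one when the values are distinct. Tied
    values always share a single bin: every member of a tie group receives
    the bin of the group's smallest rank (stable, rank-based), so the
    labelling is invariant under strictly monotone transforms of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    n = x.size
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds vector length {n}")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    bins = (ranks * n_bins) // n
    # collapse ties onto the bin of the first (lowest-rank) member
    sorted_x = x[order]
    sorted_bins = bins[order]
    group_start = np.concatenate(([True], sorted_x[1:] != sorted_x[:-1]))
    group_id = np.cumsum(group_start) - 1
    tied_bins = sorted_bins[group_start][group_id]
    out = np.empty(n, dtype=np.int64)
    out[order] = tied_bins
    return out


def _joint_counts(lx: np.ndarray, ly: np.ndarray, n_bins: int) -> np.ndarray:
    flat = lx * n_bins + ly
    return np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in MI (bits) between two profiles on equal-frequency bins.

    MI = sum_ij p_ij log2(p_ij / (p_i. p_.j)) over the joint histogram of
    the bin labels. Nonnegative and symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional with equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    for name, v in (("x", x), ("y", y)):
        if np.all(v == v[0]):
            raise ValueError(f"{name} is constant; MI is undefined")
    b = default_bin_count(n) if n_bins is None else int(n_bins)
    lx = discretize_equal_frequency(x, b)
    ly = discretize_equal_frequency(y, b)
    counts = _joint_counts(lx, ly, b)
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    mi = float(np.nansum(terms))
    return max(mi, 0.0)


@dataclass(frozen=True)
class ScoredPairs:
    """MI score for every retained miR-gene pair (a dense incidence matrix)."""

    mir_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)  # shape (n_mirs, n_genes), bits
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.mir_ids), len(self.gene_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("MI scores must be nonnegative")

    @property
    def total_pair_count(self) -> int:
        return self.scores.size

    def entries(self) -> Iterator[tuple[str, str, float]]:
        for i, m in enumerate(self.mir_ids):
            for j, g in enumerate(self.gene_ids):
                yield m, g, float(self.scores[i, j])


def score_all_pairs(
    mir: ExpressionMatrix,
    gene: ExpressionMatrix,
    n_bins: int | None = None,
) -> ScoredPairs:
    """Score every miR-gene pair by plug-in MI on equal-frequency bins.

    Both matrices must carry the same samples in the same order. Constant
    transcripts (normally removed upstream) are dropped here defensively.

    The dense loop factorizes MI as
    ``(1/n) sum c log2 c  -  (1/n) sum a log2 a  -  (1/n) sum b log2 b  +  log2 n``
    so the per-transcript marginal terms are computed once and only the
    joint-histogram term is evaluated per pair.
    """
    if mir.sample_ids != gene.sample_ids:
        raise ValueError("miR and gene matrices must share identically ordered samples")
    n = mir.n_samples
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    b = default_bin_count(n) if n_bins is None else int(n_bins)

    def _labels(expr: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
        vals = expr.values
        keep_ids, rows = [], []
        for tid, row in zip(expr.transcript_ids, vals):
            if np.all(row == row[0]):
                logger.info("dropping constant %s transcript %s", expr.layer, tid)
                continue
            keep_ids.append(tid)
            rows.append(discretize_equal_frequency(row, b))
        return keep_ids, np.asarray(rows, dtype=np.int32)

    mir_ids, lm = _labels(mir)
    gene_ids, lg = _labels(gene)
    if not mir_ids or not gene_ids:
        raise ValueError("no non-constant transcripts to score")

    n_mirs, n_genes = len(mir_ids), len(gene_ids)
    # c*log2(c) lookup for integer counts 0..n
    table = np.zeros(n + 1)
    c = np.arange(1, n + 1)
    table[1:] = c * np.log2(c)

    def _marginal_term(labels: np.ndarray) -> np.ndarray:
        out = np.empty(labels.shape[0])
        for i, row in enumerate(labels):
            out[i] = table[np.bincount(row, minlength=b)].sum()
        return out / n

    hm = _marginal_term(lm)
    hg = _marginal_term(lg)

    offsets = (np.arange(n_genes, dtype=np.int64) * (b * b))[:, None]
    scores = np.empty((n_mirs, n_genes))
    log2n = math.log2(n)
    for i in range(n_mirs):
        code = lg + (b * lm[i])[None, :] + offsets
        cnt = np.bincount(code.ravel(), minlength=n_genes * b * b)
        joint = table[cnt].reshape(n_genes, b * b).sum(axis=1) / n
        scores[i] = joint - hm[i] - hg + log2n
    np.maximum(scores, 0.0, out=scores)
    return ScoredPairs(
        mir_ids=tuple(mir_ids), gene_ids=tuple(gene_ids), scores=scores, n_bins=b
    )


@dataclass(frozen=True)
class BipartiteNetwork:
    """miR-gene co-expression network: cross-layer MI-weighted edges only.

    Nodes with no retained edge stay in the node sets with degree zero;
    connected (k > 0) nodes are counted separately by the summary step.
    """

    mir_nodes: tuple[str, ...]
    gene_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    threshold_value: float
    quantile: float

    def __post_init__(self) -> None:
        mirs, genes = set(self.mir_nodes), set(self.gene_nodes)
        if mirs & genes:
            raise ValueError("miR and gene node sets overlap")
        for m, g, w in self.edges:
            if m not in mirs or g not in genes:
                raise ValueError(f"edge ({m!r}, {g!r}) is not a miR->gene edge")
            if w < self.threshold_value:
                raise ValueError("edge weight below threshold")

    @cached_property
    def _adjacency(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.mir_nodes}
        adj.update({n: set() for n in self.gene_nodes})
        for m, g, _ in self.edges:
            adj[m].add(g)
            adj[g].add(m)
        return {k: frozenset(v) for k, v in adj.items()}

    def neighbors(self, node_id: str) -> frozenset[str]:
        try:
            return self._adjacency[node_id]
        except KeyError:
            raise KeyError(f"unknown node: {node_id!r}") from None

    def layer_of(self, node_id: str) -> str:
        if node_id in set(self.mir_nodes):
            return "miR"
        if node_id in set(self.gene_nodes):
            return "gene"
        raise KeyError(f"unknown node: {node_id!r}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.mir_nodes, layer="miR")
        g.add_nodes_from(self.gene_nodes, layer="gene")
        g.add_weighted_edges_from(self.edges, weight="mi")
        return g


def threshold_by_quantile(
    scores: ScoredPairs, q: float = DEFAULT_QUANTILE
) -> BipartiteNetwork:
    """Keep the upper-``q`` quantile of all possible links as network edges.

    With N total pairs, the threshold is the m-th largest score for
    m = ceil((1-q) N); every pair scoring >= that value becomes an edge, so
    ties at the threshold are all retained and the edge count may exceed m.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    total = scores.total_pair_count
    if total == 0:
        raise ValueError("empty score set")
    # small epsilon so 1-q rounding (e.g. 1-0.95 = 0.050000...044) cannot
    # inflate the ceil by one
    m = math.ceil((1.0 - q) * total - 1e-9)
    m = max(m, 1)
    flat = scores.scores.ravel()
    threshold = float(np.partition(flat, total - m)[total - m])
    if flat.min() == flat.max():
        warnings.warn(
            "all MI scores are equal; every pair becomes an edge", stacklevel=2
        )
    mask = scores.scores >= threshold
    ii, jj = np.nonzero(mask)
    edges = tuple(
        (scores.mir_ids[i], scores.gene_ids[j], float(scores.scores[i, j]))
        for i, j in zip(ii, jj)
    )
    logger.info(
        "quantile %.6f over %d pairs: nominal %d edges, kept %d (ties at threshold)",
        q, total, m, len(edges),
    )
    return BipartiteNetwork(
        mir_nodes=scores.mir_ids,
        gene_nodes=scores.gene_ids,
        edges=edges,
        threshold_value=threshold,
        quantile=q,
    )


def write_edge_list(net: BipartiteNetwork, path: str | Path) -> None:
    """Edge list TSV: mir_id, gene_id, mi (stable order, fixed precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mir_id\tgene_id\tmi\n")
        for m, g, w in sorted(net.edges):
            fh.write(f"{m}\t{g}\t{w:.10g}\n")


def write_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    """GraphML export with a ``layer`` node attribute."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.to_networkx(), path)


def read_edge_list(
    path: str | Path,
    mir_nodes: tuple[str, ...] | None = None,
    gene_nodes: tuple[str, ...] | None = None,
    quantile: float = DEFAULT_QUANTILE,
) -> BipartiteNetwork:
    """Rebuild a network from an edge-list TSV written by ``write_edge_list``.

    Node sets default to the nodes appearing in edges (degree-0 nodes are
    only preserved if explicit node sets are given).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"mir_id": str, "gene_id": str})
    edges = tuple(
        (m, g, float(w)) for m, g, w in zip(df["mir_id"], df["gene_id"], df["mi"])
    )
    mirs = mir_nodes if mir_nodes is not None else tuple(dict.fromkeys(df["mir_id"]))
    genes = gene_nodes if gene_nodes is not None else tuple(dict.fromkeys(df["gene_id"]))
    thr = min((w for *_, w in edges), default=0.0)
    return BipartiteNetwork(
        mir_nodes=mirs, gene_nodes=genes, edges=edges,
        threshold_value=thr, quantile=quantile,
    )
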