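"""Bipartite topology: degree, redundancy coefficient, components, summaries.

The redundancy coefficient of a node v in a bipartite graph measures how
dispensable v is for the connectivity of the opposite layer: the fraction of
v's neighbor pairs that would remain co-connected through some other node if
v were removed. rc = 1 means every neighbor pair is covered elsewhere (fully
redundant); rc = 0 means v is the sole bridge between each pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import BipartiteNetwork


def degree(net: BipartiteNetwork, node_id: str) -> int:
    """Number of incident edges (raises KeyError for unknown nodes)."""
    return len(net.neighbors(node_id))


def redundancy_coefficient(net: BipartiteNetwork, node_id: str) -> float | None:
    """Fraction of v's neighbor pairs co-connected through some other node.

    rc(v) = |{{u,w} in N(v) : exists v' != v with u,w in N(v')}| / C(k, 2).

    Undefined (returns ``None``) when the degree is below 2 — the C(k,2)
    denominator vanishes — never coerced to a number.
    """
    nbrs = net.neighbors(node_id)
    k = len(nbrs)
    if k < 2:
        return None
    covered = 0
    for u, w in combinations(sorted(nbrs), 2):
        # another node adjacent to both u and w?
        if (net.neighbors(u) & net.neighbors(w)) - {node_id}:
            covered += 1
    return covered / (k * (k - 1) // 2)


@dataclass(frozen=True)
class NetworkSummary:
    """Headline topology of one subtype network."""

    connected_mirs: int
    connected_genes: int
    n_edges: int
    n_components: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "connected_nodes_miR": [self.connected_mirs],
                "connected_nodes_gene": [self.connected_genes],
                "edges": [self.n_edges],
                "connected_components": [self.n_components],
            }
        )


def connected_components(net: BipartiteNetwork) -> list[set[str]]:
    """Maximal connected sets among non-isolated (k > 0) nodes.

    Isolated nodes are excluded: a component here always spans at least one
    edge, matching the "connected components (non-single nodes)" convention.
    """
    g = nx.Graph()
    g.add_edges_from((m, gn) for m, gn, _ in net.edges)
    return [set(c) for c in nx.connected_components(g)]


def network_summary(net: BipartiteNetwork) -> NetworkSummary:
    connected = {n for m, g, _ in net.edges for n in (m, g)}
    return NetworkSummary(
        connected_mirs=sum(1 for n in net.mir_nodes if n in connected),
        connected_genes=sum(1 for n in net.gene_nodes if n in connected),
        n_edges=net.n_edges,
        n_components=len(connected_components(net)),
    )


def node_metrics(net: BipartiteNetwork) -> pd.DataFrame:
    """Per-node table: node_id, layer, degree, redundancy (NaN if undefined)."""
    rows = []
    for layer, nodes in (("miR", net.mir_nodes), ("gene", net.gene_nodes)):
        for n in nodes:
            rc = redundancy_coefficient(net, n)
            rows.append(
                {
                    "node_id": n,
                    "layer": layer,
                    "degree": degree(net, n),
                    "redundancy": np.nan if rc is None else rc,
                }
            )
    return pd.DataFrame(rows, columns=["node_id", "layer", "degree", "redundancy"])


def degree_distribution(net: BipartiteNetwork) -> pd.DataFrame:
    """Degree histogram per layer (export analog of the supplementary tables)."""
    records = []
    for layer, nodes in (("miR", net.mir_nodes), ("gene", net.gene_nodes)):
        degs = pd.Series([degree(net, n) for n in nodes], dtype=int)
        counts = degs.value_counts().sort_index()
        for k, c in counts.items():
            records.append({"layer": layer, "degree": int(k), "n_nodes": int(c)})
    return pd.DataFrame(records, columns=["layer", "degree", "n_nodes"])


def write_metrics_table(metrics: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, sep="\t", index=False, float_format="%.10g")
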