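"""Independent brute-force oracles used only by the tests.

Each oracle is coded from the definition, deliberately avoiding the code
paths of the package implementation it checks.
"""

from __future__ import annotations

import math
from collections import defaultdict
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from cdremir.network import BipartiteNetwork


def make_net(mirs, genes, pairs) -> BipartiteNetwork:
    """Build a network directly from (mir, gene) pairs, unit weights."""
    return BipartiteNetwork(
        mir_nodes=tuple(mirs),
        gene_nodes=tuple(genes),
        edges=tuple((m, g, 1.0) for m, g in pairs),
        threshold_value=0.0,
        quantile=0.5,
    )


def mi_plugin_oracle(x, y, n_bins: int) -> float:
    """Histogram MI in bits via an independently coded equal-frequency path.

    Labels from ordinal ranks (scipy rankdata), joint histogram via
    numpy histogram2d, direct double sum over cells.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size

    def labels(v):
        r = rankdata(v, method="ordinal") - 1
        lab = (r * n_bins) // n
        # ties share the bin of the group's minimum rank
        out = lab.copy()
        for val in np.unique(v):
            mask = v == val
            out[mask] = lab[mask].min()
        return out

    lx, ly = labels(x), labels(y)
    joint, _, _ = np.histogram2d(lx, ly, bins=[np.arange(n_bins + 1) - 0.5] * 2)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if p[i, j] > 0:
                mi += p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
    return mi


def rc_brute_force(edges, node):
    """Redundancy coefficient by exhaustive neighbor-pair enumeration."""
    adj = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    nbrs = sorted(adj[node])
    k = len(nbrs)
    if k < 2:
        return None
    covered = 0
    for u, w in combinations(nbrs, 2):
        for other in adj:
            if other != node and u in adj[other] and w in adj[other]:
                covered += 1
                break
    return covered / (k * (k - 1) // 2)


def components_union_find(edges):
    """Connected components over non-isolated nodes via union-find."""
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps = defaultdict(set)
    for node in parent:
        comps[find(node)].add(node)
    return sorted(comps.values(), key=lambda s: sorted(s))


def hypergeom_tail_exact(N, K, n, k) -> float:
    """P(X >= k) by exact rational enumeration over the whole support."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def bh_stepup_oracle(pvalues):
    """Benjamini-Hochberg by hand: sort, scale, enforce monotone, cap."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = min(1.0, scaled[rank])
    return out


def svalues_max_over_paths(term, parents, weights):
    """S-values by enumerating every upward path and taking the max product.

    ``parents`` maps child -> [(parent, edge_type)].
    """
    best: dict[str, float] = {}

    def walk(node, prod):
        if prod > best.get(node, 0.0):
            best[node] = prod
        for parent, etype in parents[node]:
            walk(parent, prod * weights[etype])

    walk(term, 1.0)
    return best


def random_bipartite(rng, n_mirs, n_genes, p):
    """Random bipartite edge set with edge probability p."""
    mirs = [f"m{i}" for i in range(n_mirs)]
    genes = [f"g{j}" for j in range(n_genes)]
    pairs = [(m, g) for m in mirs for g in genes if rng.random() < p]
    return mirs, genes, pairs


def random_dag(rng, n_terms):
    """Random single-root DAG: each term attaches to 1-2 earlier terms."""
    parents = {"R0": ()}
    terms = ["R0"]
    for i in range(1, n_terms):
        t = f"T{i}"
        n_par = 1 if len(terms) == 1 or rng.random() < 0.6 else 2
        chosen = rng.choice(len(terms), size=min(n_par, len(terms)), replace=False)
        plist = []
        for c in np.atleast_1d(chosen):
            etype = "is_a" if rng.random() < 0.7 else "part_of"
            plist.append((terms[int(c)], etype))
        parents[t] = tuple(plist)
        terms.append(t)
    return parents
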