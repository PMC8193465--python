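"""Shared fixtures: small graphs and the 20-seed planted-recovery study.

The recovery study (one planted driver with 120 disjoint targets at
strength 0.9, one redundant trio sharing 120 targets, 6000 genes x
1000 miRs x 100 samples, defaults q=0.9999 / k>=100 / rc<=0.5) is the
package's parameter-recovery surface. It is expensive, so it runs once per
session and several tests read off different aspects of the same runs.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cdremir.commodore import classify_commodores, neighborhood
from cdremir.metrics import node_metrics
from cdremir.network import score_all_pairs, threshold_by_quantile
from cdremir.synthetic import (
    DEFAULT_N_GENES,
    DEFAULT_N_MIRS,
    DEFAULT_N_SAMPLES,
    default_planted,
    generate_dataset,
    noise_only,
)

from _oracles import make_net

N_STUDY_SEEDS = 20


def _one_run(structure):
    gene, mir, _assign, _st = generate_dataset(
        DEFAULT_N_SAMPLES, DEFAULT_N_GENES, DEFAULT_N_MIRS, structure
    )
    scores = score_all_pairs(mir, gene)
    net = threshold_by_quantile(scores)
    metrics = node_metrics(net)
    records = classify_commodores(net, metrics=metrics)
    return net, metrics, records


@pytest.fixture(scope="session")
def recovery_study():
    """Twenty seeded runs with planted driver + redundant trio."""
    runs = []
    for i in range(N_STUDY_SEEDS):
        st = default_planted(seed=1000 + i)
        driver = st.commodore_mirs[0]
        trio = st.redundant_hub_groups[0][0]
        targets = st.commodore_targets[driver]
        net, metrics, records = _one_run(st)
        mir_metrics = metrics[metrics["layer"] == "miR"].set_index("node_id")
        runs.append(
            {
                "seed": 1000 + i,
                "driver": driver,
                "trio": trio,
                "targets": targets,
                "commodores": {r.mir_id for r in records},
                "driver_targets_linked": len(neighborhood(net, driver) & targets),
                "trio_rc": [float(mir_metrics.loc[m, "redundancy"]) for m in trio],
                "n_edges": net.n_edges,
                "threshold": net.threshold_value,
            }
        )
    return runs


@pytest.fixture(scope="session")
def noise_study():
    """Twenty seeded pure-noise runs (driver_strength = 0, nothing planted)."""
    runs = []
    for i in range(N_STUDY_SEEDS):
        net, _metrics, records = _one_run(noise_only(seed=5000 + i))
        runs.append(
            {
                "seed": 5000 + i,
                "commodores": {r.mir_id for r in records},
                "n_edges": net.n_edges,
                "max_mir_degree": max(
                    (len(net.neighbors(m)) for m in net.mir_nodes), default=0
                ),
            }
        )
    return runs


@pytest.fixture
def k22():
    """Complete bipartite K_{2,2}."""
    return make_net(
        ["m1", "m2"], ["g1", "g2"],
        [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")],
    )


@pytest.fixture
def two_blocks():
    """Two disjoint K_{2,2} blocks (2 components, 8 edges)."""
    pairs = [
        ("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2"),
        ("m3", "g3"), ("m3", "g4"), ("m4", "g3"), ("m4", "g4"),
    ]
    return make_net(["m1", "m2", "m3", "m4"], ["g1", "g2", "g3", "g4"], pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
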