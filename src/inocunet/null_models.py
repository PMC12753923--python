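"""Erdős–Rényi null ensembles and the small-world comparison.

The null model is G(n, m): uniform simple graphs with exactly the observed
node and edge counts, so degree and density match the real network by
construction.  Metrics are computed with the same routine (and the same
community-detection policy) as the real network.  The small-world verdict
follows the qualitative rule used for these soil networks: modularity,
average clustering coefficient and average path length all greater than the
ensemble means.  z-scores are reported alongside as additional context.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import NetworkMetrics, graph_metrics

__all__ = [
    "NullEnsembleSummary",
    "SmallWorldVerdict",
    "er_ensemble",
    "small_world_assessment",
]

_METRICS = ("clustering", "path_length", "modularity", "average_degree", "density")


@dataclass(frozen=True)
class NullEnsembleSummary:
    n_nodes: int
    n_edges: int
    mean: dict[str, float]
    sd: dict[str, float]
    ensemble_size: int
    seed: int


@dataclass(frozen=True)
class SmallWorldVerdict:
    exceeds: dict[str, bool]            # real value > null mean, per metric
    z_scores: dict[str, float | None]   # None where the ensemble sd is 0
    small_world: bool                   # Q, C and L all exceed null means
    modular: bool                       # Q > 0.4 (strict)


def er_ensemble(n_nodes: int, n_edges: int, replicates: int = 10_000,
                seed: int = 0, restarts: int = 10) -> NullEnsembleSummary:
    """Metric distribution over G(n, m) uniform random simple graphs."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible on {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {k: [] for k in _METRICS}
    for _ in range(replicates):
        graph = nx.gnm_random_graph(n_nodes, n_edges,
                                    seed=int(rng.integers(2 ** 31)))
        metrics = graph_metrics(graph, seed=int(rng.integers(2 ** 31)),
                                restarts=restarts)
        for key in _METRICS:
            samples[key].append(getattr(metrics, key))
    return NullEnsembleSummary(
        n_nodes=n_nodes, n_edges=n_edges,
        mean={k: float(np.mean(v)) for k, v in samples.items()},
        sd={k: float(np.std(v, ddof=0)) for k, v in samples.items()},
        ensemble_size=replicates, seed=seed,
    )


def small_world_assessment(real: NetworkMetrics,
                           null: NullEnsembleSummary) -> SmallWorldVerdict:
    """Compare a real network against its matched G(n, m) ensemble."""
    if (real.n_nodes, real.n_edges) != (null.n_nodes, null.n_edges):
        raise ValueError(
            f"real network ({real.n_nodes} nodes, {real.n_edges} edges) does "
            f"not match the ensemble ({null.n_nodes}, {null.n_edges})")
    exceeds, z_scores = {}, {}
    for key in ("modularity", "clustering", "path_length"):
        value = getattr(real, key)
        exceeds[key] = value > null.mean[key]
        sd = null.sd[key]
        z_scores[key] = (value - null.mean[key]) / sd if sd > 0 else None
    return SmallWorldVerdict(
        exceeds=exceeds, z_scores=z_scores,
        small_world=all(exceeds.values()),
        modular=real.modularity > 0.4,
    )
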