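"""Co-occurrence network construction and topology.

The cascade per treatment network: keep OTUs whose mean relative abundance
exceeds 0.05%, compute all pairwise Spearman rank correlations, adjust
p-values with the Benjamini-Hochberg step-up, and keep edges with
|rho| > 0.6 and adjusted q < 0.05 (both strict).  Topological metrics
(average degree, density, clustering, path length over connected pairs,
Louvain modularity) are computed identically for real and null graphs so
they remain comparable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    OtuTable,
    RelativeAbundanceMatrix,
    SampleMetadata,
    TaxonomyTable,
    to_relative_abundance,
)

__all__ = [
    "CorrelationResult",
    "CooccurrenceNetwork",
    "NetworkMetrics",
    "filter_abundant_otus",
    "spearman_all_pairs",
    "bh_adjust",
    "build_network",
    "build_treatment_network",
    "compute_metrics",
    "graph_metrics",
    "edge_sign_fractions",
    "phylum_edge_matrix",
    "write_graphml",
]

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 9  # below 10 samples the t-approximation is unreliable


@dataclass(frozen=True)
class CorrelationResult:
    """All-pairs Spearman correlations with BH-adjusted q-values."""

    pairs: pd.DataFrame            # otu_a, otu_b, rho, p_raw, q, n
    excluded_pairs: tuple[tuple[str, str], ...] = ()   # zero-variance OTUs
    n_samples: int = 0


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Simple signed graph over OTUs passing both correlation thresholds."""

    graph: nx.Graph
    rho_threshold: float
    q_threshold: float
    boundary_ties: int = 0         # pairs excluded exactly at a threshold

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    clustering: float
    path_length: float
    modularity: float
    n_components: int
    positive_fraction: float | None = None
    negative_fraction: float | None = None
    partition: tuple[frozenset, ...] = field(default=(), repr=False)


def filter_abundant_otus(matrix: RelativeAbundanceMatrix,
                         threshold: float = 0.0005,
                         mode: str = "mean") -> list[str]:
    """OTUs whose mean (or, with ``mode="max"``, maximum) relative abundance
    across the samples in scope is strictly greater than ``threshold``."""
    if mode not in ("mean", "max"):
        raise ValueError(f"unknown abundance filter mode {mode!r}")
    df = matrix.to_dataframe()
    stat = df.mean(axis=0) if mode == "mean" else df.max(axis=0)
    kept = [otu for otu in df.columns if stat[otu] > threshold]
    if not kept:
        logger.warning("abundance filter at %g retained no OTUs", threshold)
    logger.info("abundance filter: retained %d of %d OTUs", len(kept), df.shape[1])
    return kept


class _ExactSpearmanNull:
    """Exact permutation null of Spearman rho for small n (<= 9).

    Permuting one midrank vector against the other over all n! orderings;
    the null distribution depends only on the two rank multisets (tie
    patterns), so it is computed once per distinct pattern pair and reused
    across OTU pairs.
    """

    def __init__(self, n: int) -> None:
        self._perms = np.array(list(itertools.permutations(range(n))))
        self._cache: dict[tuple, np.ndarray] = {}

    def _null_abs(self, rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
        key = tuple(sorted((tuple(np.sort(rx)), tuple(np.sort(ry)))))
        cached = self._cache.get(key)
        if cached is None:
            sx = rx - rx.mean()
            sy = ry - ry.mean()
            denom = np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
            null = np.abs(sy[self._perms] @ sx) / denom
            cached = np.sort(null)
            self._cache[key] = cached
        return cached

    def p_value(self, rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
        null_abs = self._null_abs(rx, ry)
        # two-sided: fraction of permutations with |rho| >= |rho_obs|
        below = np.searchsorted(null_abs, abs(rho_obs) - 1e-12, side="left")
        return float(len(null_abs) - below) / len(null_abs)


def spearman_all_pairs(matrix: RelativeAbundanceMatrix | pd.DataFrame,
                       otu_ids: list[str] | None = None) -> CorrelationResult:
    """Spearman rho and p for every OTU pair (midrank tie handling).

    p-values come from the exact permutation distribution when the number of
    samples is <= 9 and from the t-approximation otherwise.  Needs at least
    4 samples.  Zero-variance OTU vectors make rho undefined; such pairs are
    excluded from testing and recorded on the result.
    """
    df = matrix.to_dataframe() if isinstance(matrix, RelativeAbundanceMatrix) else matrix
    if otu_ids is not None:
        df = df[otu_ids]
    n, k = df.shape
    if n < 4:
        raise ValueError(f"Spearman testing needs >= 4 samples, got {n}")

    values = df.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    constant = values.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_matrix = np.corrcoef(ranks, rowvar=False)

    exact_null = _ExactSpearmanNull(n) if n <= EXACT_P_MAX_N else None
    rows, excluded = [], []
    cols = list(df.columns)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = cols[i], cols[j]
            if constant[i] or constant[j]:
                excluded.append((a, b))
                continue
            rho = float(np.clip(rho_matrix[i, j], -1.0, 1.0))
            if exact_null is not None:
                p = exact_null.p_value(ranks[:, i], ranks[:, j], rho)
            elif abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            rows.append({"otu_a": a, "otu_b": b, "rho": rho, "p_raw": p, "n": n})

    pairs = pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p_raw", "n"])
    pairs["q"] = bh_adjust(pairs["p_raw"].to_numpy()) if len(pairs) else []
    if excluded:
        logger.info("excluded %d pairs with zero-variance OTU vectors", len(excluded))
    logger.info("tested %d OTU pairs across %d samples", len(pairs), n)
    return CorrelationResult(pairs=pairs, excluded_pairs=tuple(excluded), n_samples=n)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def build_network(corr: CorrelationResult, taxonomy: TaxonomyTable,
                  mean_abundance: pd.Series | None = None,
                  rho_threshold: float = 0.6, q_threshold: float = 0.05,
                  include_isolated: bool = False,
                  filtered_otus: list[str] | None = None,
                  use_adjusted: bool = True) -> CooccurrenceNetwork:
    """Threshold the correlation table into a signed co-occurrence graph.

    An edge requires |rho| strictly above ``rho_threshold`` and q strictly
    below ``q_threshold``; pairs exactly at either boundary are excluded and
    counted.  By default the node set is the filtered OTUs that carry at
    least one edge; ``include_isolated`` adds the rest of ``filtered_otus``.
    ``use_adjusted=False`` thresholds the raw p-values instead of the BH
    q-values (sensitivity analysis only; the adjusted value is authoritative).
    """
    pairs = corr.pairs
    pcol = "q" if use_adjusted else "p_raw"
    strong = pairs["rho"].abs() > rho_threshold
    significant = pairs[pcol] < q_threshold
    at_boundary = ((pairs["rho"].abs() == rho_threshold) & significant) | \
                  ((pairs[pcol] == q_threshold) & strong)
    kept = pairs[strong & significant].sort_values(["otu_a", "otu_b"])

    graph = nx.Graph()
    if include_isolated and filtered_otus is not None:
        graph.add_nodes_from(sorted(filtered_otus))
    for row in kept.itertuples():
        graph.add_edge(row.otu_a, row.otu_b, rho=float(row.rho),
                       q=float(row.q), weight=float(row.rho),
                       sign=1 if row.rho > 0 else -1)
    for node in graph.nodes:
        graph.nodes[node]["phylum"] = taxonomy.phylum(node)
        if mean_abundance is not None and node in mean_abundance.index:
            graph.nodes[node]["mean_abundance"] = float(mean_abundance[node])
    n_ties = int(at_boundary.sum())
    if n_ties:
        logger.info("excluded %d boundary ties at the thresholds", n_ties)
    logger.info("network: %d nodes, %d edges (|rho|>%g, q<%g)",
                graph.number_of_nodes(), graph.number_of_edges(),
                rho_threshold, q_threshold)
    return CooccurrenceNetwork(graph=graph, rho_threshold=rho_threshold,
                               q_threshold=q_threshold, boundary_ties=n_ties)


def build_treatment_network(table: OtuTable, taxonomy: TaxonomyTable,
                            metadata: SampleMetadata, treatment: str,
                            abundance_threshold: float = 0.0005,
                            rho_threshold: float = 0.6,
                            q_threshold: float = 0.05,
                            abundance_mode: str = "mean",
                            include_isolated: bool = False) -> CooccurrenceNetwork:
    """Full cascade for one treatment, pooling bulk + rhizosphere samples."""
    samples = metadata.samples_for(treatment=treatment)
    present = [s for s in table.sample_ids if s in samples]
    if len(present) < 4:
        raise ValueError(f"treatment {treatment!r} has {len(present)} samples; need >= 4")
    sub = table.select_samples(present)
    rel = to_relative_abundance(sub)
    kept = filter_abundant_otus(rel, threshold=abundance_threshold, mode=abundance_mode)
    corr = spearman_all_pairs(rel, otu_ids=kept)
    return build_network(corr, taxonomy, mean_abundance=rel.mean_abundance(),
                         rho_threshold=rho_threshold, q_threshold=q_threshold,
                         include_isolated=include_isolated, filtered_otus=kept)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _best_louvain_partition(graph: nx.Graph, seed: int, restarts: int
                            ) -> tuple[list[set], float]:
    """Greedy modularity maximization (Louvain/Leiden family), best of
    ``restarts`` seeded runs; Q scored with the standard partition formula."""
    import igraph as ig
    import leidenalg

    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes),
                 edges=[(index[a], index[b]) for a, b in graph.edges])
    best_q, best_parts = -math.inf, [set(nodes)]
    for r in range(restarts):
        partition = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition,
            seed=seed + r + 1, n_iterations=2)
        parts = [{nodes[i] for i in community} for community in partition]
        # weight=None: Q is defined on the unsigned, unweighted graph
        q = nx.community.modularity(graph, parts, resolution=1.0, weight=None)
        if q > best_q:
            best_q, best_parts = q, parts
    return best_parts, best_q


def graph_metrics(graph: nx.Graph, seed: int = 0, restarts: int = 10) -> NetworkMetrics:
    """Topology of an arbitrary simple graph (shared by real and null runs).

    Average path length is the mean shortest-path length over connected node
    pairs only; modularity is the best of ``restarts`` Louvain runs at
    resolution 1 on the unsigned graph.  Nodes of degree < 2 contribute a
    local clustering of 0.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("cannot compute metrics of an empty graph")
    m = graph.number_of_edges()
    avg_degree = 2.0 * m / n
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    clustering = float(np.mean(list(nx.clustering(graph).values())))

    total, pairs, n_components = 0.0, 0, 0
    for component in nx.connected_components(graph):
        n_components += 1
        sub = graph.subgraph(component)
        if len(component) < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += len(component) * (len(component) - 1)
    path_length = total / pairs if pairs else 0.0

    if m > 0:
        parts, q = _best_louvain_partition(graph, seed, restarts)
    else:
        parts, q = [ {v} for v in graph.nodes ], 0.0
    return NetworkMetrics(
        n_nodes=n, n_edges=m, average_degree=avg_degree, density=density,
        clustering=clustering, path_length=path_length, modularity=float(q),
        n_components=n_components,
        partition=tuple(frozenset(p) for p in parts),
    )


def compute_metrics(net: CooccurrenceNetwork, seed: int = 0,
                    restarts: int = 10) -> NetworkMetrics:
    """NetworkMetrics for a co-occurrence network, with sign fractions."""
    metrics = graph_metrics(net.graph, seed=seed, restarts=restarts)
    fractions = edge_sign_fractions(net)
    pos, neg = fractions if fractions is not None else (None, None)
    return NetworkMetrics(
        n_nodes=metrics.n_nodes, n_edges=metrics.n_edges,
        average_degree=metrics.average_degree, density=metrics.density,
        clustering=metrics.clustering, path_length=metrics.path_length,
        modularity=metrics.modularity, n_components=metrics.n_components,
        positive_fraction=pos, negative_fraction=neg,
        partition=metrics.partition,
    )


def edge_sign_fractions(net: CooccurrenceNetwork) -> tuple[float, float] | None:
    """(positive, negative) edge fractions; None on an edgeless graph."""
    m = net.n_edges
    if m == 0:
        return None
    positive = sum(1 for *_, d in net.graph.edges(data=True) if d["sign"] > 0)
    return positive / m, (m - positive) / m


def phylum_edge_matrix(net: CooccurrenceNetwork,
                       taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Symmetric phylum x phylum edge-count matrix (diagonal = intra-phylum)."""
    phyla = sorted({taxonomy.phylum(v) for v in net.graph.nodes})
    matrix = pd.DataFrame(0, index=phyla, columns=phyla, dtype=int)
    for a, b in net.graph.edges:
        pa, pb = taxonomy.phylum(a), taxonomy.phylum(b)
        matrix.loc[pa, pb] += 1
        if pa != pb:
            matrix.loc[pb, pa] += 1
    return matrix


def write_graphml(net: CooccurrenceNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
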