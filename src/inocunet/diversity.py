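"""Alpha and beta diversity statistics and group comparisons.

Alpha diversity follows mothur conventions (Shannon in nats, bias-corrected
Chao1, both Simpson variants, Good's coverage).  Beta diversity is
Bray-Curtis dissimilarity with classical-scaling PCoA, average-linkage
(UPGMA) clustering and ANOSIM.  Group comparisons reproduce the standard
design: one-way ANOVA with Duncan's multiple-range letters across
treatments, and a Welch t-test between bulk and rhizosphere compartments
within each treatment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .data_model import OtuTable, RelativeAbundanceMatrix, SampleMetadata

__all__ = [
    "alpha_diversity",
    "rarefy_counts",
    "rarefaction_curve",
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "upgma_dendrogram",
    "AnosimResult",
    "anosim",
    "GroupTestResult",
    "group_tests",
    "duncan_letters",
]

ALPHA_METRICS = ("observed_otus", "shannon", "simpson_gini", "simpson_dominance",
                 "chao1", "goods_coverage")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _alpha_one(counts: np.ndarray) -> dict[str, float]:
    counts = counts[counts > 0]
    n = counts.sum()
    p = counts / n
    shannon = float(-(p * np.log(p)).sum())
    dominance = float((p ** 2).sum())
    s_obs = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))  # bias-corrected form
    return {
        "observed_otus": float(s_obs),
        "shannon": shannon,
        "simpson_gini": 1.0 - dominance,
        "simpson_dominance": dominance,
        "chao1": float(chao1),
        "goods_coverage": 1.0 - f1 / n,
    }


def rarefy_counts(counts: np.ndarray, depth: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Subsample one sample's counts to ``depth`` reads without replacement."""
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def alpha_diversity(table: OtuTable, rarefy_to: int | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    With ``rarefy_to`` set, every sample is first subsampled without
    replacement to that even depth (seeded, bit-reproducible); every sample
    total must be at least the requested depth.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        if rarefy_to is not None:
            total = int(counts.sum())
            if rarefy_to > total:
                raise ValueError(
                    f"rarefy_to={rarefy_to} exceeds total {total} of sample {sid!r}")
            counts = rarefy_counts(counts, rarefy_to, rng)
        rows[sid] = _alpha_one(np.asarray(counts))
    return pd.DataFrame.from_dict(rows, orient="index")[list(ALPHA_METRICS)]


def rarefaction_curve(table: OtuTable, depths: list[int], reps: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean observed-OTU count per sample at each subsampling depth."""
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    result = pd.DataFrame(index=list(table.sample_ids),
                          columns=[int(d) for d in depths], dtype=float)
    for i, sid in enumerate(table.sample_ids):
        for depth in depths:
            if depth > totals[i]:
                raise ValueError(
                    f"depth {depth} exceeds total {totals[i]} of sample {sid!r}")
            if depth == 0:
                result.loc[sid, depth] = 0.0
                continue
            observed = [int((rarefy_counts(table.counts[i], depth, rng) > 0).sum())
                        for _ in range(reps)]
            result.loc[sid, depth] = float(np.mean(observed))
    return result


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(matrix: RelativeAbundanceMatrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    d = squareform(pdist(matrix.values, metric="braycurtis"))
    ids = list(matrix.sample_ids)
    return pd.DataFrame(d, index=ids, columns=ids)


def _check_distance_matrix(distances: pd.DataFrame) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame     # samples x axes
    explained: np.ndarray         # fraction of positive-eigenvalue variance
    eigenvalues: np.ndarray       # all eigenvalues, descending


def pcoa(distances: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates analysis by double-centering -1/2 D^2.

    Only positive eigenvalues yield axes; explained-variance fractions are
    taken over the sum of positive eigenvalues (negative eigenvalues from
    the semi-metric input are reported but not corrected).  Each axis's sign
    is fixed by making its largest-magnitude loading positive.
    """
    d = _check_distance_matrix(distances)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-10 * abs(eigval[0]) if n else 0)
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    for k in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] *= -1
    explained = eigval[positive] / eigval[positive].sum() if positive.any() else np.array([])
    axes = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(distances.index), columns=axes),
        explained=explained,
        eigenvalues=eigval,
    )


def upgma_dendrogram(distances: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) tree of the samples as a newick string.

    Samples are processed in lexicographic label order so that merge
    tie-breaking is deterministic.  Branch lengths place every leaf at its
    cluster's merge height / 2 (ultrametric output).
    """
    d = _check_distance_matrix(distances)
    labels = sorted(str(x) for x in distances.index)
    order = [list(distances.index).index(lbl) for lbl in labels]
    d = d[np.ix_(order, order)]
    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")

    n = len(labels)
    newick = {i: (labels[i], 0.0) for i in range(n)}  # node -> (subtree, height)
    for k, (a, b, height, _) in enumerate(linkage):
        sa, ha = newick.pop(int(a))
        sb, hb = newick.pop(int(b))
        branch_a = height / 2 - ha
        branch_b = height / 2 - hb
        newick[n + k] = (f"({sa}:{branch_a:.10g},{sb}:{branch_b:.10g})", height / 2)
    (tree, _), = newick.values()
    return tree + ";"


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    grouping_name: str


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    m = len(labels) * (len(labels) - 1) / 2
    return float((between.mean() - within.mean()) / (m / 2))


def anosim(distances: pd.DataFrame, grouping: pd.Series | dict,
           n_permutations: int | str = 999, seed: int = 0,
           grouping_name: str = "group") -> AnosimResult:
    """Analysis of similarities on rank-transformed dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2.  The p-value uses the add-one permutation estimator,
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations); pass
    ``n_permutations="all"`` to enumerate every label permutation instead
    (then p is the exact fraction of permutations with R >= R_obs).
    """
    d = _check_distance_matrix(distances)
    if isinstance(grouping, dict):
        grouping = pd.Series(grouping)
    labels = np.asarray([grouping[s] for s in distances.index])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        small = uniq[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    iu = np.triu_indices(d.shape[0], k=1)
    ranks = np.zeros_like(d)
    ranked = stats.rankdata(d[iu])
    ranks[iu] = ranked
    ranks.T[iu] = ranked

    r_obs = _anosim_r(ranks, labels)
    if n_permutations == "all":
        perms = list(itertools.permutations(labels))
        r_null = np.array([_anosim_r(ranks, np.asarray(p)) for p in perms])
        p_value = float((r_null >= r_obs - 1e-12).mean())
        n_done = len(perms)
    else:
        rng = np.random.default_rng(seed)
        n_done = int(n_permutations)
        hits = 0
        for _ in range(n_done):
            if _anosim_r(ranks, rng.permutation(labels)) >= r_obs - 1e-12:
                hits += 1
        p_value = (1 + hits) / (1 + n_done)
    return AnosimResult(r=r_obs, p_value=p_value, n_permutations=n_done,
                        grouping_name=grouping_name)


# ---------------------------------------------------------------------------
# Group comparisons (ANOVA, Duncan letters, Welch t)
# ---------------------------------------------------------------------------

def _duncan_critical_range(n_means_spanned: int, df_error: int, mse: float,
                           harmonic_n: float, alpha: float) -> float:
    # Duncan's protection level: the test for a span of p means runs at
    # 1 - (1 - alpha)^(p-1), using the studentized range distribution.
    level = (1.0 - alpha) ** (n_means_spanned - 1)
    q = stats.studentized_range.ppf(level, n_means_spanned, df_error)
    return float(q * np.sqrt(mse / harmonic_n))


def duncan_letters(values: pd.Series, groups: pd.Series,
                   alpha: float = 0.05) -> dict[str, str]:
    """Duncan's multiple-range test compact letter display.

    Groups sharing a letter are not separated at the given alpha.  Uses the
    harmonic mean group size for unbalanced designs.  With zero error
    variance, groups share a letter iff their means tie exactly.
    """
    groups = groups.loc[values.index]
    names = list(pd.unique(groups))
    means = {g: float(values[groups == g].mean()) for g in names}
    ns = {g: int((groups == g).sum()) for g in names}
    k = len(names)
    if k < 2:
        return {names[0]: "a"} if names else {}

    df_error = sum(ns.values()) - k
    sse = sum(((values[groups == g] - means[g]) ** 2).sum() for g in names)
    mse = sse / df_error if df_error > 0 else 0.0
    harmonic_n = k / sum(1.0 / ns[g] for g in names)

    ordered = sorted(names, key=lambda g: (-means[g], str(g)))

    def separated(i: int, j: int) -> bool:
        # i < j in descending-mean order; spans j - i + 1 means
        diff = means[ordered[i]] - means[ordered[j]]
        if mse == 0.0 or df_error == 0:
            return diff > 1e-12
        crit = _duncan_critical_range(j - i + 1, df_error, mse, harmonic_n, alpha)
        return diff > crit

    # maximal non-separated stretches -> letters (insert-absorb display)
    stretches: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not separated(i, j + 1):
            j += 1
        if not any(a <= i and j <= b for a, b in stretches):
            stretches.append((i, j))
    letters = {g: "" for g in names}
    for idx, (a, b) in enumerate(stretches):
        symbol = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for g in ordered[a:b + 1]:
            letters[g] += symbol
    return letters


@dataclass(frozen=True)
class GroupTestResult:
    anova: pd.DataFrame        # per compartment: F, p, df
    duncan: pd.DataFrame       # compartment x treatment -> letter
    ttests: pd.DataFrame       # per treatment: Welch t, Satterthwaite df, p


def group_tests(values: pd.Series, metadata: SampleMetadata) -> GroupTestResult:
    """Treatment/compartment comparisons for one per-sample metric.

    Within each compartment: one-way ANOVA across treatments plus Duncan
    letters at alpha = 0.05.  Within each treatment: Welch two-sample t-test
    (Satterthwaite df) between bulk and rhizosphere samples.
    """
    meta = metadata.to_dataframe().loc[list(values.index)]
    anova_rows, duncan_rows, ttest_rows = [], [], []

    for compartment in sorted(meta["compartment"].unique()):
        mask = meta["compartment"] == compartment
        sub, submeta = values[mask], meta[mask]
        groups = [sub[submeta["treatment"] == t].to_numpy()
                  for t in sorted(submeta["treatment"].unique())]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            if np.ptp(np.concatenate(groups)) == 0:
                f_stat, p_val = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    f_stat, p_val = stats.f_oneway(*groups)
                if np.isnan(f_stat):  # zero within- and between-group variance
                    f_stat, p_val = 0.0, 1.0
            anova_rows.append({"compartment": compartment, "F": float(f_stat),
                               "p": float(p_val),
                               "df_between": len(groups) - 1,
                               "df_within": sum(len(g) for g in groups) - len(groups)})
            letters = duncan_letters(sub, submeta["treatment"])
            for treatment, letter in letters.items():
                duncan_rows.append({"compartment": compartment,
                                    "treatment": treatment, "letters": letter})

    for treatment in sorted(meta["treatment"].unique()):
        mask = meta["treatment"] == treatment
        bulk = values[mask & (meta["compartment"] == "bulk")].to_numpy()
        rhizo = values[mask & (meta["compartment"] == "rhizosphere")].to_numpy()
        if len(bulk) >= 2 and len(rhizo) >= 2:
            if np.ptp(np.concatenate([bulk, rhizo])) == 0:
                t_stat, p_val, df = 0.0, 1.0, float(len(bulk) + len(rhizo) - 2)
            else:
                res = stats.ttest_ind(bulk, rhizo, equal_var=False)
                t_stat, p_val, df = float(res.statistic), float(res.pvalue), float(res.df)
            ttest_rows.append({"treatment": treatment, "t": t_stat, "df": df,
                               "p": p_val})

    return GroupTestResult(
        anova=pd.DataFrame(anova_rows),
        duncan=pd.DataFrame(duncan_rows),
        ttests=pd.DataFrame(ttest_rows),
    )
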