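import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from inocunet.data_model import OtuTable, RelativeAbundanceMatrix
from inocunet.diversity import (
    alpha_diversity,
    anosim,
    bray_curtis,
    duncan_letters,
    group_tests,
    pcoa,
    rarefaction_curve,
    upgma_dendrogram,
)


def _table(rows, sample_ids=None, otu_ids=None):
    rows = np.atleast_2d(np.asarray(rows))
    sample_ids = sample_ids or tuple(f"s{i+1}" for i in range(rows.shape[0]))
    otu_ids = otu_ids or tuple(f"o{j+1}" for j in range(rows.shape[1]))
    return OtuTable(tuple(sample_ids), tuple(otu_ids), rows)


def _relabund(rows, sample_ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    sample_ids = sample_ids or tuple(f"s{i+1}" for i in range(rows.shape[0]))
    otu_ids = tuple(f"o{j+1}" for j in range(rows.shape[1]))
    return RelativeAbundanceMatrix(tuple(sample_ids), otu_ids, rows)


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        table = _table([[10] * 8, [10] * 8])
        alpha = alpha_diversity(table)
        assert alpha.loc["s1", "shannon"] == pytest.approx(math.log(8))
        assert alpha.loc["s1", "simpson_gini"] == pytest.approx(0.875)
        assert alpha.loc["s1", "simpson_dominance"] == pytest.approx(0.125)

    def test_no_singletons_means_chao1_equals_richness_and_full_coverage(self):
        table = _table([[2, 3, 5, 7], [2, 3, 5, 7]])
        alpha = alpha_diversity(table)
        assert alpha.loc["s1", "chao1"] == alpha.loc["s1", "observed_otus"] == 4
        assert alpha.loc["s1", "goods_coverage"] == 1.0

    def test_bias_corrected_chao1_hand_case(self):
        # 4 singletons, 2 doubletons, 10 OTUs at 5: 16 + 4*3/(2*3) = 18
        counts = [1, 1, 1, 1, 2, 2] + [5] * 10
        table = _table([counts, counts])
        alpha = alpha_diversity(table)
        assert alpha.loc["s1", "chao1"] == pytest.approx(18.0)

    def test_goods_coverage_counts_singletons(self):
        table = _table([[1, 1, 8], [5, 5, 0]])
        alpha = alpha_diversity(table)
        assert alpha.loc["s1", "goods_coverage"] == pytest.approx(1 - 2 / 10)
        assert alpha.loc["s2", "goods_coverage"] == 1.0

    def test_matches_skbio_on_random_counts(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=30)
        counts[0] = 1  # ensure a singleton
        table = _table([counts, counts])
        alpha = alpha_diversity(table)
        assert alpha.loc["s1", "shannon"] == pytest.approx(
            float(skbio_alpha.shannon(counts, base=math.e)))
        assert alpha.loc["s1", "chao1"] == pytest.approx(
            float(skbio_alpha.chao1(counts, bias_corrected=True)))

    def test_rarefied_alpha_is_reproducible(self):
        table = _table([[50, 30, 20, 10], [10, 20, 30, 50]])
        a = alpha_diversity(table, rarefy_to=60, seed=11)
        b = alpha_diversity(table, rarefy_to=60, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_rarefy_beyond_total_errors_with_sample_name(self):
        table = _table([[5, 5], [100, 100]])
        with pytest.raises(ValueError, match="s1"):
            alpha_diversity(table, rarefy_to=50)


class TestRarefactionCurve:
    def test_full_depth_recovers_observed_richness(self):
        table = _table([[10, 5, 0, 1], [4, 4, 4, 4]])
        curve = rarefaction_curve(table, depths=[16], reps=5, seed=0)
        assert curve.loc["s1", 16] == 3.0
        assert curve.loc["s2", 16] == 4.0

    def test_depth_zero_gives_zero(self):
        table = _table([[10, 10], [10, 10]])
        curve = rarefaction_curve(table, depths=[0, 5], reps=3, seed=0)
        assert (curve[0] == 0).all()

    def test_monotone_in_depth(self):
        table = _table([np.arange(1, 11), np.arange(1, 11)])
        curve = rarefaction_curve(table, depths=[1, 5, 20, 55], reps=30, seed=2)
        diffs = curve.to_numpy()[:, 1:] - curve.to_numpy()[:, :-1]
        assert (diffs >= 0).all()

    def test_hypergeometric_closed_form(self):
        # 2 OTUs at 50/50, depth 2: E[observed] = 2*(1 - C(50,2)/C(100,2))
        table = _table([[50, 50], [50, 50]])
        reps = 2000
        curve = rarefaction_curve(table, depths=[2], reps=reps, seed=5)
        expected = 2 * (1 - comb(50, 2) / comb(100, 2))
        p_two = 1 - 2 * comb(50, 2) / comb(100, 2)  # both OTUs seen
        se = math.sqrt(p_two * (1 - p_two) / reps)
        assert abs(curve.loc["s1", 2] - expected) < 3 * se


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        rel = _relabund([[0.5, 0.5], [0.5, 0.5]])
        assert bray_curtis(rel).loc["s1", "s2"] == 0.0

    def test_disjoint_supports_distance_one(self):
        rel = _relabund([[1.0, 0.0], [0.0, 1.0]])
        assert bray_curtis(rel).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        rel = _relabund([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]])
        assert bray_curtis(rel).loc["s1", "s2"] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal_unit_range(self):
        rng = np.random.default_rng(3)
        raw = rng.random((6, 10))
        rel = _relabund(raw / raw.sum(axis=1, keepdims=True))
        d = bray_curtis(rel).to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestPcoa:
    def test_two_samples_at_distance_d(self):
        d = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(d)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        np.testing.assert_allclose(coords, [-0.4, 0.4], atol=1e-12)

    def test_collinear_points_put_all_variance_on_axis_one(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        res = pcoa(d)
        assert res.explained[0] == pytest.approx(1.0)

    def test_euclidean_input_reconstructs_distances(self):
        rng = np.random.default_rng(1)
        points = rng.random((4, 2))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        coords = res.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-6)

    def test_explained_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        raw = rng.random((7, 12))
        rel = _relabund(raw / raw.sum(axis=1, keepdims=True))
        res = pcoa(bray_curtis(rel))
        ev = res.explained
        assert (np.diff(ev) <= 1e-12).all()
        assert (ev >= 0).all() and ev.sum() <= 1 + 1e-9

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


def _cophenetic_from_newick(newick: str) -> pd.DataFrame:
    skbio = pytest.importorskip("skbio")
    import io

    tree = skbio.TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def _naive_upgma_cophenetic(d: np.ndarray, labels: list[str]) -> pd.DataFrame:
    """Independent textbook UPGMA agglomeration (oracle)."""
    clusters = [[i] for i in range(len(labels))]
    coph = np.zeros_like(d, dtype=float)
    dist = d.astype(float).copy()
    active = list(range(len(labels)))
    cluster_d = {(i, j): dist[i, j] for i in active for j in active if i < j}
    members = {i: [i] for i in active}
    next_id = len(labels)
    while len(active) > 1:
        (a, b), h = min(cluster_d.items(), key=lambda kv: (kv[1], kv[0]))
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        merged = members[a] + members[b]
        active = [x for x in active if x not in (a, b)]
        new_d = {}
        for x in active:
            pairs = [(min(x, y), max(x, y)) for y in (a, b)]
            na, nb = len(members[a]), len(members[b])
            new_d[x] = (cluster_d[pairs[0]] * na + cluster_d[pairs[1]] * nb) / (na + nb)
        cluster_d = {k: v for k, v in cluster_d.items()
                     if a not in k and b not in k}
        for x in active:
            cluster_d[(min(x, next_id), max(x, next_id))] = new_d[x]
        members[next_id] = merged
        active.append(next_id)
        next_id += 1
    return pd.DataFrame(coph, index=labels, columns=labels)


class TestUpgma:
    def test_close_pair_forms_sister_clade(self):
        d = pd.DataFrame([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
                         index=list("ABC"), columns=list("ABC"))
        coph = _cophenetic_from_newick(upgma_dendrogram(d))
        assert coph.loc["A", "B"] < coph.loc["A", "C"]
        assert coph.loc["A", "C"] == pytest.approx(coph.loc["B", "C"])

    def test_ultrametric_input_reproduced_exactly(self):
        # ((A,B),(C,D)) with merge heights 0.2, 0.4, 0.8
        d = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ])
        labels = list("ABCD")
        dm = pd.DataFrame(d, index=labels, columns=labels)
        coph = _cophenetic_from_newick(upgma_dendrogram(dm))
        np.testing.assert_allclose(coph.loc[labels, labels].to_numpy(), d,
                                   atol=1e-9)

    def test_matches_independent_upgma_on_random_matrix(self):
        rng = np.random.default_rng(8)
        raw = rng.random((5, 5))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        labels = list("ABCDE")
        dm = pd.DataFrame(d, index=labels, columns=labels)
        coph = _cophenetic_from_newick(upgma_dendrogram(dm))
        oracle = _naive_upgma_cophenetic(d, labels)
        np.testing.assert_allclose(coph.loc[labels, labels].to_numpy(),
                                   oracle.to_numpy(), atol=1e-9)


class TestAnosim:
    @staticmethod
    def _random_distances(rng, n):
        raw = rng.random((n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        return pd.DataFrame(d)

    def test_null_centering(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(100):
            d = self._random_distances(rng, 8)
            labels = pd.Series(rng.permutation(["x"] * 4 + ["y"] * 4),
                               index=d.index)
            rs.append(anosim(d, labels, n_permutations=1, seed=0).r)
        # R has sd ~0.2 at n=8; the mean over 100 draws should sit near 0
        assert abs(np.mean(rs)) < 3 * np.std(rs, ddof=1) / 10

    def test_complete_separation_gives_r_one(self):
        d = np.full((6, 6), 0.9)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        dm = pd.DataFrame(d)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=dm.index)
        assert anosim(dm, labels, n_permutations=99, seed=1).r == pytest.approx(1.0)

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        d = self._random_distances(rng, 6)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=d.index)
        res = anosim(d, labels, n_permutations="all", seed=0)

        # independent enumeration: rank distances, compute R per permutation
        dvals = d.to_numpy()
        iu = np.triu_indices(6, 1)
        ranks = np.zeros((6, 6))
        rk = stats.rankdata(dvals[iu])
        ranks[iu] = rk
        ranks.T[iu] = rk

        def r_stat(lab):
            lab = np.asarray(lab)
            same = lab[:, None] == lab[None, :]
            w = ranks[iu][same[iu]].mean()
            b = ranks[iu][~same[iu]].mean()
            return (b - w) / ((6 * 5 / 2) / 2)

        r_obs = r_stat(labels.to_numpy())
        null = [r_stat(p) for p in itertools.permutations(labels)]
        p_expected = np.mean([r >= r_obs - 1e-12 for r in null])
        assert res.r == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(p_expected)

    def test_singleton_group_rejected(self):
        d = self._random_distances(np.random.default_rng(0), 5)
        labels = pd.Series(["a"] * 4 + ["b"], index=d.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(d, labels)


class TestGroupTests:
    def test_constant_values_share_one_letter_everywhere(self, paired_metadata):
        values = pd.Series(1.0, index=list(paired_metadata.samples))
        res = group_tests(values, paired_metadata)
        assert set(res.duncan["letters"]) == {"a"}
        assert (res.ttests["p"] == 1.0).all()

    def test_welch_t_matches_hand_computation(self, paired_metadata):
        bulk = [5.1, 4.9, 5.3]
        rhizo = [6.2, 6.8, 6.5]
        values = {}
        for rep, v in enumerate(bulk, 1):
            values[f"CK-B{rep}"] = v
        for rep, v in enumerate(rhizo, 1):
            values[f"CK-R{rep}"] = v
        # fill other cells with constants so they don't interfere
        for sid in paired_metadata.samples:
            values.setdefault(sid, 1.0)
        res = group_tests(pd.Series(values), paired_metadata)
        row = res.ttests.set_index("treatment").loc["CK"]
        expected = stats.ttest_ind(bulk, rhizo, equal_var=False)
        assert row["t"] == pytest.approx(expected.statistic)
        assert row["p"] == pytest.approx(expected.pvalue)
        assert row["df"] == pytest.approx(expected.df)

    def test_anova_type_one_error_calibration(self):
        rng = np.random.default_rng(0)
        reps, k, n = 1000, 3, 5
        a, b, c = (rng.standard_normal((reps, n)) for _ in range(k))
        pvals = stats.f_oneway(a, b, c, axis=1).pvalue
        rate = (pvals < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_duncan_separates_distant_groups(self):
        rng = np.random.default_rng(1)
        values, groups = {}, {}
        for g, mu in (("lo", 0.0), ("mid", 0.5), ("hi", 10.0)):
            for i in range(4):
                sid = f"{g}{i}"
                values[sid] = mu + 0.1 * rng.standard_normal()
                groups[sid] = g
        letters = duncan_letters(pd.Series(values), pd.Series(groups))
        assert letters["hi"] != letters["lo"]
        assert set(letters["hi"]) & set(letters["mid"]) == set()

    def test_duncan_overlapping_groups_share_a_letter(self):
        values = pd.Series({"a1": 1.0, "a2": 1.1, "b1": 1.05, "b2": 1.15,
                            "c1": 0.95, "c2": 1.2})
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                            "c1": "C", "c2": "C"})
        letters = duncan_letters(values, groups)
        assert len({v for v in letters.values()}) == 1
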