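"""CLR, rarefaction, Hill numbers, distances, PCoA, PERMANOVA, rank-sum."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spikeline import diversity
from spikeline.model import CountTable, DistanceMatrix, ValidationError


def _table(rows, sample_ids=None, sv_ids=None):
    rows = np.atleast_2d(rows)
    return CountTable(
        pd.DataFrame(
            rows,
            index=sample_ids or [f"s{i}" for i in range(rows.shape[0])],
            columns=sv_ids or [f"sv{i}" for i in range(rows.shape[1])],
        )
    )


def _meta(sample_ids, **columns):
    df = pd.DataFrame({"sample_id": sample_ids, "biomass_mass": 1.0, "mc_dose_fraction": 0.0})
    for k, v in columns.items():
        df[k] = v
    return df.set_index("sample_id", drop=False)


class TestCLR:
    def test_uniform_row_maps_to_zeros(self):
        out = diversity.clr_normalize(_table([[5, 5, 5, 5]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_hand_arithmetic_two_parts(self):
        out = diversity.clr_normalize(_table([[1, 3]]), offset=1)
        expected = math.log(2) - (math.log(2) + math.log(4)) / 2
        assert out.iloc[0, 0] == pytest.approx(expected, abs=1e-10)
        assert out.iloc[0, 0] == pytest.approx(-0.3466, abs=5e-5)
        assert out.iloc[0, 1] == pytest.approx(0.3466, abs=5e-5)

    def test_zero_offset_with_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            diversity.clr_normalize(_table([[0, 3]]), offset=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(2, 6), st.integers(2, 8)),
            elements=st.integers(0, 10_000),
        )
    )
    def test_row_means_always_zero(self, counts):
        df = pd.DataFrame(counts)
        df.index = [f"s{i}" for i in range(df.shape[0])]
        df.columns = [f"v{i}" for i in range(df.shape[1])]
        out = diversity.clr_normalize(CountTable(df.abs()))
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-10)

    def test_euclidean_on_clr_approx_scale_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1000, 50_000, size=(4, 20))
        d1 = diversity.distance(diversity.clr_normalize(_table(counts)), "euclidean")
        d2 = diversity.distance(diversity.clr_normalize(_table(counts * 10)), "euclidean")
        assert np.allclose(d1.data, d2.data, rtol=1e-2, atol=1e-3)


class TestRarefy:
    def test_default_depth_is_99pct_of_minimum(self):
        t = _table([[10_195, 0], [20_000, 5_000]])
        assert diversity.default_rarefaction_depth(t) == 10_093

    def test_sample_at_depth_unchanged(self):
        t = _table([[6, 4], [50, 50]])
        out = diversity.rarefy(t, depth=10, seed=0)
        assert list(out.data.loc["s0"]) == [6, 4]
        assert out.totals["s1"] == 10

    def test_shallow_samples_dropped_with_warning(self):
        t = _table([[6, 4], [2, 1]])
        with pytest.warns(UserWarning, match="dropped"):
            out = diversity.rarefy(t, depth=10, seed=0)
        assert out.sample_ids == ["s0"]

    def test_hypergeometric_expectation(self):
        """Mean post-rarefaction count over many seeds matches
        depth × count / total within 3 standard errors."""
        counts = np.array([10, 14, 16])
        t = _table([counts])
        m, total, n_rep = 20, counts.sum(), 1000
        draws = np.array(
            [diversity.rarefy(t, depth=m, seed=s).data.iloc[0].to_numpy() for s in range(n_rep)]
        )
        expected = m * counts / total
        var = m * (counts / total) * (1 - counts / total) * (total - m) / (total - 1)
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_reproducible_from_seed(self):
        t = _table([[100, 200, 300]])
        a = diversity.rarefy(t, depth=50, seed=3)
        b = diversity.rarefy(t, depth=50, seed=3)
        assert a == b


class TestAlpha:
    def test_single_sv(self):
        out = diversity.alpha_diversity(_table([[7]]))
        assert tuple(out.iloc[0]) == (1.0, 0.0, 1.0)

    def test_two_equal_svs(self):
        out = diversity.alpha_diversity(_table([[5, 5]]))
        assert out.iloc[0]["S"] == 2
        assert out.iloc[0]["H"] == pytest.approx(math.log(2))
        assert out.iloc[0]["D2"] == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        out = diversity.alpha_diversity(_table([[10, 10, 20]]))
        assert out.iloc[0]["H"] == pytest.approx(1.0397, abs=1e-4)
        assert out.iloc[0]["D2"] == pytest.approx(2.6667, abs=1e-4)

    def test_empty_sample_gives_null_row(self):
        out = diversity.alpha_diversity(_table([[0, 0], [1, 1]]))
        assert out.iloc[0].isna().all()

    def test_matches_skbio_shannon(self):
        import skbio.diversity.alpha as ska

        counts = np.array([3, 9, 1, 27, 5])
        out = diversity.alpha_diversity(_table([counts]))
        assert out.iloc[0]["H"] == pytest.approx(ska.shannon(counts, base=math.e), rel=1e-12)
        assert out.iloc[0]["D2"] == pytest.approx(ska.enspie(counts), rel=1e-12)


class TestRECurves:
    def test_full_depth_matches_observed_hill_numbers(self):
        counts = np.array([10, 10, 20])
        t = _table([counts])
        curves = diversity.re_curves(t, grid=[40], n_boot=20, seed=0)
        by_q = curves.set_index("q")["estimate"]
        assert by_q[0] == pytest.approx(3.0, abs=1e-10)
        assert by_q[1] == pytest.approx(math.exp(1.0397), abs=1e-3)
        assert by_q[2] == pytest.approx(2.6667, abs=1e-4)

    def test_two_sv_enumeration_oracle(self):
        """Subsample of size 2 from counts [2, 2]: expected richness is
        1 × P(same SV) + 2 × P(different) = (2/6) + 2 × (4/6) = 5/3."""
        t = _table([[2, 2]])
        curves = diversity.re_curves(t, q_set=[0], grid=[2], n_boot=3000, seed=1)
        est = curves["estimate"].iloc[0]
        p_diff = 4 / 6
        sd = math.sqrt(p_diff * (1 - p_diff))
        assert abs(est - 5 / 3) < 3 * sd / math.sqrt(3000)

    def test_richness_curve_non_decreasing(self):
        t = _table([[50, 30, 10, 5, 2, 1]])
        curves = diversity.re_curves(t, q_set=[0], grid=[5, 20, 50, 98], n_boot=100, seed=2)
        est = curves.sort_values("m")["estimate"].to_numpy()
        assert np.all(np.diff(est) >= 0)

    def test_ci_contains_point_estimate(self):
        t = _table([[50, 30, 10, 5, 2, 1]])
        curves = diversity.re_curves(t, grid=[10, 50], n_boot=200, seed=3)
        assert ((curves["ci_low"] <= curves["estimate"]) & (curves["estimate"] <= curves["ci_high"])).all()

    def test_grid_beyond_total_skipped_with_warning(self):
        t = _table([[5, 5]])
        with pytest.warns(UserWarning, match="skipped"):
            curves = diversity.re_curves(t, q_set=[0], grid=[5, 100], n_boot=10, seed=0)
        assert set(curves["m"]) == {5}


class TestDistance:
    def test_identical_samples_distance_zero(self):
        t = _table([[3, 4], [3, 4]])
        d = diversity.distance(t, "bray-curtis")
        assert d.data[0, 1] == 0.0

    def test_disjoint_support_bray_curtis_one(self):
        t = _table([[2, 0], [0, 2]])
        assert diversity.distance(t, "bray-curtis").data[0, 1] == 1.0

    def test_matches_naive_double_loop(self):
        counts = np.array([[5, 0, 3], [1, 1, 1], [0, 9, 2]], dtype=float)
        t = _table(counts.astype(int))
        bc = diversity.distance(t, "bray-curtis").data
        for i, j in itertools.combinations(range(3), 2):
            expected = np.abs(counts[i] - counts[j]).sum() / (counts[i] + counts[j]).sum()
            assert bc[i, j] == pytest.approx(expected, rel=1e-12)
        clr = diversity.clr_normalize(t).to_numpy()
        eu = diversity.distance(diversity.clr_normalize(t), "euclidean").data
        for i, j in itertools.combinations(range(3), 2):
            assert eu[i, j] == pytest.approx(np.sqrt(((clr[i] - clr[j]) ** 2).sum()), rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(np.int64, st.tuples(st.integers(2, 5), st.integers(2, 6)), elements=st.integers(0, 100))
    )
    def test_bray_curtis_bounded_and_symmetric(self, counts):
        counts[0, 0] += 1  # avoid an all-zero table
        d = diversity.distance(_table(counts), "bray-curtis").data
        assert np.all((d >= 0) & (d <= 1 + 1e-12))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestPCoA:
    def test_equilateral_triangle_eigenvalues(self):
        d = 2.0
        dist = DistanceMatrix(["a", "b", "c"], np.array([[0, d, d], [d, 0, d], [d, d, 0]]))
        out = diversity.pcoa(dist)
        assert out["eigenvalues"][:2] == pytest.approx([d**2 / 2, d**2 / 2], abs=1e-10)
        assert out["eigenvalues"][2] == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_sample_identical_coordinates(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 2]])
        from scipy.spatial.distance import pdist, squareform

        dist = DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        out = diversity.pcoa(dist)
        coords = out["coordinates"]
        assert np.allclose(coords.loc["b"], coords.loc["c"], atol=1e-10)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(pts))
        out = diversity.pcoa(DistanceMatrix([str(i) for i in range(6)], dmat))
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dmat**2) @ j
        assert out["eigenvalues"].sum() == pytest.approx(np.trace(b), abs=1e-10)

    def test_matches_skbio_pcoa(self):
        import skbio

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 4))
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(pts))
        ids = [str(i) for i in range(5)]
        ours = diversity.pcoa(DistanceMatrix(ids, dmat))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dmat, ids))
        assert np.allclose(
            np.sort(ours["eigenvalues"])[::-1][:4],
            np.sort(theirs.eigvals.to_numpy())[::-1][:4],
            atol=1e-8,
        )


def _brute_force_one_factor(dmat, labels):
    """Independent one-factor pseudo-F from group sums of squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_total = (dmat**2).sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        sub = dmat[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _dist(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))

    def test_r2_partition_sums_to_one(self):
        dist = self._dist(8, seed=1)
        meta = _meta(dist.sample_ids, grp=["a", "a", "b", "b", "a", "b", "a", "b"],
                     cov=np.arange(8.0))
        res = diversity.permanova(dist, meta, ["grp", "cov"], n_perm=99, seed=0)
        assert res.table["R2"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_matches_independent_brute_force(self):
        """Exact p over all 720 label permutations equals an enumeration
        using the classic group-sum-of-squares pseudo-F formula."""
        dist = self._dist(6, seed=2)
        labels = ["a", "a", "a", "b", "b", "b"]
        meta = _meta(dist.sample_ids, grp=labels)
        res = diversity.permanova(dist, meta, ["grp"], exhaustive=True)
        dmat = dist.data
        f_obs = _brute_force_one_factor(dmat, labels)
        assert res.table.loc["grp", "F"] == pytest.approx(f_obs, rel=1e-10)
        count = 0
        total = 0
        arr = np.asarray(labels)
        for perm in itertools.permutations(range(6)):
            f_p = _brute_force_one_factor(dmat, arr[list(perm)])
            count += f_p >= f_obs - 1e-12
            total += 1
        assert res.table.loc["grp", "p"] == pytest.approx(count / total, abs=1e-12)

    def test_sampled_p_consistent_with_exact(self):
        dist = self._dist(6, seed=3)
        meta = _meta(dist.sample_ids, grp=["a", "a", "a", "b", "b", "b"])
        exact = diversity.permanova(dist, meta, ["grp"], exhaustive=True).table.loc["grp", "p"]
        sampled = diversity.permanova(dist, meta, ["grp"], n_perm=999, seed=0).table.loc["grp", "p"]
        tol = 3 * math.sqrt(exact * (1 - exact) / 999) + 2 / 999
        assert abs(sampled - exact) <= tol

    def test_matches_skbio_pseudo_f(self):
        import skbio

        dist = self._dist(10, seed=4)
        labels = ["a"] * 5 + ["b"] * 5
        meta = _meta(dist.sample_ids, grp=labels)
        res = diversity.permanova(dist, meta, ["grp"], n_perm=99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.data, dist.sample_ids), grouping=labels, permutations=0
        )
        assert res.table.loc["grp", "F"] == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_constant_term_rejected(self):
        dist = self._dist(6)
        meta = _meta(dist.sample_ids, grp=["a"] * 6)
        with pytest.raises(ValidationError, match="grp"):
            diversity.permanova(dist, meta, ["grp"], n_perm=9)

    def test_confounded_term_rejected(self):
        dist = self._dist(6)
        meta = _meta(dist.sample_ids, g1=["a", "a", "a", "b", "b", "b"],
                     g2=["x", "x", "x", "y", "y", "y"])
        with pytest.raises(ValidationError, match="g2"):
            diversity.permanova(dist, meta, ["g1", "g2"], n_perm=9)


class TestCompareAlpha:
    def _alpha(self, values1, values2):
        vals = list(values1) + list(values2)
        table = pd.DataFrame({"S": vals, "H": vals, "D2": vals},
                             index=[f"s{i}" for i in range(len(vals))])
        grouping = pd.Series(
            ["g1"] * len(values1) + ["g2"] * len(values2), index=table.index
        )
        return table, grouping

    def test_identical_groups_p_one(self):
        table, grouping = self._alpha([1, 2, 3], [1, 2, 3])
        assert (diversity.compare_alpha(table, grouping) == 1.0).all()

    def test_separated_groups_exact_p(self):
        table, grouping = self._alpha([1, 2, 3], [4, 5, 6])
        p = diversity.compare_alpha(table, grouping)
        assert p["S"] == pytest.approx(0.1, abs=1e-12)

    def test_matches_scipy_exact(self):
        from scipy.stats import mannwhitneyu

        x, y = [1.2, 3.4, 0.1, 7.7], [2.2, 5.1, 6.3, 9.0, 4.4]
        table, grouping = self._alpha(x, y)
        p = diversity.compare_alpha(table, grouping)["S"]
        expected = mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        table, grouping = self._alpha([1, 5, 2, 8], [3, 9, 11, 4])
        p1 = diversity.compare_alpha(table, grouping)
        p2 = diversity.compare_alpha(np.exp(table / 4), grouping)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_large_groups_match_scipy_asymptotic(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=12)
        table, grouping = self._alpha(x, y)
        p = diversity.compare_alpha(table, grouping)["S"]
        expected = mannwhitneyu(
            x, y, method="asymptotic", use_continuity=False, alternative="two-sided"
        ).pvalue
        assert p == pytest.approx(expected, rel=1e-9)

    def test_more_than_two_groups_rejected(self):
        table, grouping = self._alpha([1, 2], [3, 4])
        grouping.iloc[0] = "g3"
        with pytest.raises(ValidationError):
            diversity.compare_alpha(table, grouping)
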