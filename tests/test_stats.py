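"""Community statistics: Bray-Curtis, PERMANOVA, Storey FDR, differential activity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilvirome import stats, synth


class TestBrayCurtis:
    def test_identical_zero(self):
        assert stats.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_one(self):
        assert stats.bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_worked_example(self):
        assert stats.bray_curtis([2, 0, 1], [0, 2, 1]) == pytest.approx(4 / 6)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            stats.bray_curtis([0, 0], [0, 0])

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import braycurtis

        for _ in range(10):
            x, y = rng.lognormal(size=(2, 20))
            assert stats.bray_curtis(x, y) == pytest.approx(braycurtis(x, y))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=20),
        st.data(),
    )
    def test_bounds_and_symmetry(self, x, data):
        y = data.draw(
            st.lists(st.floats(0, 1e6), min_size=len(x), max_size=len(x))
        )
        if sum(x) + sum(y) == 0:
            return
        d = stats.bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(stats.bray_curtis(y, x))

    def test_matrix_properties(self, rng):
        mat = pd.DataFrame(rng.lognormal(size=(15, 8)))
        d = stats.bray_curtis_matrix(mat)
        assert (d.values == d.values.T).all()
        assert (np.diag(d.values) == 0).all()
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestPermanova:
    def _separated(self, n_per=8):
        # two groups, zero within-group and positive between-group distance;
        # large enough that no permutation re-creates the exact partition
        n = 2 * n_per
        d = np.ones((n, n))
        d[:n_per, :n_per] = 0
        d[n_per:, n_per:] = 0
        np.fill_diagonal(d, 0)
        return d, ["a"] * n_per + ["b"] * n_per

    def test_maximal_separation_min_p(self):
        d, g = self._separated()
        res = stats.permanova(d, g, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r2 > 0.9

    def test_total_ss_permutation_invariant(self, rng):
        d = np.abs(rng.normal(size=(10, 10)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        codes = np.array([0] * 5 + [1] * 5)
        ss1, _ = stats._permanova_ss(d**2, codes, np.array([0, 1]))
        perm = rng.permutation(codes)
        ss2, _ = stats._permanova_ss(d**2, perm, np.array([0, 1]))
        assert ss1 == pytest.approx(ss2)

    def test_matches_skbio_pseudo_f(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.lognormal(size=(12, 10))
        mat = pd.DataFrame(x.T)
        d = stats.bray_curtis_matrix(mat)
        groups = ["a"] * 6 + ["b"] * 6
        ours = stats.permanova(d, groups, n_permutations=99, seed=1)
        theirs = sk_permanova(DistanceMatrix(d.values), groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_seeded_reproducibility(self, rng):
        x = rng.lognormal(size=(12, 10))
        d = stats.bray_curtis_matrix(pd.DataFrame(x.T))
        groups = ["a", "b", "c"] * 4
        r1 = stats.permanova(d, groups, seed=7)
        r2 = stats.permanova(d, groups, seed=7)
        assert r1 == r2

    def test_degenerate_grouping_rejected(self):
        d, _ = self._separated(3)
        with pytest.raises(ValueError):
            stats.permanova(d, ["a"] * 6)
        with pytest.raises(ValueError):
            stats.permanova(d, ["a"] * 5 + ["b"])


class TestStoreyQvalues:
    def test_single_p_one(self):
        assert stats.storey_qvalues([1.0]) == pytest.approx([1.0])

    def test_pi0_one_equals_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        q = stats.storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    def test_matches_naive_qvalue_oracle(self, rng):
        # independent O(m^2) restatement: q_i = min over p_j >= p_i of
        # pi0 * m * p_j / rank(p_j)
        p = np.round(rng.uniform(size=20), 3)
        m = len(p)
        pi0 = min(1.0, (p > 0.5).sum() / (m * 0.5))
        ranks = {pv: (p <= pv).sum() for pv in p}
        expected = [
            min(pi0 * m * pj / ranks[pj] for pj in p if pj >= pi) for pi in p
        ]
        expected = np.minimum(expected, 1.0)
        assert np.allclose(stats.storey_qvalues(p), expected)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = stats.storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.storey_qvalues([])
        with pytest.raises(ValueError):
            stats.storey_qvalues([0.5, 1.2])


def _toy_matrix():
    months = ["Mar"] * 3 + ["May"] * 3
    samples = [f"s{i}" for i in range(6)]
    meta = pd.DataFrame({"month": months, "season": months}, index=samples)
    data = {
        "flat": [5, 5, 5, 5, 5, 5],
        "noisy_null": [4, 6, 5, 5, 4, 6],
        "seasonal": [1, 2, 1, 50, 60, 55],
    }
    return pd.DataFrame(data, index=samples).T, meta


class TestDifferentialActivity:
    def test_zero_variance_excluded(self):
        matrix, meta = _toy_matrix()
        results = stats.differential_activity(matrix, meta)
        assert "flat" not in {r.votu_id for r in results}

    def test_strong_seasonal_flagged_with_peak(self):
        matrix, meta = _toy_matrix()
        results = {r.votu_id: r for r in stats.differential_activity(matrix, meta)}
        r = results["seasonal"]
        assert r.seasonal
        assert r.eta_squared > 0.9
        assert r.peak_month == "May"
        assert any({g1, g2} == {"Mar", "May"} for g1, g2, _ in r.significant_pairs)

    def test_eta_squared_hand_computation(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        # grand mean 3.5; SS_between = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5; SS_total = 17.5
        assert stats._eta_squared(groups) == pytest.approx(13.5 / 17.5)

    def test_single_month_rejected(self):
        matrix, meta = _toy_matrix()
        meta["month"] = "Mar"
        with pytest.raises(ValueError):
            stats.differential_activity(matrix, meta)


class TestZScoreProfiles:
    def _meta(self):
        months = ["Mar", "Mar", "May", "May", "Jun", "Jun", "Sep", "Sep"]
        samples = [f"s{i}" for i in range(8)]
        return pd.DataFrame({"month": months, "season": months}, index=samples), samples

    def test_constant_profile_all_zero(self):
        meta, samples = self._meta()
        matrix = pd.DataFrame([[3.0] * 8], index=["v"], columns=samples)
        prof = stats.zscore_profiles(matrix, meta)["unassigned"][0]
        assert (prof.z_scores == 0).all()

    def test_peak_month_maximal_z(self):
        meta, samples = self._meta()
        matrix = pd.DataFrame([[0, 0, 0, 0, 10, 10, 0, 0]], index=["v"], columns=samples)
        prof = stats.zscore_profiles(matrix, meta)["unassigned"][0]
        assert prof.z_scores.idxmax() == "Jun"
        assert prof.z_scores.sum() == pytest.approx(0.0, abs=1e-9)

    def test_strategy_grouping(self):
        meta, samples = self._meta()
        matrix = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6, 7, 8], [8, 7, 6, 5, 4, 3, 2, 1]],
            index=["v1", "v2"],
            columns=samples,
        )
        grouped = stats.zscore_profiles(matrix, meta, {"v1": "winter-adapted"})
        assert {p.votu_id for p in grouped["winter-adapted"]} == {"v1"}
        assert {p.votu_id for p in grouped["unassigned"]} == {"v2"}


class TestSeasonOccupancy:
    def test_core_and_specific(self):
        samples = ["s1", "s2", "s3", "s4"]
        meta = pd.DataFrame(
            {"season": ["winter", "snowmelt", "spring", "autumn"], "month": list("wxyz")},
            index=samples,
        )
        matrix = pd.DataFrame(
            {"s1": [1, 0, 1], "s2": [2, 3, 0], "s3": [1, 0, 0], "s4": [5, 0, 0]},
            index=["core_v", "snow_v", "winter_v"],
        )
        occ = stats.season_occupancy(matrix, meta)
        assert occ.loc["core_v", "core"]
        assert occ.loc["snow_v", "specific_season"] == "snowmelt"
        assert occ.loc["winter_v", "specific_season"] == "winter"

    def test_planted_occupancy_recovered(self):
        matrix, meta, seasonal = synth.simulate_expression_matrix(
            n_votus=50, samples_per_month=3, seed=4
        )
        occ = stats.season_occupancy(matrix, meta)
        # NB counts at baseline mean 50 are present everywhere: all core
        assert occ["core"].mean() > 0.9
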