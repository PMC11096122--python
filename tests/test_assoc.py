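"""Concordance statistic correctness (against a brute-force Kendall oracle),
permutation calibration, observation filters, BH and size regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitodlp import assoc


def single_stratum(h, y, weight=1.0):
    return pd.DataFrame({"h": h, "y": y, "stratum": "s", "weight": weight})


def kendall_tau_a(h, y):
    """O(n^2) brute-force tau-a: (concordant - discordant) / all pairs."""
    h = np.asarray(h, float)
    y = np.asarray(y, float)
    n = len(h)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (h[i] - h[j]) * (y[i] - y[j])
            conc += s > 0
            disc += s < 0
    return (conc - disc) / (n * (n - 1) / 2)


class TestConcordanceFilters:
    def make(self, h_rows, alt_rows, cn, strata=None):
        cells = [f"c{i}" for i in range(len(cn))]
        het = pd.DataFrame(h_rows, index=cells)
        alt = pd.DataFrame(alt_rows, index=cells)
        cnv = pd.Series(cn, index=cells)
        strata = pd.Series(strata or ["L0"] * len(cn), index=cells)
        return het, alt, cnv, strata

    def test_all_rules_keep_variant(self):
        het, alt, cnv, strata = self.make(
            {"v": [0.1, 0.2, 0.3]}, {"v": [12, 15, 20]}, [100, 200, 300]
        )
        obs = assoc.concordance_filters(het, alt, cnv, strata)
        assert "v" in obs and len(obs["v"]) == 3

    def test_window_shrinks_range_and_drops_variant(self):
        het, alt, cnv, strata = self.make(
            {"v": [0.04, 0.5, 0.96]}, {"v": [50, 50, 50]}, [1, 2, 3]
        )
        obs = assoc.concordance_filters(het, alt, cnv, strata)
        assert "v" not in obs

    def test_window_endpoints_retained(self):
        het, alt, cnv, strata = self.make(
            {"v": [0.05, 0.5, 0.95]}, {"v": [50, 50, 50]}, [1, 2, 3]
        )
        obs = assoc.concordance_filters(het, alt, cnv, strata)
        assert len(obs["v"]) == 3

    def test_min_alt_threshold(self):
        het, alt, cnv, strata = self.make({"v": [0.2, 0.4, 0.6]}, {"v": [9, 9, 9]}, [1, 2, 3])
        assert "v" not in assoc.concordance_filters(het, alt, cnv, strata)

    def test_range_rule_inclusive(self):
        het, alt, cnv, strata = self.make({"v": [0.30, 0.45, 0.45]}, {"v": [50, 50, 50]}, [1, 2, 3])
        assert "v" in assoc.concordance_filters(het, alt, cnv, strata)  # range exactly 0.15

    def test_stratum_weights_are_library_cell_counts(self):
        het, alt, cnv, strata = self.make(
            {"v": [0.2, 0.4, 0.6, 0.8]}, {"v": [50] * 4}, [1, 2, 3, 4],
            strata=["L0", "L0", "L0", "L1"],
        )
        obs = assoc.concordance_filters(het, alt, cnv, strata)["v"]
        assert set(zip(obs["stratum"], obs["weight"])) == {("L0", 3.0), ("L1", 1.0)}


class TestStratifiedConcordance:
    def test_perfect_concordance(self):
        r = assoc.stratified_concordance(single_stratum([1, 2, 3], [1, 2, 3]))
        assert r.c == 1.0 and r.c_scaled == 1.0

    def test_perfect_discordance(self):
        r = assoc.stratified_concordance(single_stratum([1, 2, 3], [3, 2, 1]))
        assert r.c == 0.0 and r.c_scaled == -1.0

    def test_brute_force_pair_count(self):
        # h=(1,2,3,4), y=(1,3,2,4): 6 pairs, 1 discordant -> c = 5/6
        r = assoc.stratified_concordance(single_stratum([1, 2, 3, 4], [1, 3, 2, 4]))
        assert r.c == pytest.approx(5 / 6)
        assert r.c_scaled == pytest.approx(2 / 3)

    def test_z_and_variance_identities(self):
        r = assoc.stratified_concordance(single_stratum([1, 2, 3, 4], [1, 3, 2, 4]))
        assert r.c_scaled == pytest.approx(2 * r.c - 1)
        assert r.z == pytest.approx((r.c - 0.5) / np.sqrt(r.variance))
        n = 4
        expected_var = (2 * (2 * n + 5) / (9 * n * (n - 1))) / 4
        assert r.variance == pytest.approx(expected_var)

    def test_all_strata_degenerate(self):
        obs = pd.DataFrame({"h": [1.0], "y": [1.0], "stratum": ["a"], "weight": [1.0]})
        r = assoc.stratified_concordance(obs)
        assert not r.defined and r.reason == "all_strata_degenerate"

    def test_weighted_combination_of_strata(self):
        obs = pd.concat(
            [
                pd.DataFrame({"h": [1, 2, 3], "y": [1, 2, 3], "stratum": "a", "weight": 3.0}),
                pd.DataFrame({"h": [1, 2, 3], "y": [3, 2, 1], "stratum": "b", "weight": 1.0}),
            ]
        )
        r = assoc.stratified_concordance(obs)
        assert r.c == pytest.approx((3 * 1.0 + 1 * 0.0) / 4)
        assert r.n_strata == 2

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_kendall_tau_a_without_ties(self, seed):
        """Single stratum, no ties: c_scaled equals brute-force tau-a exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        h = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        r = assoc.stratified_concordance(single_stratum(h, y))
        assert r.c_scaled == pytest.approx(kendall_tau_a(h, y), abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.random(15)
        y = rng.random(15)
        base = assoc.stratified_concordance(single_stratum(h, y))
        trans = assoc.stratified_concordance(single_stratum(np.exp(3 * h), y**3 + y))
        assert trans.c == pytest.approx(base.c, abs=1e-12)


class TestPermutationNull:
    def test_extreme_concordance_small_p(self):
        h = np.arange(10, dtype=float)
        p = assoc.permutation_null(single_stratum(h, h), n_perm=999, seed=0)
        assert p <= 0.02

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            assoc.permutation_null(single_stratum([1, 2], [1, 2]), n_perm=10)

    def test_two_observations_coarse_floor(self):
        p = assoc.permutation_null(single_stratum([1.0, 2.0], [1.0, 2.0]), n_perm=100, seed=0)
        assert p >= 0.33

    def test_agrees_with_analytic_p(self):
        rng = np.random.default_rng(1)
        n = 40
        h = rng.random(n)
        y = 0.5 * h + rng.random(n)
        obs = single_stratum(h, y)
        analytic = assoc.stratified_concordance(obs).p
        n_perm = 999
        perm = assoc.permutation_null(obs, n_perm=n_perm, seed=2)
        se = np.sqrt(max(perm, analytic) * (1 - min(perm, analytic)) / n_perm)
        assert abs(perm - analytic) <= max(3 * se, 0.02)


class TestBH:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(assoc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert assoc.bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(assoc.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            assoc.bh_adjust([0.5, 1.5])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        perm = rng.permutation(20)
        q = assoc.bh_adjust(p)
        q_perm = assoc.bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestSizeRegression:
    def make_cells(self, diam, cnv, lib="L0", ploidy=None):
        return pd.DataFrame(
            {
                "library_id": lib,
                "diameter_um": diam,
                "cn": cnv,
                "average_ploidy": ploidy if ploidy is not None else 2.0,
            }
        )

    def test_exact_line_recovered(self):
        d = np.array([10.0, 20.0, 30.0, 40.0])
        out = assoc.size_regression(self.make_cells(d, 24.0 * d))
        row = out.iloc[0]
        assert row["slope"] == pytest.approx(24.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert row["pearson_r"] == pytest.approx(1.0)

    def test_three_collinear_points(self):
        out = assoc.size_regression(self.make_cells([1.0, 2.0, 3.0], [10.0, 20.0, 30.0]))
        row = out.iloc[0]
        assert row["slope"] == pytest.approx(10.0)
        assert 0 < row["p"] <= 1e-6  # collapses to the smallest representable float

    def test_constant_diameter_flagged(self):
        out = assoc.size_regression(self.make_cells([5.0] * 4, [1.0, 2.0, 3.0, 4.0]))
        assert out.iloc[0]["flag"] == "constant_diameter"

    def test_shuffled_diameter_r_centered_at_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        for seed in range(20):
            d = rng.random(50) * 20 + 10
            c = rng.permutation(rng.random(50) * 500)
            rs.append(assoc.size_regression(self.make_cells(d, c)).iloc[0]["pearson_r"])
        assert abs(np.mean(rs)) < 0.1

    def test_bh_across_libraries(self):
        rng = np.random.default_rng(5)
        frames = []
        for lib in range(4):
            d = rng.random(30) * 20 + 10
            c = 24 * d + rng.normal(0, 20, 30)
            frames.append(self.make_cells(d, c, lib=f"L{lib}"))
        out = assoc.size_regression(pd.concat(frames, ignore_index=True))
        assert "q" in out.columns and out["q"].notna().all()
        np.testing.assert_allclose(
            out["q"].to_numpy(), assoc.bh_adjust(out["p"].to_numpy())
        )


def test_type_one_error_calibrated_under_null():
    """Independent h and y in two strata: rejection rate near alpha=0.05."""
    rng = np.random.default_rng(6)
    hits = 0
    reps = 400
    for _ in range(reps):
        n = 40
        obs = pd.DataFrame(
            {
                "h": rng.random(n),
                "y": rng.random(n),
                "stratum": np.repeat(["a", "b"], n // 2),
                "weight": np.repeat([20.0, 20.0], n // 2),
            }
        )
        if assoc.stratified_concordance(obs).p < 0.05:
            hits += 1
    rate = hits / reps
    assert 0.02 <= rate <= 0.08
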