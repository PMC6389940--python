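"""Growth curves, AUC/MS/ECS, the mid-parent d statistic and U tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridpaint.growth import (
    GrowthCurve,
    build_growth_curve,
    compare_hybrid_to_parents,
    compute_growth_metrics,
    mann_whitney_u,
    midparent_d,
)
from hybridpaint.simdata import SimConfig, logistic_true_metrics, simulate_growth_dataset


def _raw(times, sizes_by_rep, flags=None):
    rows = []
    for rep, sizes in enumerate(sizes_by_rep):
        for t, s in zip(times, sizes):
            rows.append({"time_h": t, "replicate": rep, "colony_size": s,
                         "flag": False if flags is None else flags(rep, t)})
    return pd.DataFrame(rows)


class TestBuildGrowthCurve:
    def test_identical_replicates_equal_normalized_log2(self):
        times = [0, 4, 8, 12, 16]
        series = [10, 20, 40, 80, 160]
        curve = build_growth_curve(_raw(times, [series] * 3))
        expected = np.log2(series) - np.log2(series[0])
        assert np.allclose(curve.values, expected)

    def test_zero_size_excluded_from_that_time_only(self):
        times = [0, 4, 8, 12, 16]
        good = [10, 20, 40, 80, 160]
        bad = [10, 20, 0, 80, 160]  # zero at t=8 ignored in that median
        curve = build_growth_curve(_raw(times, [good, good, bad]))
        assert curve.values[2] == pytest.approx(np.log2(40) - np.log2(10))
        assert curve.n_replicates_per_point[2] == 2

    def test_truncation_and_min_points(self):
        times = list(range(0, 100, 10))
        series = [10 * 2 ** (t / 20) for t in times]
        curve = build_growth_curve(_raw(times, [series]), truncate_at=80.0)
        assert curve.times.max() == 80.0
        with pytest.raises(ValueError, match="usable time points"):
            build_growth_curve(_raw(times, [series]), truncate_at=30.0)

    def test_median_curve_beats_single_replicates(self):
        # replicate median is a better estimate of the noiseless curve
        cfg = SimConfig(seed=11, n_strains_per_lineage=1, n_replicates=12,
                        growth_noise_sd=0.15)
        wins = 0
        n_runs = 40
        for i in range(n_runs):
            cfg = SimConfig(seed=100 + i, n_strains_per_lineage=1,
                            n_replicates=12, growth_noise_sd=0.15)
            raw, _ = simulate_growth_dataset(cfg, {("L", "c"): (4.0, 0.15, 40.0)})
            sub = raw[raw.strain == "L_1"]
            t = np.sort(sub["time_h"].unique())
            noiseless = 4.0 / (1 + np.exp(-0.15 * (t - 40.0)))
            noiseless -= noiseless[0]
            curve = build_growth_curve(sub)
            med_rmse = np.sqrt(np.mean((curve.values - noiseless) ** 2))
            rep0 = sub[sub.replicate == 0].sort_values("time_h")
            v = np.log2(rep0["colony_size"].to_numpy())
            v -= v[0]
            rep_rmse = np.sqrt(np.mean((v - noiseless) ** 2))
            wins += med_rmse < rep_rmse
        assert wins >= int(0.75 * n_runs)


class TestGrowthMetrics:
    def test_linear_curve_closed_forms(self):
        m, T = 0.5, 9.0
        t = np.arange(0.0, T + 1, 1.0)
        curve = GrowthCurve("s", "c", t, m * t, np.ones(len(t)))
        res = compute_growth_metrics(curve)
        assert res.AUC == pytest.approx(m * T**2 / 2, rel=1e-9)
        assert res.MS == pytest.approx(m, rel=1e-12)
        assert res.ECS == pytest.approx(m * T, rel=1e-12)

    def test_constant_zero_curve_degenerate(self):
        t = np.arange(0.0, 10.0, 1.0)
        curve = GrowthCurve("s", "c", t, np.zeros(len(t)), np.ones(len(t)))
        res = compute_growth_metrics(curve)
        assert res.AUC == 0.0 and res.ECS == 0.0 and res.MS is None

    def test_noiseless_logistic_max_slope_within_five_percent(self):
        K, r, tm = 4.0, 0.2, 40.0
        t = np.arange(0.0, 81.0, 1.0)
        y = K / (1 + np.exp(-r * (t - tm)))
        y -= y[0]
        curve = GrowthCurve("s", "c", t, y, np.ones(len(t)))
        res = compute_growth_metrics(curve)
        truth = logistic_true_metrics(K, r, tm, t)
        assert res.MS == pytest.approx(truth["MS"], rel=0.05)
        assert res.AUC == pytest.approx(truth["AUC"], rel=0.01)
        assert res.ECS == pytest.approx(truth["ECS"], rel=1e-9)

    def test_auc_additive_over_split(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 20.0, 1.0)
        y = np.cumsum(rng.uniform(0, 0.5, len(t)))
        y -= y[0]
        curve = GrowthCurve("s", "c", t, y, np.ones(len(t)))
        from scipy.interpolate import make_smoothing_spline
        spline = make_smoothing_spline(t, y)
        full = spline.integrate(t[0], t[-1])
        split = spline.integrate(t[0], 7.5) + spline.integrate(7.5, t[-1])
        assert full == pytest.approx(split, abs=1e-6)


class TestMidParentD:
    def test_parent_median_maps_to_plus_minus_one(self):
        low = [1.0, 2.0, 3.0]
        high = [7.0, 8.0, 9.0]
        assert midparent_d(2.0, low, high).d == pytest.approx(-1.0)
        assert midparent_d(8.0, low, high).d == pytest.approx(1.0)

    def test_midpoint_maps_to_zero(self):
        assert midparent_d(5.0, [1, 2, 3], [7, 8, 9]).d == pytest.approx(0.0)

    def test_transgressive_value(self):
        # med(P1)=10, med(P2)=20, x=25 -> d = +2
        assert midparent_d(25.0, [10], [20]).d == pytest.approx(2.0)

    def test_invariant_under_parent_swap(self, rng):
        # the half-difference denominator carries an absolute value, so the
        # sign of d tracks the larger-median parent, not the argument order
        p1 = rng.normal(0, 1, 9)
        p2 = rng.normal(3, 1, 9)
        x = float(rng.normal(1.5, 1))
        assert midparent_d(x, p1, p2).d == pytest.approx(midparent_d(x, p2, p1).d)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.01, 100))
    def test_affine_invariance(self, shift, scale):
        p1, p2, x = [1.0, 2.0, 3.0], [7.0, 8.0, 9.0], 4.0
        d0 = midparent_d(x, p1, p2).d
        d1 = midparent_d(
            x * scale + shift,
            [v * scale + shift for v in p1],
            [v * scale + shift for v in p2],
        ).d
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_equal_parent_medians_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            midparent_d(1.0, [5.0], [5.0])


def _exact_p_enumeration(x, y, alternative):
    """Full enumeration over all C(n+m, n) group assignments (oracle)."""
    combined = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(combined)) + 1
    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2
    u_obs = u_of(range(n))
    us = [u_of(idx) for idx in itertools.combinations(range(len(combined)), n)]
    us = np.array(us)
    if alternative == "less":
        return float(np.mean(us <= u_obs))
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return float(min(1.0, 2 * min(lo, hi)))


class TestMannWhitney:
    def test_exact_example_one_in_twenty(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p == pytest.approx(0.05)
        assert res.method == "exact"

    def test_identical_samples_two_sided_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3], alternative="two_sided")
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_exact_branch_matches_full_enumeration(self, alternative, rng):
        for _ in range(10):
            n, m = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            res = mann_whitney_u(x, y, alternative=alternative)
            assert res.method == "exact"
            oracle = _exact_p_enumeration(x, y, alternative.replace("_", "-")
                                          if alternative != "two_sided" else "two-sided")
            assert res.p == pytest.approx(oracle, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 8)
        exact = mann_whitney_u(x, y, alternative="less").p
        from scipy import stats
        approx = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert abs(exact - approx) < 0.01


class TestCompareHybridToParents:
    def _table(self, hyb, p1, p2):
        rows = []
        for lin, vals in (("H", hyb), ("P1", p1), ("P2", p2)):
            for i, v in enumerate(vals):
                rows.append({"lineage": lin, "condition": f"c{i % 2}", "d": v})
        return pd.DataFrame(rows)

    def test_intermediate_hybrid_rejects_both_sides(self, rng):
        hyb = rng.normal(0.0, 0.1, 13)
        p1 = rng.normal(-1.0, 0.1, 13)
        p2 = rng.normal(1.0, 0.1, 13)
        table, _ = compare_hybrid_to_parents(self._table(hyb, p1, p2), "H", ("P1", "P2"))
        assert (table["p"] < 0.05).all()
        assert set(table["alternative"]) == {"greater", "less"}

    def test_hybrid_matching_one_parent_not_significant(self, rng):
        p1 = rng.normal(-1.0, 0.1, 13)
        hyb = rng.normal(-1.0, 0.1, 13)
        p2 = rng.normal(1.0, 0.1, 13)
        table, _ = compare_hybrid_to_parents(self._table(hyb, p1, p2), "H", ("P1", "P2"))
        low_row = table[table["alternative"] == "greater"].iloc[0]
        assert low_row["p"] > 0.05

    def test_transgressive_condition_flagged(self):
        df = pd.DataFrame(
            [{"lineage": "H", "condition": "mannose", "d": 2.0},
             {"lineage": "P1", "condition": "mannose", "d": -1.0},
             {"lineage": "P2", "condition": "mannose", "d": 1.0},
             {"lineage": "H", "condition": "glucose", "d": 0.0},
             {"lineage": "P1", "condition": "glucose", "d": -1.0},
             {"lineage": "P2", "condition": "glucose", "d": 1.0}]
        )
        _table, transgressive = compare_hybrid_to_parents(df, "H", ("P1", "P2"))
        assert transgressive == ["mannose"]

    def test_missing_lineage_rejected(self):
        df = pd.DataFrame([{"lineage": "H", "condition": "c", "d": 0.0}])
        with pytest.raises(ValueError, match="missing"):
            compare_hybrid_to_parents(df, "H", ("P1", "P2"))


class TestPowerOfIntermediateHybridDetection:
    def test_simulated_intermediate_hybrid_detected_in_most_seeds(self):
        # true d = 0, noise 0.2, n = 13 per group: both one-sided tests
        # significant in >= 90/100 seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            hyb = rng.normal(0.0, 0.2, 13)
            p1 = rng.normal(-1.0, 0.2, 13)
            p2 = rng.normal(1.0, 0.2, 13)
            a = mann_whitney_u(hyb, p1, alternative="greater").p
            b = mann_whitney_u(hyb, p2, alternative="less").p
            hits += (a < 0.05) and (b < 0.05)
        assert hits >= 90
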