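"""ROI trimming, gated tests, FDR adjustment, regressions, laterality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from oxibold import (
    bh_adjust,
    chi_square_2x2,
    compare_groups,
    compare_region_to_global,
    fit_age_model,
    laterality,
    pearson_age_corr,
    prepare_masks,
    roi_summary,
    run_stats_battery,
    simulate_cohort,
    volumetrics,
)
from oxibold.cohort import consistent_anchor_config, default_cohort_config
from oxibold.config import CohortConfig, RegionCohortParams
from oxibold.regions import REPORT_REGIONS


def bh_bruteforce(p):
    """O(m^2) direct evaluation of the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestRoiSummary:
    def test_trimming_one_to_hundred(self):
        vals = np.arange(1.0, 101.0)
        s = roi_summary(vals, np.ones(100, bool))
        # P5 = 5.95, P95 = 95.05 under linear-interpolation percentiles:
        # 6..95 retained
        assert s.n_kept == 90
        assert s.mean == pytest.approx(50.5)

    def test_plausibility_filter(self):
        vals = np.array([-1.0, 0.0, np.inf, 5.0])
        s = roi_summary(vals, np.ones(4, bool))
        assert s.n_kept == 1
        assert s.mean == 5.0
        assert s.low_confidence

    def test_constant_values_all_retained(self):
        vals = np.full(50, 3.3)
        s = roi_summary(vals, np.ones(50, bool))
        assert s.n_kept == 50
        assert s.mean == pytest.approx(3.3)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_retention_fraction_for_large_rois(self, rng):
        # distinct-valued plausible voxels: between 89 % and 91 % retained
        for n in (100, 500, 2000):
            vals = rng.uniform(1, 100, n)
            s = roi_summary(vals, np.ones(n, bool))
            assert 0.89 <= s.n_kept / n <= 0.91

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_summary(np.ones(5), np.zeros(5, bool))


class TestPrepareMasks:
    def test_identity_when_grids_match(self, phantom):
        masks, warns = prepare_masks(phantom.labels, phantom.labels.shape,
                                     erode_wm=False)
        np.testing.assert_array_equal(masks["hc"], phantom.labels == 5)
        assert warns == []

    def test_wm_cube_erosion_leaves_center(self):
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[1:4, 1:4, 1:4] = 3  # 3x3x3 solid WM cube
        masks, _ = prepare_masks(labels, erode_wm=True)
        assert masks["wm"].sum() == 1
        assert masks["wm"][2, 2, 2]

    def test_downsampling_uniform_block(self):
        labels = np.full((8, 8, 8), 2, dtype=np.int16)
        masks, _ = prepare_masks(labels, target_shape=(4, 4, 4),
                                 erode_wm=False)
        assert masks["gm"].shape == (4, 4, 4)
        assert masks["gm"].all()

    def test_unknown_labels_warned(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = 99
        _, warns = prepare_masks(labels, erode_wm=False)
        assert any("99" in w for w in warns)

    def test_composite_hierarchy(self, phantom):
        masks, _ = prepare_masks(phantom.labels, erode_wm=False)
        assert (masks["hc"] & ~masks["mtl"]).sum() == 0
        assert (masks["ag"] & ~masks["mtl"]).sum() == 0


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res.test == "t"
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_separated_normal_groups_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 19)
        res = compare_groups(a, b)
        assert res.test == "t"
        assert res.p < 0.05
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_nonnormal_group_routes_to_mann_whitney(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 15)
        b = rng.exponential(1.0, 19) ** 3  # strongly non-normal
        assert sps.shapiro(b).pvalue < 0.05  # gate fixture verified
        res = compare_groups(a, b)
        assert res.test == "mann-whitney"
        assert res.normal_gate[1] is False

    def test_degenerate_zero_variance(self):
        res = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p == 1.0
        assert "degenerate" in res.flag

    def test_type_one_error_calibration(self):
        # 2000 null replicates (n = 15 vs 19, normal): rejection rate at
        # alpha 0.05 stays within [0.035, 0.065]
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 19)
            rejections += compare_groups(a, b).p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065


class TestCompareRegionToGlobal:
    def test_identical_region_and_global(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_region_to_global(v, v)
        assert res.p == 1.0
        assert res.mean_diff == 0.0

    def test_constant_shift_detected(self, rng):
        g = rng.normal(40, 3, 15)
        r = g + 2.0 + rng.normal(0, 0.05, 15)
        res = compare_region_to_global(r, g)
        assert res.mean_diff == pytest.approx(2.0, abs=0.1)
        assert res.p < 0.001
        assert res.effect_size > 5

    def test_sign_flip_antisymmetry(self, rng):
        g = rng.normal(40, 3, 12)
        r = g + rng.normal(1, 0.5, 12)
        a = compare_region_to_global(r, g)
        b = compare_region_to_global(2 * g - r, g)  # flips d = r - g
        assert b.mean_diff == pytest.approx(-a.mean_diff)
        assert b.effect_size == pytest.approx(-a.effect_size)
        assert b.p == pytest.approx(a.p)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 21)
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p),
                                       atol=1e-12)

    def test_order_preservation_and_dominance(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order_p = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order_p]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_bruteforce_equivalence_property(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


class TestFitAgeModel:
    def _frame(self, n, slope, resid_sd, rng):
        age = rng.uniform(20, 90, n)
        sex = rng.integers(0, 2, n).astype(float)
        vol = rng.normal(80, 2, n)
        y = 30 + slope * age + resid_sd * rng.standard_normal(n)
        return pd.DataFrame({"age_years": age, "sex": sex, "norm_volume": vol,
                             "metric": y})

    def test_exact_linear_interpolation(self, rng):
        df = self._frame(40, 0.15, 0.0, rng)
        res = fit_age_model(df, "metric")
        assert res.params["age_years"] == pytest.approx(0.150, abs=1e-10)
        assert res.se["age_years"] == pytest.approx(0.0, abs=1e-8)

    def test_generative_slope_recovery(self):
        cfg = consistent_anchor_config(seed=5, n_young=100, n_old=100)
        df = simulate_cohort(cfg)
        icv = df.gm_volume_ml + df.wm_volume_ml + df.csf_volume_ml
        df["norm_volume"] = 100 * (df.gm_volume_ml + df.wm_volume_ml) / icv
        res = fit_age_model(df, "wb_oef")
        lo, hi = res.ci["age_years"]
        assert lo <= 0.150 <= hi

    def test_univariate_std_beta_equals_pearson_r(self, rng):
        df = self._frame(60, 0.1, 3.0, rng)
        res = fit_age_model(df, "metric", covariates=("age_years",))
        r, _ = pearson_age_corr(df.age_years, df.metric)
        assert res.std_beta["age_years"] == pytest.approx(r, abs=1e-12)

    def test_collinear_design_rejected(self, rng):
        df = self._frame(30, 0.1, 1.0, rng)
        df["norm_volume"] = 2 * df["age_years"]
        with pytest.raises(ValueError, match="collinear"):
            fit_age_model(df, "metric")

    def test_ci_coverage_of_generative_slope(self):
        # 20 seeded replicates at n = 200: >= 90 % of nominal 95 % CIs
        # contain the generating slope
        hits = 0
        for seed in range(20):
            cfg = consistent_anchor_config(seed=seed, n_young=100, n_old=100)
            df = simulate_cohort(cfg)
            icv = df.gm_volume_ml + df.wm_volume_ml + df.csf_volume_ml
            df["norm_volume"] = 100 * (df.gm_volume_ml + df.wm_volume_ml) / icv
            res = fit_age_model(df, "wb_oef")
            lo, hi = res.ci["age_years"]
            hits += lo <= 0.150 <= hi
        assert hits >= 18


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_age_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_age_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_value_against_permutation_oracle(self):
        rng = np.random.default_rng(14)
        n = 20
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        r, p = pearson_age_corr(x, y)
        assert 0.2 <= r <= 0.9
        perm = np.zeros(10000)
        for i in range(10000):
            perm[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = np.mean(np.abs(perm) >= abs(r))
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_age_corr(np.ones(5), np.arange(5.0))


class TestLaterality:
    def test_symmetric_subjects(self):
        v = np.array([10.0, 12.0, 9.0, 11.0])
        res = laterality(v, v)
        assert res.mean_li == 0.0
        assert res.p == 1.0

    def test_worked_index(self):
        res = laterality(np.full(5, 11.0), np.full(5, 9.0))
        assert res.mean_li == pytest.approx(0.1)

    def test_swap_antisymmetry(self, rng):
        r = rng.normal(10, 1, 15)
        l = rng.normal(10, 1, 15)
        a = laterality(r, l)
        b = laterality(l, r)
        assert b.mean_li == pytest.approx(-a.mean_li)
        assert b.p == pytest.approx(a.p)

    def test_zero_denominator_excluded(self):
        res = laterality(np.array([1.0, 0.0, 2.0, 1.5]),
                         np.array([1.0, 0.0, 1.8, 1.4]))
        assert res.n_excluded == 1


class TestVolumetrics:
    def test_reference_normalization(self):
        out = volumetrics(685.2, 493.9, 300.0)
        assert out["icv_ml"] == pytest.approx(1479.1)
        assert out["gm_pct_icv"] == pytest.approx(46.33, abs=0.01)

    def test_no_csf_makes_wb_the_icv(self):
        out = volumetrics(600.0, 400.0, 0.0)
        assert out["wb_pct_icv"] == pytest.approx(100.0)

    def test_scale_invariance(self):
        a = volumetrics(685.2, 493.9, 300.0, {"hc": 8.6})
        b = volumetrics(2 * 685.2, 2 * 493.9, 2 * 300.0, {"hc": 2 * 8.6})
        for key in a:
            if key.endswith("_ml"):
                continue
            assert a[key] == pytest.approx(b[key])

    def test_zero_icv_rejected(self):
        with pytest.raises(ValueError):
            volumetrics(0.0, 0.0, 0.0)


class TestChiSquare:
    def test_balanced_table(self):
        res = chi_square_2x2(np.array([[10, 10], [10, 10]]))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_study_sex_table(self):
        # 11/4 males/females young vs 14/5 old
        res = chi_square_2x2(np.array([[11, 4], [14, 5]]))
        assert res.p == pytest.approx(0.982, abs=5e-4)
        assert res.statistic == pytest.approx(0.001, abs=5e-4)

    def test_perfect_association(self):
        res = chi_square_2x2(np.array([[20, 0], [0, 20]]))
        assert res.statistic == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[5, 0], [7, 0]]))


class TestBattery:
    def test_report_shapes(self):
        df = simulate_cohort(default_cohort_config(seed=1))
        rep = run_stats_battery(df)
        assert len(rep["group"]) == 3 * 11  # 3 metric families x 11 regions
        assert len(rep["region_vs_global"]) == 3 * 2 * 10
        assert len(rep["regression"]) == 3 * 11
        assert set(rep["group"].columns) >= {"family", "region", "test", "p", "q"}

    def test_separated_groups_all_significant(self):
        # zero residual noise and distinct group anchors: every OEF group
        # comparison significant before and after BH
        base = default_cohort_config(seed=2)
        regions = {
            k: RegionCohortParams(**{**v.__dict__, "oef_sd_young": 1e-6,
                                     "oef_sd_old": 1e-6,
                                     "cbf_sd_young": 1e-6,
                                     "cbf_sd_old": 1e-6})
            for k, v in base.regions.items()
        }
        cfg = CohortConfig(regions=regions, volumes=base.volumes, seed=2)
        rep = run_stats_battery(simulate_cohort(cfg))
        oef = rep["group"][rep["group"].family == "oef"]
        assert (oef.p < 0.05).all()
        assert (oef.q < 0.05).all()

    def test_null_cohort_fdr_control(self):
        # identical groups, no age effect: the fraction of replicates with
        # any BH-significant OEF comparison is controlled at ~5 %
        base = default_cohort_config()
        regions = {
            k: RegionCohortParams(
                oef_anchor_young=35.0, oef_anchor_old=35.0,
                oef_sd_young=4.0, oef_sd_old=4.0, oef_slope=0.0,
                cbf_anchor_young=50.0, cbf_anchor_old=50.0,
                cbf_sd_young=8.0, cbf_sd_old=8.0, cbf_slope=0.0)
            for k in REPORT_REGIONS
        }
        n_rep, famwise = 200, 0
        for seed in range(n_rep):
            cfg = CohortConfig(regions=regions, volumes=base.volumes,
                               seed=seed)
            df = simulate_cohort(cfg)
            ps = [compare_groups(df[df.group == "young"][f"{r}_oef"],
                                 df[df.group == "old"][f"{r}_oef"]).p
                  for r in REPORT_REGIONS]
            famwise += (bh_adjust(ps) < 0.05).any()
        # expected <= 0.05; allow two binomial standard errors
        assert famwise / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_missing_region_column_named(self):
        df = simulate_cohort(default_cohort_config(seed=1))
        with pytest.raises(ValueError, match="hc_oef"):
            run_stats_battery(df.drop(columns=["hc_oef"]))
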