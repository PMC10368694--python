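"""Growth-curve analytics: caliper formula, model fitting, agreement stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mousecbct.growth import (
    CaliperRecord,
    GrowthCurve,
    GrowthParams,
    TumorGrowthModel,
    bland_altman,
    caliper_residual_analysis,
    caliper_volume,
    correlations,
    curves_from_records,
    curves_from_table,
    eval_growth_model,
    fit_growth_model,
    growth_rates,
    match_pairs,
    read_caliper_csv,
    spline_mean_volume,
    write_volumes_csv,
    zero_volume_crosstab,
)
from mousecbct.phantom import make_growth_dataset


class TestCaliperVolume:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(10.0, 6.0, 180.0), (6.0, 10.0, 180.0), (4.0, 4.0, 32.0)],
    )
    def test_half_long_short_squared(self, m1, m2, expected):
        assert caliper_volume(m1, m2) == pytest.approx(expected)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            caliper_volume(-1.0, 5.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        m1=st.floats(0.1, 30.0),
        m2=st.floats(0.1, 30.0),
        s=st.floats(0.1, 10.0),
    )
    def test_scale_cubic_and_order_invariant(self, m1, m2, s):
        v = caliper_volume(m1, m2)
        assert caliper_volume(m2, m1) == pytest.approx(v)
        assert caliper_volume(s * m1, s * m2) == pytest.approx(s**3 * v, rel=1e-9)

    def test_record_normalizes_long_short(self):
        rec = CaliperRecord("m1", 10.0, 4.0, 9.0)
        assert rec.d_long_mm == 9.0 and rec.d_short_mm == 4.0
        assert rec.volume_mm3() == pytest.approx(0.5 * 9.0 * 16.0)


class TestEvalGrowthModel:
    P = GrowthParams(a=80.0, b=11.0, c=6.0, d=300.0, f=0.3, g=25.0, h=10.0)

    def test_early_time_limit_is_d_plus_h(self):
        v = eval_growth_model(self.P, -1e6)
        assert v == pytest.approx(self.P.d + self.P.h)

    def test_value_at_coincident_peak_and_midpoint(self):
        p = GrowthParams(a=80.0, b=25.0, c=6.0, d=300.0, f=0.3, g=25.0, h=10.0)
        assert eval_growth_model(p, 25.0) == pytest.approx(80.0 + 1.5 * 300.0 + 10.0)

    def test_zero_amplitudes_give_constant(self):
        p = GrowthParams(a=0.0, b=11.0, c=6.0, d=0.0, f=0.3, g=25.0, h=7.0)
        t = np.linspace(0, 60, 20)
        assert np.allclose(eval_growth_model(p, t), 7.0)

    def test_drop_extra_d_changes_plateau(self):
        late = 1e6
        assert eval_growth_model(self.P, late) == pytest.approx(
            2 * self.P.d + self.P.h
        )
        assert eval_growth_model(self.P, late, drop_extra_d=True) == pytest.approx(
            self.P.d + self.P.h
        )

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(1.0, 1.0, 0.0, 1.0, 0.1, 1.0, 0.0)


class TestFitGrowthModel:
    def test_noiseless_parameter_recovery(self):
        truth = GrowthParams(a=90.0, b=11.5, c=6.0, d=320.0, f=0.35, g=26.0, h=-320.0)
        days = np.linspace(4, 46, 15)
        curve = GrowthCurve("m1", "ct", days, eval_growth_model(truth, days))
        fit = fit_growth_model(curve, rt_day=8.0)
        p = fit.params
        assert abs(p.a - truth.a) / truth.a < 0.01
        assert abs(p.d - truth.d) / truth.d < 0.01
        assert abs(p.h - truth.h) / abs(truth.h) < 0.01
        assert abs(p.g - truth.g) < 0.5
        assert fit.residual_rms < 1.0

    def test_noisy_recovery_median_errors(self):
        rng = np.random.default_rng(0)
        truth = GrowthParams(a=70.0, b=11.0, c=6.0, d=300.0, f=0.3, g=25.0, h=-300.0)
        days = np.linspace(4, 46, 15)
        clean = eval_growth_model(truth, days)
        g_err, f_err = [], []
        for _ in range(20):
            noisy = np.maximum(clean * (1 + rng.normal(0, 0.10, len(days))), 0.0)
            fit = fit_growth_model(GrowthCurve("m", "ct", days, noisy), rt_day=8.0)
            g_err.append(abs(fit.params.g - truth.g))
            f_err.append(abs(fit.params.f - truth.f) / truth.f)
        assert np.median(g_err) <= 1.0
        assert np.median(f_err) <= 0.20

    def test_flat_zero_curve_flags_degenerate(self):
        days = np.arange(10, dtype=float)
        fit = fit_growth_model(GrowthCurve("m", "ct", days, np.zeros(10)), rt_day=2.0)
        assert fit.degenerate
        assert fit.params.a == 0.0 and fit.params.d == 0.0

    def test_model_results_summary_and_predict(self):
        truth = GrowthParams(a=90.0, b=11.5, c=6.0, d=320.0, f=0.35, g=26.0, h=-320.0)
        days = np.linspace(4, 46, 15)
        model = TumorGrowthModel(days, eval_growth_model(truth, days), rt_day=8.0)
        res = model.fit()
        assert "regrowth" in res.summary()
        assert np.allclose(res.predict(days), model.volumes, atol=1.0)
        assert len(res.residuals) == 15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TumorGrowthModel(np.arange(5.0), np.arange(5.0), rt_day=2.0)


class TestSplineMeanVolume:
    def test_constant_curve_is_exact(self):
        days = np.arange(0.0, 31.0, 3.0)
        curve = GrowthCurve("m", "ct", days, np.full(len(days), 100.0))
        assert spline_mean_volume(curve) == pytest.approx(100.0)

    def test_linear_curve_mean_is_midpoint(self):
        days = np.arange(0.0, 31.0, 2.0)
        curve = GrowthCurve("m", "ct", days, days.copy())
        assert spline_mean_volume(curve, 8.0, 20.0) == pytest.approx(14.0)

    def test_model_curve_close_to_direct_mean(self):
        p = GrowthParams(a=80.0, b=11.0, c=6.0, d=300.0, f=0.3, g=25.0, h=-300.0)
        days = np.arange(2.0, 41.0, 2.0)
        curve = GrowthCurve("m", "ct", days, eval_growth_model(p, days))
        direct = np.mean(eval_growth_model(p, np.linspace(8, 20, 10)))
        assert spline_mean_volume(curve) == pytest.approx(direct, rel=0.02)

    def test_insufficient_span_rejected(self):
        curve = GrowthCurve("m", "ct", np.array([10.0, 12.0, 14.0]), np.ones(3))
        with pytest.raises(ValueError):
            spline_mean_volume(curve, 8.0, 20.0)


class TestGrowthRates:
    def test_simple_rate_at_midpoint(self):
        curve = GrowthCurve("m", "ct", np.array([0.0, 2.0]), np.array([0.0, 10.0]))
        mid, rates = growth_rates(curve)
        assert mid == pytest.approx([1.0]) and rates == pytest.approx([5.0])

    def test_constant_curve_zero_rates(self):
        curve = GrowthCurve("m", "ct", np.arange(5.0), np.full(5, 7.0))
        _, rates = growth_rates(curve)
        assert np.allclose(rates, 0.0)

    def test_shrinking_curve_keeps_negative_sign(self):
        curve = GrowthCurve("m", "ct", np.arange(4.0), np.array([40.0, 30.0, 20.0, 5.0]))
        _, rates = growth_rates(curve)
        assert np.all(rates < 0)


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlations(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(1, 3, 12)
        res = correlations(x, x**3)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.pearson_r < 1.0

    def test_matches_textbook_formulas(self):
        x = np.array([1.2, 3.4, 2.2, 5.6, 4.4, 7.1, 0.3, 6.6, 5.0, 2.9])
        y = np.array([2.0, 3.1, 1.8, 6.0, 3.9, 6.5, 1.0, 5.8, 5.2, 2.5])
        res = correlations(x, y)
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.pearson_r == pytest.approx(r_direct, abs=1e-12)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        rho_direct = ((rx - rx.mean()) * (ry - ry.mean())).sum() / np.sqrt(
            ((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum()
        )
        assert res.spearman_rho == pytest.approx(rho_direct, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = correlations(x, y).spearman_rho
        assert correlations(np.exp(x), y).spearman_rho == pytest.approx(base, abs=1e-12)

    def test_constant_input_flagged_undefined(self):
        res = correlations(np.ones(5), np.arange(5.0))
        assert res.undefined


class TestResidualAnalysis:
    def test_exact_cubic_relation_gives_zero_residuals(self):
        days = np.arange(4.0, 40.0, 3.0)
        rng = np.random.default_rng(1)
        ct_curves, cal_curves = [], []
        for m in range(4):
            ct = np.abs(rng.normal(100, 40, len(days)))
            cal = 0.001 * ct**3 + 0.2 * ct + 5.0
            ct_curves.append(GrowthCurve(f"m{m}", "ct", days, ct))
            cal_curves.append(GrowthCurve(f"m{m}", "caliper", days, cal))
        res = caliper_residual_analysis(cal_curves, ct_curves, smooth_predictor=False)
        assert np.abs(res.residuals["residual"]).max() < 1e-6
        assert res.correlation is None or res.correlation.undefined

    def test_contextual_bias_detected(self):
        rs = []
        for seed in (5, 6, 7):
            ds = make_growth_dataset(n_mice=20, noise_sigma=0.10, seed=seed,
                                     contextual_bias=0.4)
            rs.append(caliper_residual_analysis(ds.caliper, ds.ct).correlation.pearson_r)
        assert np.median(rs) > 0.5

    def test_no_bias_gives_weak_correlation(self):
        # judge the typical (median over seeds) magnitude, not a single draw
        rs = []
        for seed in (5, 6, 7):
            ds = make_growth_dataset(n_mice=20, noise_sigma=0.10, seed=seed)
            rs.append(abs(caliper_residual_analysis(ds.caliper, ds.ct).correlation.pearson_r))
        assert np.median(rs) < 0.3

    def test_short_curves_skipped_with_log(self):
        days = np.arange(3.0)
        cal = [GrowthCurve("m1", "caliper", days, np.ones(3))]
        ct = [GrowthCurve("m1", "ct", days, np.ones(3))]
        res = caliper_residual_analysis(cal, ct)
        assert res.skipped == ["m1"]


class TestAgreementStats:
    def test_identical_methods(self):
        v = np.array([10.0, 20.0, 30.0])
        res = bland_altman(v, v)
        assert res.bias == 0.0 and np.all(res.differences == 0.0)

    def test_constant_offset(self):
        ct = np.array([10.0, 20.0, 30.0])
        res = bland_altman(ct + 10.0, ct)
        assert res.bias == pytest.approx(10.0)
        assert res.loa_low == pytest.approx(10.0) and res.loa_high == pytest.approx(10.0)

    def test_volume_dependent_bias_detected(self):
        rng = np.random.default_rng(2)
        ct = rng.uniform(10, 400, 50)
        cal = ct + 0.3 * ct + rng.normal(0, 5, 50)
        res = bland_altman(cal, ct)
        corr = correlations(res.means, res.differences)
        assert corr.pearson_r > 0.8

    def test_zero_crosstab_counts(self):
        cal = np.array([0.0, 0.0, 0.0, 0.0, 5.0, 5.0, 7.0])
        ct = np.array([0.0, 3.0, 3.0, 3.0, 0.0, 0.0, 7.0])
        tab = zero_volume_crosstab(cal, ct)
        assert (tab.both, tab.caliper_only, tab.ct_only, tab.neither) == (1, 3, 2, 1)
        assert tab.as_array().sum() == len(cal)

    def test_no_zeros(self):
        tab = zero_volume_crosstab(np.ones(4), np.ones(4))
        assert (tab.both, tab.caliper_only, tab.ct_only) == (0, 0, 0)


class TestMatchPairsAndIO:
    def test_exact_day_matching(self):
        cal = [GrowthCurve("m1", "caliper", np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 4.0]))]
        ct = [GrowthCurve("m1", "ct", np.array([2.0, 3.0, 4.0]), np.array([20.0, 30.0, 40.0]))]
        pairs = match_pairs(cal, ct)
        assert list(pairs["day"]) == [2.0, 4.0]

    def test_interpolated_matching_fills_gaps(self):
        cal = [GrowthCurve("m1", "caliper", np.array([1.0, 3.0]), np.array([10.0, 30.0]))]
        ct = [GrowthCurve("m1", "ct", np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))]
        pairs = match_pairs(cal, ct, interpolate=True)
        assert list(pairs["day"]) == [1.0, 2.0, 3.0]
        assert pairs.loc[pairs["day"] == 2.0, "caliper"].item() == pytest.approx(20.0)

    def test_caliper_csv_roundtrip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "cal.csv"
        pd.DataFrame(
            {
                "mouse": ["m1", "m1", "m2"],
                "day": [1, 2, 1],
                "d_long": [10.0, 11.0, 8.0],
                "d_short": [5.0, 6.0, 4.0],
                "measurer": ["A", "A", "B"],
            }
        ).to_csv(path, index=False)
        curves = curves_from_records(read_caliper_csv(path))
        assert [c.mouse_id for c in curves] == ["m1", "m2"]
        assert curves[0].volumes[0] == pytest.approx(0.5 * 10 * 25)

    def test_volumes_csv_roundtrip(self, tmp_path):
        import pandas as pd

        curves = [
            GrowthCurve("m1", "ct", np.array([1.0, 2.0]), np.array([10.123456789, 20.0]))
        ]
        path = tmp_path / "vol.csv"
        write_volumes_csv(curves, path)
        back = curves_from_table(
            pd.read_csv(path).rename(columns={"volume": "volume"}), "ct"
        )
        assert np.allclose(back[0].volumes, curves[0].volumes, atol=1e-9)
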