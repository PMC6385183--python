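"""Curve families, nested model selection, curve-sharing F tests, runs test."""

import math

import numpy as np
import pytest
from scipy import stats

import gaitasym as g
from gaitasym.speedfit import (
    DEFAULT_LADDER,
    CurveShareTest,
    Family,
    ModelSpec,
    SpeedCurveModel,
    averaged_analysis,
    compare_curves,
    eval_model,
    extra_ss_ftest,
    fit_model,
    inverse_stance_transform,
    runs_test,
    select_model,
    stance_transform,
    sweep_speed_ranges,
)


class TestEvalModel:
    def test_linear_identity_line(self):
        assert eval_model(Family.LINEAR, (0.0, 1.0), [7.0])[0] == 7.0

    def test_one_phase_reaches_plateau_at_large_k(self):
        y = eval_model(Family.ONE_PHASE, (0.0, 1.0, 1e6), [5.0])[0]
        assert y == pytest.approx(1.0)

    def test_one_phase_closed_form_value(self):
        y = eval_model(Family.ONE_PHASE, (0.6, 0.1, 0.3), [5.0])[0]
        assert y == pytest.approx(0.6 + (0.1 - 0.6) * (1 - math.exp(-1.5)), abs=1e-12)

    def test_wrong_param_count_rejected(self):
        with pytest.raises(ValueError):
            eval_model(Family.ONE_PHASE, (1.0, 2.0), [1.0])


class TestFitModel:
    def test_collinear_points_fit_exactly(self):
        x = np.array([1.0, 2.0, 4.0])
        fit = fit_model(x, 2 + 3 * x, Family.LINEAR)
        assert fit.ss_resid == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(fit.params, [2.0, 3.0], atol=1e-12)

    def test_noisy_linear_slope_within_3_se(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 10, 200)
        y = x + rng.standard_normal(200)
        fit = fit_model(x, y, Family.LINEAR)
        assert abs(fit.params[1] - 1.0) < 3 * fit.bse[1]

    def test_two_phase_rates_ordered(self):
        x = np.linspace(0.5, 16, 40)
        y = eval_model(Family.TWO_PHASE, (1.0, 4.0, 0.8, 3.0, 0.08), x)
        fit = fit_model(x, y, Family.TWO_PHASE, seed=1)
        assert fit.params[2] >= fit.params[4]  # KFast >= KSlow

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_model([1.0, 2.0], [1.0, 2.0], Family.LINEAR)


class TestExtraSSFTest:
    def _fit(self, ss, n, family=Family.LINEAR):
        f = fit_model(np.linspace(0, 1, n), np.zeros(n), family)
        f.ss_resid = ss
        return f

    def test_equal_ss_gives_f_zero_p_one(self):
        simple = self._fit(10.0, 20)
        complex_ = self._fit(10.0, 20, Family.ONE_PHASE)
        res = extra_ss_ftest(simple, complex_)
        assert res.F == 0.0 and res.p == 1.0

    def test_hand_computed_f_statistic(self):
        # SS 10 -> 5 with df 18 -> 17: F = (5/1)/(5/17) = 17
        simple = self._fit(10.0, 20)
        complex_ = self._fit(5.0, 20, Family.ONE_PHASE)
        res = extra_ss_ftest(simple, complex_)
        assert res.F == pytest.approx(17.0)
        assert (res.df_num, res.df_den) == (1, 17)

class TestSelectModel:
    def test_linear_data_selects_linear(self):
        rng = np.random.default_rng(0)
        x = np.linspace(3, 16, 60)
        y = 2 + 0.3 * x + 0.05 * rng.standard_normal(60)
        assert select_model(x, y).family is Family.LINEAR

    def test_saturating_data_promotes_to_one_phase(self):
        rng = np.random.default_rng(1)
        x = np.linspace(3, 16, 60)
        y = eval_model(Family.ONE_PHASE, (1.0, 7.0, 0.35), x) + 0.1 * rng.standard_normal(60)
        assert select_model(x, y, alpha_select=0.05).family is Family.ONE_PHASE

    def test_tiny_sample_forced_to_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        sel = select_model(x, 1 + x + np.array([0.01, -0.02, 0.015, 0.0]))
        assert sel.family is Family.LINEAR

    def test_ss_resid_non_increasing_along_ladder(self):
        rng = np.random.default_rng(2)
        x = np.linspace(1, 16, 80)
        y = eval_model(Family.ONE_PHASE, (1.0, 7.0, 0.35), x) + 0.2 * rng.standard_normal(80)
        fits = [fit_model(x, y, spec, seed=0) for spec in DEFAULT_LADDER]
        ss = [f.ss_resid for f in fits if f.converged]
        assert all(a >= b - 1e-8 for a, b in zip(ss, ss[1:]))


class TestSweep:
    def test_linear_everywhere_selects_linear_in_all_windows(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 25, 400)
        y = 1 + 0.2 * x + 0.05 * rng.standard_normal(400)
        report = sweep_speed_ranges(x, y, lo_start=0, hi_start=25, step=5,
                                    alpha_select=0.001)
        assert set(report.table["family"]) == {"linear"}
        assert report.widest_window()[:2] == (0.0, 25.0)

    def test_curvature_confined_below_three(self):
        """Piecewise data: curvature only below 3; windows excluding the
        slow tail select linear."""
        rng = np.random.default_rng(4)
        x = rng.uniform(0.5, 16, 500)
        y = 1 + 0.2 * x + np.where(x < 3, 2.0 * (3 - x) ** 2, 0.0)
        y = y + 0.05 * rng.standard_normal(500)
        report = sweep_speed_ranges(x, y, lo_start=0, hi_start=16, step=1,
                                    alpha_select=0.001)
        tab = report.table
        clean = tab[tab["lo"] >= 3]
        assert (clean["family"] == "linear").all()
        full = tab[(tab["lo"] == 0) & (tab["hi"] == 16)]
        assert (full["family"] != "linear").all()


class TestCompareCurves:
    def test_identical_datasets_share(self):
        rng = np.random.default_rng(5)
        x = np.linspace(3, 16, 50)
        y = 2 + 0.3 * x + 0.1 * rng.standard_normal(50)
        res = compare_curves(x, y, x, y)
        assert res.F == 0.0 and res.p == 1.0 and res.shared

    def test_distinct_noiseless_lines_differ(self):
        x = np.linspace(3, 16, 30)
        res = compare_curves(x, 2 + 0.3 * x, x, 3 + 0.3 * x)
        assert not res.shared and res.p == 0.0

    def test_symmetric_in_dataset_order(self):
        rng = np.random.default_rng(6)
        x = np.linspace(3, 16, 40)
        ya = 2 + 0.3 * x + 0.2 * rng.standard_normal(40)
        yb = 2.5 + 0.28 * x + 0.2 * rng.standard_normal(40)
        ab = compare_curves(x, ya, x, yb)
        ba = compare_curves(x, yb, x, ya)
        assert ab.F == pytest.approx(ba.F) and ab.p == pytest.approx(ba.p)

    def test_f_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(7)
        x = np.linspace(3, 16, 40)
        ya = 2 + 0.3 * x + 0.2 * rng.standard_normal(40)
        yb = 2.5 + 0.28 * x + 0.2 * rng.standard_normal(40)
        base = compare_curves(x, ya, x, yb)
        scaled = compare_curves(2 * x + 1, 5 * ya - 3, 2 * x + 1, 5 * yb - 3)
        assert scaled.F == pytest.approx(base.F, rel=1e-9)

    def test_df_accounting(self):
        rng = np.random.default_rng(8)
        xa = np.linspace(3, 16, 30)
        xb = np.linspace(3, 16, 25)
        res = compare_curves(xa, xa + rng.standard_normal(30),
                             xb, xb + rng.standard_normal(25))
        assert res.df_num == 2
        assert res.df_den == 30 + 25 - 4


class TestPower:
    def test_ten_percent_step_offset_detected_at_n300(self):
        """A 10% one-sided step shortening at ~300 strides/side is detected
        by the curve-sharing F test at alpha=0.001 in >80% of replicates."""
        from gaitasym.simulate import Asymmetry, GaitProfile

        prof = GaitProfile.mouse().with_asymmetry(step_delta=-0.10)
        rejections = 0
        n_rep = 30
        for rep in range(n_rep):
            ev = g.make_cohort(prof, 1, {"c": None}, n_trials=25,
                               strides_per_trial=12, subject_sd=0.0, seed=500 + rep)
            ds = g.filter_speed_range(g.build_dataset(ev), 3, 16)
            lh, rh = ds.side_pair("hind")
            lh = lh.dropna(subset=["step_length"])
            rh = rh.dropna(subset=["step_length"])
            res = compare_curves(
                lh["stride_velocity"], lh["step_length"],
                rh["stride_velocity"], rh["step_length"], alpha=0.001,
            )
            rejections += not res.shared
        assert rejections / n_rep > 0.8


class TestStanceTransform:
    def test_unit_stance_maps_to_one(self):
        X, Y, _ = stance_transform([1.0], [5.0])
        assert Y[0] == pytest.approx(1.0)

    def test_unit_speed_maps_to_one(self):
        X, Y, _ = stance_transform([0.5], [1.0])
        assert X[0] == pytest.approx(1.0)

    def test_round_trip_bijection(self):
        rng = np.random.default_rng(9)
        st_ = rng.uniform(0.1, 2.0, 100)
        v = rng.uniform(0.3, 16, 100)
        X, Y, n_excl = stance_transform(st_, v)
        assert n_excl == 0
        v2, st2 = inverse_stance_transform(X, Y)
        np.testing.assert_allclose(v2, v, rtol=1e-12)
        np.testing.assert_allclose(st2, st_, rtol=1e-12)

    def test_non_positive_records_excluded_and_counted(self):
        X, Y, n_excl = stance_transform([0.5, -0.1, 0.4], [5.0, 5.0, 0.0])
        assert n_excl == 2 and len(X) == 1


class TestRunsTest:
    def test_alternating_signs_give_positive_z(self):
        res = runs_test([1, -1, 1, -1, 1, -1], reference=0.0)
        assert res.n_runs == 6 and res.z > 0

    def test_hand_computed_z(self):
        # (+,+,+,-,-,-): R=2, mu=4, sigma^2=1.2
        res = runs_test([1, 1, 1, -1, -1, -1], reference=0.0)
        assert res.n_runs == 2
        assert res.z == pytest.approx((2 - 4) / math.sqrt(1.2))

    def test_all_one_side_is_undefined(self):
        res = runs_test([1.0, 2.0, 3.0], reference=0.0)
        assert not res.valid

    def test_values_equal_to_reference_dropped(self):
        a = runs_test([1, 0, -1, 1, 0, -1], reference=0.0)
        b = runs_test([1, -1, 1, -1], reference=0.0)
        assert a.n_runs == b.n_runs

    def test_exact_distribution_sums_to_one(self):
        from gaitasym.speedfit import _runs_pmf

        for na, nb in [(3, 3), (4, 6), (2, 8), (7, 3)]:
            assert _runs_pmf(na, nb).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_statsmodels_z_without_correction(self):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        rng = np.random.default_rng(10)
        x = rng.standard_normal(40)
        z_sm, _ = runstest_1samp(x, cutoff="mean", correction=False)
        assert runs_test(x).z == pytest.approx(z_sm, abs=1e-10)


class TestAveragedAnalysis:
    def _dataset(self, offsets):
        rows = []
        rng = np.random.default_rng(12)
        for i, delta in enumerate(offsets):
            for limb, off in (("LH", 0.0), ("RH", delta)):
                for k in range(6):
                    v = rng.uniform(4, 14)
                    rows.append(
                        {
                            "subject_id": f"s{i}",
                            "condition": "baseline",
                            "trial_id": "t1",
                            "limb": limb,
                            "stride_velocity": v,
                            "stride_length": 3 + 0.3 * v,
                            "step_length": 1.5 + 0.15 * v + off + 0.05 * rng.standard_normal(),
                            "swing_time": 0.1,
                            "stance_time": 0.4,
                            "cycle_duration": 0.5,
                            "t_start": float(k),
                            "position": float(k),
                        }
                    )
        import pandas as pd

        return g.GaitDataset(pd.DataFrame(rows))

    def test_identical_sides_give_t_zero_p_one(self):
        ds = self._dataset([0.0] * 5)
        rec = ds.records
        rh = rec[rec.limb == "RH"].copy()
        rec.loc[rh.index, "step_length"] = rec[rec.limb == "LH"]["step_length"].to_numpy()
        res = averaged_analysis(g.GaitDataset(rec), "step_length")
        assert res.t == 0.0 and res.p == 1.0

    def test_t_sign_follows_injected_offset(self):
        res = averaged_analysis(self._dataset([0.4] * 6), "step_length")
        assert res.t < 0  # right side larger -> left minus right negative

    def test_t_equals_hand_formula_on_five_subjects(self):
        ds = self._dataset([0.1, 0.3, -0.2, 0.25, 0.15])
        res = averaged_analysis(ds, "step_length")
        means = res.means.pivot(index="subject_id", columns="limb",
                                values="mean_step_length")
        d = (means["LH"] - means["RH"]).to_numpy()
        t_hand = d.mean() * math.sqrt(len(d)) / d.std(ddof=1)
        assert res.t == pytest.approx(t_hand, rel=1e-12)


class TestObjectLayer:
    def test_model_results_summary_and_predict(self):
        rng = np.random.default_rng(13)
        x = np.linspace(3, 16, 50)
        y = 2 + 0.3 * x + 0.1 * rng.standard_normal(50)
        res = SpeedCurveModel(x, y, family=Family.LINEAR).fit(runs=True)
        assert "linear" in res.summary()
        assert res.params.index.tolist() == ["intercept", "slope"]
        assert res.predict([10.0])[0] == pytest.approx(
            res.params["intercept"] + 10 * res.params["slope"])
        assert res.runs is not None

    def test_curve_share_from_dataset(self, unilateral_dataset):
        res = CurveShareTest.from_dataset(
            unilateral_dataset.select(condition="lesioned"), "step_length",
            pair="hind",
        ).fit()
        assert res.labels == ("LH", "RH")
        assert "Curve-sharing" in res.summary()
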