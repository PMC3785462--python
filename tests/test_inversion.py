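"""Calibration regression, N_sc* lookup and the design inversions."""

import numpy as np
import pandas as pd
import pytest

from haplopower.design import EffectSpec, InputError
from haplopower.inversion import (
    CalibrationGrid,
    CalibrationRangeError,
    NscCalibration,
    calibrate_nsc,
    fit_power_curve,
    load_default_calibration,
    local_linear_smooth,
    loo_cv_score,
    min_cases_given_controls,
    min_cases_given_ratio,
    min_controls_given_cases,
    min_detectable_effect,
)
from haplopower.scaling import n_sc_corrected

QUICK_GRID = CalibrationGrid(
    n_haplogroups=(4, 12, 20),
    risky_freqs=(0.30, 0.05),
    deviations=(1.0, 0.5),
    n_cases=(100, 500, 1000),
    ratios=(1.0, 3.0),
    n_sim=500,
)


@pytest.fixture(scope="module")
def quick_cal():
    return calibrate_nsc([0.05, 0.01], [0.5, 0.8, 0.9], grid=QUICK_GRID, seed=5)


class TestLocalLinear:
    def test_matches_statsmodels_kernel_regression(self):
        """Closed-form local-linear fit equals statsmodels KernelReg (ll)."""
        from statsmodels.nonparametric.kernel_regression import KernelReg

        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 80))
        y = np.sin(x) + rng.normal(0, 0.2, 80)
        h = 0.8
        ref = KernelReg(y, x, var_type="c", reg_type="ll", bw=[h])
        x_eval = np.linspace(0.5, 9.5, 41)
        ours = local_linear_smooth(x, y, x_eval, h)
        theirs, _ = ref.fit(x_eval)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_reproduces_exact_line(self):
        x = np.linspace(0, 1, 30)
        y = 2.0 * x + 1.0
        out = local_linear_smooth(x, y, x, 0.2)
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_cv_prefers_moderate_bandwidth_for_smooth_signal(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 150))
        y = np.sin(x) + rng.normal(0, 0.1, 150)
        scores = {h: loo_cv_score(x, y, h) for h in (0.05, 0.5, 5.0)}
        assert scores[0.5] < scores[5.0]
        assert np.isfinite(scores[0.5])


class TestFitPowerCurve:
    def test_fit_is_monotone_and_invertible(self, quick_cal):
        curve = quick_cal.curves[0.05]
        assert np.all(np.diff(curve.fitted) >= 0)
        x80 = curve.invert(0.8)
        assert curve(x80) == pytest.approx(0.8, abs=0.01)

    def test_inversion_out_of_range_raises(self, quick_cal):
        with pytest.raises(CalibrationRangeError, match="attainable"):
            quick_cal.curves[0.05].invert(0.99999)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_power_curve([1, 2, 3], [0.1, 0.2, 0.3])


class TestCalibration:
    def test_monotone_in_beta_and_alpha(self, quick_cal):
        tab = quick_cal.table.pivot(index="beta", columns="alpha", values="n_sc_star")
        for alpha in tab.columns:
            col = tab[alpha].dropna()
            assert np.all(np.diff(col.to_numpy()) > 0), f"beta order broken at {alpha}"
        for beta in tab.index:
            row = tab.loc[beta].dropna()
            # stricter alpha (smaller) needs a larger threshold
            assert np.all(np.diff(row.to_numpy()[np.argsort(row.index)]) < 0) or np.all(
                np.diff(row.sort_index().to_numpy()) < 0
            )

    def test_csv_round_trip(self, quick_cal, tmp_path):
        path = tmp_path / "cal.csv"
        quick_cal.to_csv(path)
        back = NscCalibration.from_csv(path)
        assert back.n_sc_star(0.05, 0.8) == pytest.approx(
            quick_cal.n_sc_star(0.05, 0.8)
        )
        assert back.metadata["kernel"] == "gaussian"
        assert (tmp_path / "cal.json").exists()

    def test_lookup_interpolates_in_beta(self, quick_cal):
        mid = quick_cal.table
        direct = NscCalibration(table=mid[["alpha", "beta", "n_sc_star"]].copy())
        v = direct.n_sc_star(0.05, 0.85)
        lo = direct.n_sc_star(0.05, 0.8)
        hi = direct.n_sc_star(0.05, 0.9)
        assert lo < v < hi

    def test_unknown_alpha_raises(self, quick_cal):
        with pytest.raises(CalibrationRangeError):
            NscCalibration(table=quick_cal.table).n_sc_star(0.2, 0.8)

    def test_default_calibration_ships_with_metadata(self):
        cal = load_default_calibration()
        assert cal.metadata["seed"] is not None
        tab = cal.table.pivot(index="beta", columns="alpha", values="n_sc_star")
        assert np.all(np.diff(tab[0.05].to_numpy()) > 0)
        assert tab.loc[0.80, 0.01] > tab.loc[0.80, 0.05]


class TestSampleSizeInversions:
    STAR = 6.6  # a typical 80%-power threshold at alpha = 0.05

    def test_minimality_contract(self, rng):
        for _ in range(10):
            p0 = rng.uniform(0.05, 0.3)
            delta = rng.uniform(0.25, 1.0)
            n_h = int(rng.integers(4, 21))
            r = float(rng.choice([1.0, 2.0, 3.0]))
            res = min_cases_given_ratio(self.STAR, r, p0, delta, n_h)
            p1 = p0 * (1 + delta)
            assert res.achieved_n_sc_corrected >= self.STAR - 1e-12
            n = res.n_cases_min
            if n > 1:
                below = n_sc_corrected(
                    p0, p1, n - 1, max(1, int(np.floor(r * (n - 1)))), n_h
                )
                assert below < self.STAR

    def test_closed_form_warm_start_within_one(self):
        p0, delta, n_h, r = 0.11, 1.0, 11, 2.0
        p1 = p0 * (1 + delta)
        pbar = (p0 + p1) / 2
        closed = (
            self.STAR * n_h**0.37 * pbar * (1 - pbar) * (1 + 1 / r) / (p1 - p0) ** 2
        )
        res = min_cases_given_ratio(self.STAR, r, p0, delta, n_h)
        assert abs(res.n_cases_min - closed) <= 1.0 + 1e-9

    def test_more_controls_per_case_means_fewer_cases(self):
        a = min_cases_given_ratio(self.STAR, 1.0, 0.11, 1.0, 11)
        b = min_cases_given_ratio(self.STAR, 2.0, 0.11, 1.0, 11)
        assert b.n_cases_min <= a.n_cases_min

    def test_fixed_arm_consistency_with_ratio_one(self):
        res_r1 = min_cases_given_ratio(self.STAR, 1.0, 0.11, 1.0, 11)
        res_co = min_controls_given_cases(self.STAR, res_r1.n_cases_min, 0.11, 1.0, 11)
        assert res_co.feasible
        assert res_co.n_controls_min <= res_r1.n_cases_min + 1

    def test_mirrored_solver_agrees_by_symmetry(self):
        a = min_controls_given_cases(self.STAR, 300, 0.11, 1.0, 11)
        b = min_cases_given_controls(self.STAR, 300, 0.11, 1.0, 11)
        assert a.n_controls_min == b.n_cases_min

    def test_infeasible_fixed_arm_reports_ceiling(self):
        res = min_controls_given_cases(self.STAR, 20, 0.11, 0.25, 11)
        assert not res.feasible
        assert res.n_controls_min is None
        assert 0 < res.limit_n_sc_corrected < self.STAR

    def test_effectspec_accepted_in_place_of_delta(self):
        by_float = min_cases_given_ratio(self.STAR, 1.0, 0.11, 1.0, 11)
        by_spec = min_cases_given_ratio(
            self.STAR, 1.0, 0.11, EffectSpec(risky_index=2, deviation=1.0), 11
        )
        assert by_float.n_cases_min == by_spec.n_cases_min


class TestMinDetectableEffect:
    STAR = 6.6

    def test_round_trip_through_sample_size(self):
        res = min_cases_given_ratio(self.STAR, 1.0, 0.11, 1.0, 11)
        md = min_detectable_effect(
            res.n_cases_min, res.n_controls_min, 0.11, 11, self.STAR
        )
        back = min_cases_given_ratio(self.STAR, 1.0, 0.11, md.delta_min, 11)
        assert abs(back.n_cases_min - res.n_cases_min) <= 1

    def test_delta_shrinks_with_more_controls_to_a_floor(self):
        deltas = [
            min_detectable_effect(200, n_co, 0.11, 11, self.STAR).delta_min
            for n_co in (200, 800, 10_000, 10**6)
        ]
        assert np.all(np.diff(deltas) < 0)
        assert deltas[-1] > 0

    def test_or_exceeds_one_and_approaches_one(self):
        near = min_detectable_effect(10**6, 10**6, 0.11, 11, self.STAR)
        far = min_detectable_effect(500, 500, 0.11, 11, self.STAR)
        assert far.or_min > near.or_min > 1.0
        assert near.or_min == pytest.approx(1.0, abs=0.02)

    def test_infeasible_design_reports_max_achievable(self):
        res = min_detectable_effect(5, 5, 0.11, 11, self.STAR)
        assert not res.feasible
        assert res.max_n_sc_corrected < self.STAR
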