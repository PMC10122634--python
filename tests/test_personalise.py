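"""Tests for fitting, stepwise selection, group models and statistics."""

import numpy as np
import pytest

from mtufit.model import SubjectRecord
from mtufit.parameters import DEFAULT_PARAMS
from mtufit.personalise import (
    FitResult,
    FitSpec,
    compare_rmse_groups,
    default_fit,
    evaluate_group_model,
    fit_parameters,
    group_median_model,
    group_statistics,
    rmse,
    simulate_subject_curves,
    stepwise_selection,
)
from mtufit.preprocess import ProcessedCurves
from mtufit.synthetic import processed_from_truth, sample_cohort, cohort_spec


def truth_curves(subject, params):
    """Noise-free curves from a ground-truth parameterisation, cropped."""
    angle = np.arange(-30.0, 25.0 + 1e-9, 0.5)
    torque, fasc = simulate_subject_curves(subject, params, angle)
    keep = np.nonzero(torque <= 0)[0]
    s = int(keep[-1]) + 1 if keep.size else 0
    return ProcessedCurves(angle[s:], torque[s:], fasc[s:], 1,
                           (float(angle[s]), float(angle[-1])))


class TestRmse:
    def test_identical_curves_zero(self):
        x = np.linspace(0, 1, 50)
        assert rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros(30)
        assert rmse(x + 2.5, x, normaliser=1.0) == pytest.approx(2.5)

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.normal(size=64), rng.normal(size=64)
        oracle = np.sqrt(np.sum((a - b) ** 2) / 64) / 3.0
        assert rmse(a, b, normaliser=3.0) == pytest.approx(oracle, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(10), np.zeros(11))


class TestFitSpec:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(free=("k_one_f",))  # dependent stiffness is never free

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(free=("lst_scale", "lst_scale"))


class TestFitting:
    def test_curves_at_defaults_fit_stays_at_defaults(self, subject):
        curves = truth_curves(subject, None)
        fit = fit_parameters(curves, subject, FitSpec(free=("lst_scale", "eps_one_t")))
        assert fit.params["lst_scale"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["eps_one_t"] == pytest.approx(0.049, abs=1e-6)
        assert fit.rmse_torque_norm < 1e-8
        assert fit.rmse_fascicle_norm < 1e-8

    def test_single_parameter_recovery(self, subject):
        curves = truth_curves(subject, {"lst_scale": 1.05})
        fit = fit_parameters(curves, subject, FitSpec(free=("lst_scale",)))
        assert fit.params["lst_scale"] == pytest.approx(1.05, abs=1e-3)

    def test_four_parameter_recovery_on_cp_median_curves(self, subject):
        truth = {"lst_scale": 1.03, "lof_scale": 0.81,
                 "eps_one_t": 0.23, "eps_zero_f": 0.089}
        curves = truth_curves(subject, truth)
        fit = fit_parameters(
            curves, subject,
            FitSpec(free=("lst_scale", "lof_scale", "eps_one_t", "eps_zero_f")),
        )
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, rel=0.02)

    def test_fitted_values_stay_within_bounds(self, subject):
        curves = truth_curves(subject, {"eps_one_t": 0.40, "lof_scale": 0.55})
        fit = fit_parameters(
            curves, subject, FitSpec(free=("eps_one_t", "lof_scale"))
        )
        from mtufit.parameters import PARAMETER_TABLE

        for name in fit.free:
            _, lo, hi = PARAMETER_TABLE[name]
            assert lo <= fit.params[name] <= hi

    def test_objective_never_above_default_start(self, subject):
        curves = truth_curves(subject, {"lst_scale": 1.06, "eps_one_t": 0.3})
        base = default_fit(subject, curves)
        fit = fit_parameters(curves, subject, FitSpec(free=("lst_scale",)))
        assert fit.cost <= base.cost + 1e-9

    def test_nesting_adding_parameters_never_worsens_optimum(self, subject):
        curves = truth_curves(subject, {"lst_scale": 1.04, "lof_scale": 0.9})
        c1 = fit_parameters(curves, subject, FitSpec(free=("lst_scale",))).cost
        c2 = fit_parameters(
            curves, subject, FitSpec(free=("lst_scale", "lof_scale"))
        ).cost
        assert c2 <= c1 + 1e-9


class TestStepwise:
    def test_cohort_at_defaults_stops_immediately(self, subject):
        cohort = [(subject, truth_curves(subject, None))] * 2
        res = stepwise_selection(cohort)
        assert res.selected == ()
        assert res.stopped_by_rule

    def test_lst_only_cohort_selects_lst_first(self):
        cohort = []
        for i, (tibia, mass) in enumerate([(0.33, 39.0), (0.345, 33.0), (0.325, 46.0)]):
            s = SubjectRecord(
                id=f"S{i}", group="TD", mass=mass, height_cm=143.0,
                tibia_m=tibia, foot_m=0.625 * tibia, leg_m=2.1 * tibia,
            )
            cohort.append((s, truth_curves(s, {"lst_scale": 1.06})))
        res = stepwise_selection(cohort)
        assert res.selected[0] == "lst_scale"
        assert res.stopped_by_rule

    def test_requires_two_subjects(self, subject):
        with pytest.raises(ValueError):
            stepwise_selection([(subject, truth_curves(subject, None))])


def _fits_from(values, group="CP", name="lst_scale"):
    out = []
    for i, v in enumerate(values):
        params = dict(DEFAULT_PARAMS)
        params[name] = v
        out.append(FitResult(
            subject_id=f"{group}{i}", group=group, params=params, free=(name,),
            rmse_torque_norm=0.01, rmse_fascicle_norm=0.001,
            rmse_torque_nm=0.4, rmse_fascicle_mm=0.3, cost=0.0, nfev=1,
            converged=True,
        ))
    return out


class TestGroupModel:
    def test_single_subject_median_is_that_subject(self):
        gm = group_median_model(_fits_from([1.07]))
        assert gm.median["lst_scale"] == pytest.approx(1.07)
        assert gm.n == 1

    def test_three_values_median(self):
        gm = group_median_model(_fits_from([1.0, 1.03, 1.1]))
        assert gm.median["lst_scale"] == pytest.approx(1.03)

    def test_iqr_matches_sorting_quantile_oracle(self, rng):
        """IQR equals q75 - q25 with linear interpolation between order
        statistics (the stated quantile convention)."""
        vals = rng.uniform(0.8, 1.2, size=13)
        gm = group_median_model(_fits_from(vals))

        def quantile_linear(sorted_v, q):
            pos = q * (len(sorted_v) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(sorted_v) - 1)
            return sorted_v[lo] + (pos - lo) * (sorted_v[hi] - sorted_v[lo])

        sv = np.sort(vals)
        oracle = quantile_linear(sv, 0.75) - quantile_linear(sv, 0.25)
        assert gm.iqr["lst_scale"] == pytest.approx(oracle, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_median_model([])

    def test_evaluate_group_model_reports_per_subject_rmses(self, subject):
        curves = truth_curves(subject, {"lst_scale": 1.03})
        gm = group_median_model(_fits_from([1.03, 1.03, 1.03]))
        evals = evaluate_group_model(gm, [(subject, curves)])
        assert len(evals) == 1
        assert evals[0].rmse_torque_norm < 1e-8  # medians equal the truth here


class TestGroupStatistics:
    def test_complete_separation_gives_tiny_mannwhitney_p(self):
        cp = _fits_from(np.linspace(1.10, 1.20, 13))
        td = _fits_from(np.linspace(0.90, 1.00, 13), group="TD")
        table = group_statistics(cp, td)
        row = table[table.parameter == "lst_scale"].iloc[0]
        assert row.mannwhitney_p < 1e-3
        assert row.significant_cp_vs_td

    def test_identical_groups_non_significant(self):
        vals = np.linspace(0.95, 1.05, 13)
        table = group_statistics(_fits_from(vals), _fits_from(vals, group="TD"))
        row = table[table.parameter == "lst_scale"].iloc[0]
        assert row.mannwhitney_p > 0.9

    def test_all_default_values_flagged_degenerate(self):
        cp = _fits_from([1.0] * 6)
        td = _fits_from([1.0] * 6, group="TD")
        table = group_statistics(cp, td)
        row = table[table.parameter == "lst_scale"].iloc[0]
        assert row.wilcoxon_degenerate_cp
        assert not row.significant_cp_vs_default

    def test_small_sample_skipped_with_notice(self):
        table = group_statistics(_fits_from([1.02]), _fits_from([0.99], group="TD"))
        row = table[table.parameter == "lst_scale"].iloc[0]
        assert np.isnan(row.mannwhitney_p)
        assert "skipped" in row.cp_note

    def test_rmse_comparison_helper(self):
        p = compare_rmse_groups([0.3, 0.31, 0.29, 0.33], [0.01, 0.012, 0.009, 0.011])
        assert p < 0.05
        with pytest.warns(UserWarning):
            assert np.isnan(compare_rmse_groups([0.3], [0.01]))


class TestCohortRoundTripSmall:
    def test_group_medians_recovered_from_exact_median_cohort(self):
        """Fits of a noise-free cohort whose truth sits exactly at the group
        medians reproduce those medians."""
        cohort = sample_cohort(cohort_spec("CP", n=3, param_iqrs={}), seed=9)
        free = ("lst_scale", "lof_scale", "eps_one_t", "eps_zero_f")
        fits = [
            fit_parameters(processed_from_truth(s), s.record, FitSpec(free=free))
            for s in cohort
        ]
        gm = group_median_model(fits)
        assert gm.median["lof_scale"] == pytest.approx(0.81, abs=1e-3)
        assert gm.median["lst_scale"] == pytest.approx(1.03, abs=1e-3)
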