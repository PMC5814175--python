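import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from cyclederg import (
    DataValidationError,
    PhaseFractions,
    QpcrMeasurement,
    bootstrap_ci,
    colony_percentage,
    ddct_fold_change,
    densitometry_ratio,
    fit_4pl,
    four_pl,
    group_ttest,
    inhibitory_concentration,
    phase_fold_change,
    simulate_dose_response,
    simulate_qpcr,
    tumor_metrics,
)

DOSES = [1.0, 3.0, 10.0, 20.0, 40.0, 80.0, 160.0]


class TestFit4PL:
    def test_noiseless_identity_fit(self):
        tab = simulate_dose_response((0, 100, 1.5, 39.0), DOSES, noise_sd=0.0)
        fit = fit_4pl(tab["dose_uM"], tab["viability_pct"])
        assert fit.converged
        assert fit.bottom == pytest.approx(0.0, abs=1e-3)
        assert fit.top == pytest.approx(100.0, rel=1e-4)
        assert fit.hill == pytest.approx(1.5, rel=1e-4)
        assert fit.ec50 == pytest.approx(39.0, rel=1e-4)

    def test_flat_curve_flagged_not_silent(self):
        fit = fit_4pl(DOSES, np.full(len(DOSES), 100.0))
        assert not fit.converged

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(DataValidationError):
            fit_4pl([1, 1, 2, 2, 3, 3], [90, 91, 60, 59, 30, 31])
        with pytest.raises(DataValidationError):
            fit_4pl([-1, 2, 3, 4, 5], [90, 80, 70, 60, 50])

    def test_ec50_recovery_under_noise(self):
        """Median EC50 estimate over seeds stays within 10% of truth."""
        estimates = []
        for seed in range(50):
            tab = simulate_dose_response((0, 100, 1.5, 39.0), DOSES,
                                         noise_sd=2.0, seed=seed)
            fit = fit_4pl(tab["dose_uM"], tab["viability_pct"])
            if fit.converged:
                estimates.append(fit.ec50)
        assert abs(np.median(estimates) - 39.0) / 39.0 <= 0.10


class TestInhibitoryConcentration:
    def _fit(self, bottom=0, top=100, hill=1.5, ec50=39.0):
        tab = simulate_dose_response((bottom, top, hill, ec50), DOSES, 0.0)
        return fit_4pl(tab["dose_uM"], tab["viability_pct"])

    def test_symmetric_curve_ic50_equals_ec50(self):
        fit = self._fit()
        assert inhibitory_concentration(fit, 50) == pytest.approx(39.0, rel=1e-6)

    def test_monotone_in_level(self):
        fit = self._fit()
        ics = [inhibitory_concentration(fit, l) for l in (20, 25, 50, 75)]
        assert ics == sorted(ics)

    def test_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            bottom = rng.uniform(0, 10)
            top = rng.uniform(90, 110)
            hill = rng.uniform(0.8, 4.0)
            ec50 = rng.uniform(5, 60)
            tab = simulate_dose_response((bottom, top, hill, ec50), DOSES, 0.0)
            fit = fit_4pl(tab["dose_uM"], tab["viability_pct"])
            level = rng.uniform(20, 80)
            target = 100.0 - level
            if not (fit.predict(DOSES[0] / 10) > target > fit.predict(DOSES[-1] * 10)):
                continue
            root = inhibitory_concentration(fit, level)
            # independent bisection on the fitted curve
            lo, hi = DOSES[0] / 10, DOSES[-1] * 10
            for _ in range(200):
                mid = (lo + hi) / 2
                if fit.predict(mid) > target:
                    lo = mid
                else:
                    hi = mid
            assert root == pytest.approx((lo + hi) / 2, rel=1e-6)

    def test_unattainable_level_names_range(self):
        fit = self._fit(bottom=60)  # curve never reaches 25% of control
        with pytest.raises(DataValidationError, match="unattainable"):
            inhibitory_concentration(fit, 75)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        tab = simulate_dose_response((0, 100, 1.5, 39.0), DOSES, 2.0, seed=1)
        a = bootstrap_ci(tab["dose_uM"], tab["viability_pct"], B=200, seed=9)
        b = bootstrap_ci(tab["dose_uM"], tab["viability_pct"], B=200, seed=9)
        assert a == b

    def test_noiseless_interval_is_tight(self):
        tab = simulate_dose_response((0, 100, 1.5, 39.0), DOSES, 0.0)
        ci = bootstrap_ci(tab["dose_uM"], tab["viability_pct"], B=200, seed=2)
        lo, hi = ci["ec50"]
        assert hi - lo < 1e-3

    def test_b_below_200_rejected(self):
        tab = simulate_dose_response((0, 100, 1.5, 39.0), DOSES, 0.0)
        with pytest.raises(DataValidationError):
            bootstrap_ci(tab["dose_uM"], tab["viability_pct"], B=100)


class TestDdct:
    def test_identity_fold(self):
        ctrl = [QpcrMeasurement("control", "CDK1", 25.0, 20.0)] * 3
        trt = [QpcrMeasurement("treated", "CDK1", 26.0, 21.0)] * 3
        fold, _ = ddct_fold_change(ctrl, trt)
        assert fold == pytest.approx(1.0)

    def test_two_cycle_shift_gives_quarter(self):
        ctrl = [QpcrMeasurement("control", "CDK1", 25.0, 20.0)]
        trt = [QpcrMeasurement("treated", "CDK1", 27.0, 20.0)]
        fold, _ = ddct_fold_change(ctrl, trt)
        assert fold == pytest.approx(0.25)

    def test_shift_invariance_of_both_cts(self):
        ctrl = [QpcrMeasurement("control", "CDK1", 25.0, 20.0)]
        trt = [QpcrMeasurement("treated", "CDK1", 27.5, 20.0)]
        f1, _ = ddct_fold_change(ctrl, trt)
        ctrl2 = [QpcrMeasurement("control", "CDK1", 28.0, 23.0)]
        trt2 = [QpcrMeasurement("treated", "CDK1", 30.5, 23.0)]
        f2, _ = ddct_fold_change(ctrl2, trt2)
        assert f1 == pytest.approx(f2)

    def test_mismatched_genes_rejected(self):
        ctrl = [QpcrMeasurement("control", "CDK1", 25.0, 20.0)]
        trt = [QpcrMeasurement("treated", "CDK2", 27.0, 20.0)]
        with pytest.raises(DataValidationError, match="CDK"):
            ddct_fold_change(ctrl, trt)

    def test_recovers_simulated_twenty_fold_down(self):
        """fold 0.05 at CT noise 0.1 recovered within 15% over seeds."""
        folds = []
        for seed in range(50):
            tab = simulate_qpcr({"CDK1": 0.05}, noise_sd=0.1, seed=seed)
            ctrl = [QpcrMeasurement(r.group, r.gene, r.ct_target, r.ct_reference)
                    for r in tab.itertuples() if r.group == "control"]
            trt = [QpcrMeasurement(r.group, r.gene, r.ct_target, r.ct_reference)
                   for r in tab.itertuples() if r.group == "treated"]
            folds.append(ddct_fold_change(ctrl, trt)[0])
        assert abs(np.mean(folds) - 0.05) / 0.05 <= 0.15


class TestDensitometry:
    def test_control_values_give_unity(self):
        assert densitometry_ratio(10, 5, 10, 5) == pytest.approx(1.0)

    def test_halved_band(self):
        assert densitometry_ratio(5, 5, 10, 5) == pytest.approx(0.5)

    def test_invariance_to_global_rescale(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            b, l, cb, cl = rng.uniform(1, 100, 4)
            c = rng.uniform(0.01, 100)
            assert densitometry_ratio(b * c, l * c, cb * c, cl * c) == pytest.approx(
                densitometry_ratio(b, l, cb, cl)
            )

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(DataValidationError):
            densitometry_ratio(0, 5, 10, 5)


class TestColonyAndPhases:
    def test_equal_counts_give_hundred_percent(self):
        pct, p = colony_percentage([50, 50, 50], [50, 50, 50])
        assert pct == pytest.approx(100.0)
        assert p == pytest.approx(1.0)

    def test_forty_percent_inhibition_shape(self):
        pct, _ = colony_percentage([40, 40, 40], [100, 100, 100])
        assert pct == pytest.approx(40.0)

    def test_t_p_close_to_permutation_p(self):
        treated = [31.0, 28.0, 35.0]
        control = [50.0, 47.0, 55.0]
        _, p = colony_percentage(treated, control)
        # exhaustive two-sample permutation on the mean difference
        pooled = treated + control
        obs = abs(np.mean(treated) - np.mean(control))
        count = 0
        combos = list(itertools.combinations(range(6), 3))
        for combo in combos:
            g1 = [pooled[i] for i in combo]
            g2 = [pooled[i] for i in range(6) if i not in combo]
            if abs(np.mean(g1) - np.mean(g2)) >= obs - 1e-12:
                count += 1
        p_perm = count / len(combos)
        se = np.sqrt(p_perm * (1 - p_perm) / len(combos))
        assert abs(p - p_perm) <= 3 * se + 0.05

    def test_g2m_block_fold(self):
        treated = PhaseFractions(g1=30, s=18, g2m=52)
        control = PhaseFractions(g1=60, s=26, g2m=14)
        assert phase_fold_change(treated, control, "g2m") == 3.7

    def test_fold_reciprocal_symmetry(self):
        a = PhaseFractions(g1=30, s=18, g2m=52)
        b = PhaseFractions(g1=60, s=26, g2m=14)
        f = phase_fold_change(a, b, "g2m")
        r = phase_fold_change(b, a, "g2m")
        assert r == pytest.approx(round(1 / (52 / 14), 1))
        assert f == pytest.approx(round(52 / 14, 1))

    def test_phase_fraction_invariants(self):
        with pytest.raises(DataValidationError):
            PhaseFractions(g1=150, s=0, g2m=0)
        with pytest.raises(DataValidationError):
            PhaseFractions(g1=10, s=10, g2m=10)  # sums to 30


class TestTumorAndTtest:
    def test_volume_formula(self):
        m = tumor_metrics(4, 2)
        assert m.volume == pytest.approx(8.0)
        assert m.area == pytest.approx(8.0)

    def test_equal_diameters(self):
        assert tumor_metrics(2, 2).volume == pytest.approx(4.0)

    def test_swapped_inputs_reordered(self):
        assert tumor_metrics(2, 4) == tumor_metrics(4, 2)

    def test_ellipse_area_flag(self):
        m = tumor_metrics(4, 2, ellipse_area=True)
        assert m.area == pytest.approx(np.pi / 4 * 8)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(DataValidationError):
            tumor_metrics(0, 2)

    def test_identical_groups_p_one(self):
        p, diff, _ = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        assert diff == 0

    def test_large_shift_significant_and_matches_permutation(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        p, diff, _ = group_ttest(a, b)
        assert p < 0.01 and diff == -10.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=5)
        b = rng.normal(1, 1, size=5)
        p1, _, _ = group_ttest(a, b)
        p2, _, _ = group_ttest(a + 7.0, b + 7.0)
        assert p1 == pytest.approx(p2)
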