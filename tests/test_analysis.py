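"""Melting-curve pipeline: preprocessing, fitting, fallback, screening."""

import numpy as np
import pytest

from dsfsim.analysis import (
    BoltzmannFit,
    MeltCurve,
    analyze_run,
    apply_well_calibration,
    average_replicates,
    boltzmann,
    count_inflections,
    delta_tm,
    double_boltzmann,
    fit_boltzmann,
    fit_calibration,
    fit_double_boltzmann,
    fold_cmc,
    subtract_blank,
    tm_by_second_derivative,
    truncate_post_denaturation,
)
from dsfsim.instrument import (
    DyeModel,
    UnfoldingModel,
    WellThermalModel,
    simulate_plate_run,
)
from dsfsim.thermal import build_schedule
from tests.conftest import make_layout


def sigmoid_curve(t, a1=100.0, a2=1100.0, tm=52.3, dt=1.8, noise_sd=0.0, rng=None):
    y = boltzmann(t, a1, a2, tm, dt)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(t))
    return MeltCurve(temps=t, signal=y)


def averaged_triplicate(t, noise_sd, rng, **kwargs):
    reps = [sigmoid_curve(t, noise_sd=noise_sd, rng=rng, **kwargs) for _ in range(3)]
    return average_replicates(reps)


class TestPreprocessing:
    def test_self_subtraction_zeroes(self, fine_grid):
        c = sigmoid_curve(fine_grid)
        assert np.allclose(subtract_blank(c, c).signal, 0.0)

    def test_zero_blank_is_identity(self, fine_grid):
        c = sigmoid_curve(fine_grid)
        blank = MeltCurve(temps=fine_grid, signal=np.zeros_like(fine_grid))
        assert np.allclose(subtract_blank(c, blank).signal, c.signal)

    def test_grid_mismatch_rejected(self, fine_grid):
        c = sigmoid_curve(fine_grid)
        other = sigmoid_curve(fine_grid + 0.5)
        with pytest.raises(ValueError):
            subtract_blank(c, other)

    def test_sd_combines_in_quadrature(self, fine_grid):
        ones = np.ones_like(fine_grid)
        a = MeltCurve(temps=fine_grid, signal=ones, sd=3.0 * ones)
        b = MeltCurve(temps=fine_grid, signal=ones, sd=4.0 * ones)
        assert np.allclose(subtract_blank(a, b).sd, 5.0)

    def test_average_of_identical_curves(self, fine_grid):
        c = sigmoid_curve(fine_grid)
        avg = average_replicates([c, c, c])
        assert np.allclose(avg.signal, c.signal)
        assert np.allclose(avg.sd, 0.0)
        assert avg.n_replicates == 3

    def test_average_hand_value(self):
        t = np.arange(5, dtype=float)
        curves = [MeltCurve(temps=t, signal=np.full(5, v)) for v in (1.0, 2.0, 3.0)]
        avg = average_replicates(curves)
        assert np.allclose(avg.signal, 2.0)
        assert np.allclose(avg.sd, 1.0)  # sample sd of {1,2,3}

    def test_single_replicate_has_no_sd(self, fine_grid):
        avg = average_replicates([sigmoid_curve(fine_grid)])
        assert avg.sd is None and avg.n_replicates == 1

    def test_empty_average_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])


class TestTruncation:
    def test_monotone_curve_unchanged(self, fine_grid):
        c = sigmoid_curve(fine_grid)
        assert len(truncate_post_denaturation(c)) == len(c)

    def test_decay_tail_removed_exactly(self, fine_grid):
        """Sigmoid + linear decay past saturation: cut at the known peak."""
        y = boltzmann(fine_grid, 100, 1100, 50.0, 1.5)
        decay_from = 60.0
        y = y - 12.0 * np.maximum(0.0, fine_grid - decay_from)
        peak = int(np.argmax(y))
        c = MeltCurve(temps=fine_grid, signal=y)
        trunc = truncate_post_denaturation(c)
        assert len(trunc) == peak + 1
        assert trunc.temps[-1] == fine_grid[peak]

    def test_flat_curve_unchanged(self, fine_grid):
        c = MeltCurve(temps=fine_grid, signal=np.full(len(fine_grid), 5.0))
        assert len(truncate_post_denaturation(c)) == len(c)

    def test_truncation_never_reaches_the_midpoint(self, fine_grid):
        """Decay starts past full denaturation, so the Tm region survives."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            model = UnfoldingModel.single(55.0, 1.5)
            y = boltzmann(fine_grid, 100, 1100, 55.0, 1.5)
            y -= 8.0 * np.maximum(0.0, fine_grid - model.t_full_denat)
            y += rng.normal(0, 20, len(fine_grid))
            trunc = truncate_post_denaturation(MeltCurve(temps=fine_grid, signal=y))
            assert trunc.temps[-1] >= 55.0

    def test_too_few_points_rejected(self):
        c = MeltCurve(temps=np.arange(4.0), signal=np.arange(4.0))
        with pytest.raises(ValueError):
            truncate_post_denaturation(c)


class TestBoltzmannFit:
    def test_noiseless_parameter_recovery(self):
        t = np.arange(25.0, 95.1, 0.5)
        fit = fit_boltzmann(sigmoid_curve(t, a1=0.0, a2=1000.0, tm=50.0, dt=2.0))
        assert fit.ok
        assert fit.a1 == pytest.approx(0.0, abs=1e-6)
        assert fit.a2 == pytest.approx(1000.0, abs=1e-3)
        assert fit.tm == pytest.approx(50.0, abs=1e-6)
        assert fit.dt == pytest.approx(2.0, abs=1e-6)

    def test_midpoint_identity(self, fine_grid):
        """Model value at the fitted tm is the plateau average, exactly."""
        rng = np.random.default_rng(1)
        fit = fit_boltzmann(averaged_triplicate(fine_grid, 10.0, rng))
        value = boltzmann(fit.tm, fit.a1, fit.a2, fit.tm, fit.dt)
        assert value == pytest.approx((fit.a1 + fit.a2) / 2, rel=1e-12)

    def test_flat_noise_flags_no_melt(self, fine_grid):
        rng = np.random.default_rng(2)
        c = MeltCurve(temps=fine_grid, signal=rng.normal(500.0, 5.0, len(fine_grid)))
        fit = fit_boltzmann(c)
        assert not fit.converged and fit.no_melt

    def test_parameter_recovery_under_noise(self, fine_grid):
        """200 synthetic triplicate curves at 2% noise: median |ΔTm| < 0.3 °C,
        bias < 0.1 °C."""
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tm_true = float(rng.uniform(45.0, 65.0))
            avg = averaged_triplicate(fine_grid, 20.0, rng, tm=tm_true)
            fit = fit_boltzmann(truncate_post_denaturation(avg))
            assert fit.ok
            errs.append(fit.tm - tm_true)
        errs = np.asarray(errs)
        assert np.median(np.abs(errs)) < 0.3
        assert abs(errs.mean()) < 0.1

    def test_too_few_points_rejected(self):
        c = MeltCurve(temps=np.arange(4.0), signal=np.arange(4.0))
        with pytest.raises(ValueError):
            fit_boltzmann(c)


class TestDoubleBoltzmannFit:
    def test_two_transition_recovery_at_one_percent_noise(self, fine_grid):
        """Recovers two separated midpoints (46.1 / 63.1 °C) within 0.3 °C."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = double_boltzmann(fine_grid, 100, 1100, 0.5, 46.1, 63.1, 1.5, 1.5)
            reps = [
                MeltCurve(temps=fine_grid, signal=base + rng.normal(0, 10, len(fine_grid)))
                for _ in range(3)
            ]
            fit = fit_double_boltzmann(truncate_post_denaturation(average_replicates(reps)))
            assert fit.ok
            assert fit.tm1 == pytest.approx(46.1, abs=0.3)
            assert fit.tm2 == pytest.approx(63.1, abs=0.3)

    def test_degenerate_double_matches_single(self, fine_grid):
        """frac→1 data: the double fit's tm1 equals the single-model tm."""
        c = sigmoid_curve(fine_grid, tm=52.0, dt=2.0)
        single = fit_boltzmann(c)
        double = fit_double_boltzmann(c)
        assert double.converged
        matches = min(abs(double.tm1 - single.tm), abs(double.tm2 - single.tm))
        assert matches < 0.1

    def test_midpoints_reported_in_order(self, fine_grid):
        rng = np.random.default_rng(5)
        base = double_boltzmann(fine_grid, 100, 1100, 0.4, 45.0, 64.0, 1.5, 2.0)
        c = MeltCurve(temps=fine_grid, signal=base + rng.normal(0, 10, len(fine_grid)))
        fit = fit_double_boltzmann(c)
        assert fit.tm1 < fit.tm2


class TestInflectionCounting:
    def test_single_sigmoid(self, fine_grid):
        assert count_inflections(sigmoid_curve(fine_grid)) == 1

    def test_two_separated_sigmoids(self, fine_grid):
        y = double_boltzmann(fine_grid, 100, 1100, 0.5, 46.0, 63.0, 1.5, 1.5)
        assert count_inflections(MeltCurve(temps=fine_grid, signal=y)) == 2

    def test_flat_noise(self, fine_grid):
        rng = np.random.default_rng(3)
        c = MeltCurve(temps=fine_grid, signal=rng.normal(500.0, 5.0, len(fine_grid)))
        assert count_inflections(c) == 0

    def test_too_few_points_rejected(self):
        c = MeltCurve(temps=np.arange(6.0), signal=np.arange(6.0))
        with pytest.raises(ValueError):
            count_inflections(c)


class TestSecondDerivativeFallback:
    def test_matches_analytic_inflection(self):
        """On a fine grid the zero-crossing sits at the sigmoid midpoint."""
        t = np.arange(25.0, 95.1, 0.5)
        tm = tm_by_second_derivative(sigmoid_curve(t, tm=52.3))
        assert tm == pytest.approx(52.3, abs=0.25)  # half a grid step

    def test_linear_curve_has_no_crossing(self, fine_grid):
        c = MeltCurve(temps=fine_grid, signal=2.0 * fine_grid + 5.0)
        assert tm_by_second_derivative(c) is None

    def test_agreement_with_fit_across_seeds(self, fine_grid):
        """Derivative and fitted Tm agree within one grid step at 1% noise."""
        step = float(np.median(np.diff(fine_grid)))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            avg = truncate_post_denaturation(averaged_triplicate(fine_grid, 10.0, rng))
            tm_fit = fit_boltzmann(avg).tm
            tm_deriv = tm_by_second_derivative(avg)
            assert tm_deriv is not None
            assert abs(tm_fit - tm_deriv) <= step


class TestCalibration:
    def test_exact_line(self):
        x = np.arange(25.0, 95.0, 3.0)
        cal = fit_calibration(x, 2.0 * x + 1.0)
        assert cal.slope == pytest.approx(2.0, abs=1e-12)
        assert cal.intercept == pytest.approx(1.0, abs=1e-9)
        assert cal.resid_sd == pytest.approx(0.0, abs=1e-9)

    def test_simulated_wells_recover_instrument_slope(self):
        """Default well-lag model regressed over the default schedule ≈ 0.681."""
        setpoints = build_schedule().setpoints
        slopes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            from dsfsim.instrument import pad_to_well_temperature

            wells = pad_to_well_temperature(setpoints, WellThermalModel(), rng)
            slopes.append(fit_calibration(setpoints, wells).slope)
        mean = np.mean(slopes)
        sem = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - 0.681) < 3 * sem

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([25.0, 30.0], [24.0, 28.0])

    def test_apply_identity_and_default_line(self):
        from dsfsim.analysis import CalibrationLine

        ident = CalibrationLine(1.0, 0.0, 0.0, 0.0, 0.0)
        assert apply_well_calibration(63.0, ident) == 63.0
        default = CalibrationLine(0.681, 7.034, 0.0, 0.0, 0.0)
        assert apply_well_calibration(95.0, default) == pytest.approx(71.729)
        assert apply_well_calibration(0.0, default) == pytest.approx(7.034)


class TestDeltaTm:
    def fit(self, tm, sd):
        return BoltzmannFit(0, 1000, tm, 2.0, sd, 0.0, converged=True)

    def test_identical_fits_zero_shift(self):
        shift, _ = delta_tm(self.fit(50.0, 0.5), self.fit(50.0, 0.5))
        assert shift == 0.0

    def test_anoxic_oxic_shift(self):
        """48.3 vs 46.0 °C gives +2.3 °C with quadrature sd ≈ 1.208."""
        shift, sd = delta_tm(self.fit(48.3, 1.1), self.fit(46.0, 0.5))
        assert shift == pytest.approx(2.3)
        assert sd == pytest.approx(np.sqrt(1.1**2 + 0.5**2), abs=1e-9)
        assert sd == pytest.approx(1.208, abs=1e-3)

    def test_no_melt_side_is_flagged(self):
        bad = BoltzmannFit(0, 0, np.nan, 2.0, np.nan, np.nan, converged=False, no_melt=True)
        assert delta_tm(self.fit(50.0, 0.5), bad) is None


class TestFoldCmc:
    def test_ddm_worked_example(self):
        assert fold_cmc(0.05, 0.0087) == 5.7

    def test_unit_dose(self):
        assert fold_cmc(0.0087, 0.0087) == 1.0

    def test_zero_cmc_rejected(self):
        with pytest.raises(ValueError):
            fold_cmc(0.05, 0.0)


class TestAnalyzeRun:
    def test_ranking_matches_generating_order(self):
        """Four pH conditions with distinct true Tm rank as generated."""
        conds = ["pH 6.0", "pH 7.0", "pH 8.0", "pH 5.0"]
        tms = [61.0, 57.0, 52.0, 45.0]
        layout = make_layout(conds, tms)
        run = simulate_plate_run(layout, build_schedule(), seed=7)
        report = analyze_run(run, layout)
        table = report.table
        assert list(table["condition"]) == conds  # already Tm-sorted
        assert not table["no_melt"].any()
        assert (table["fit_type"] == "boltzmann").all()

    def test_interference_condition_flagged_no_melt(self):
        """A DDAO-like interference-swamped condition yields no Tm."""
        ddao = DyeModel.cpm(interference_level=2e5)
        layout = make_layout(["DDM", "DDAO"], [55.0, 55.0], dye=DyeModel.cpm())
        wells = dict(layout.wells)
        replacement = make_layout(["DDAO"], [55.0], dye=ddao, rows="B")
        wells.update(replacement.wells)
        from dsfsim.instrument import PlateLayout

        layout = PlateLayout(wells)
        run = simulate_plate_run(layout, build_schedule(), seed=3)
        table = analyze_run(run, layout).table.set_index("condition")
        assert bool(table.loc["DDAO", "no_melt"])
        assert not bool(table.loc["DDM", "no_melt"])

    def test_all_blank_plate_empty_report(self):
        from dsfsim.instrument import PlateLayout, WellAssignment

        layout = PlateLayout(
            {
                w: WellAssignment("buffer", "b", True, DyeModel.sypro(), None)
                for w in ("A1", "A2", "A3")
            }
        )
        run = simulate_plate_run(layout, build_schedule(), seed=0)
        assert len(analyze_run(run, layout).table) == 0

    def test_well_scale_transforms_tm(self):
        from dsfsim.analysis import CalibrationLine

        layout = make_layout(["c"], [55.0])
        run = simulate_plate_run(layout, build_schedule(), seed=1)
        pad = analyze_run(run, layout).table
        cal = CalibrationLine(0.681, 7.034, 0.0, 0.0, 0.0)
        well = analyze_run(run, layout, calibration=cal, well_scale=True).table
        expected = 0.681 * pad["tm"].iloc[0] + 7.034
        assert well["tm"].iloc[0] == pytest.approx(expected)

    def test_run_wells_missing_from_layout_rejected(self):
        layout = make_layout(["c1", "c2"], [50.0, 60.0])
        run = simulate_plate_run(layout, build_schedule(), seed=0)
        smaller = make_layout(["c1"], [50.0])
        with pytest.raises(ValueError):
            analyze_run(run, smaller)
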