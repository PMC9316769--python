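"""Synthetic-data generators: surfaces, calibration, chromatograms."""

import numpy as np
import pytest

from uaeqc.desirability import DesirabilitySpec, compute_desirability
from uaeqc.doe import FactorSpec, generate_bbd
from uaeqc.optimize import maximize_surface
from uaeqc.rsm import fit_quadratic
from uaeqc.simulate import (DEFAULT_SCHEDULE, GaussianPeak, SurfaceTruth,
                            WavelengthSchedule, integrate_peaks,
                            simulate_bbd_responses, simulate_calibration,
                            simulate_chromatogram)

# published fitted surface, used as simulation ground truth
TRUTH_COEF = (0.81, -0.22, 0.2, 0.084, 0.012, 0.076, -0.014,
              -0.33, -0.031, -0.069)


def make_design():
    return generate_bbd([
        FactorSpec("methanol", "%", 50, 70, 90),
        FactorSpec("ratio", "mL/g", 30, 50, 70),
        FactorSpec("time", "min", 20, 35, 50),
    ], n_center=5)


class TestSimulateBBDResponses:
    def test_zero_noise_exactly_recovered(self):
        design = make_design()
        table = simulate_bbd_responses(
            design, SurfaceTruth(TRUTH_COEF, 0.0), seed=1)
        model = fit_quadratic(design, table["response"])
        assert np.allclose(model.coef, TRUTH_COEF, atol=1e-10)

    def test_seeded_determinism(self):
        design = make_design()
        truth = SurfaceTruth(TRUTH_COEF, 0.02)
        a = simulate_bbd_responses(design, truth, seed=7)
        b = simulate_bbd_responses(design, truth, seed=7)
        assert a.equals(b)
        c = simulate_bbd_responses(design, truth, seed=8)
        assert not a["response"].equals(c["response"])

    def test_monte_carlo_parameter_recovery(self):
        """200 simulations at noise sd 0.02: the mean fitted coefficient
        vector sits within 3 standard errors of the truth."""
        design = make_design()
        truth = SurfaceTruth(TRUTH_COEF, 0.02)
        fits = np.array([
            fit_quadratic(design,
                          simulate_bbd_responses(design, truth, seed=s)
                          ["response"]).coef
            for s in range(200)
        ])
        mean = fits.mean(axis=0)
        se = fits.std(axis=0, ddof=1) / np.sqrt(len(fits))
        assert np.all(np.abs(mean - np.asarray(TRUTH_COEF)) <= 3 * se)

    def test_end_to_end_optimum_recovery(self):
        """Simulated indices → desirability → fit → maximize recovers
        the truth surface's constrained optimum within 0.05 coded
        units at low noise."""
        design = make_design()
        true_model = fit_quadratic(
            design, simulate_bbd_responses(
                design, SurfaceTruth(TRUTH_COEF, 0.0), seed=0)["response"])
        true_opt = maximize_surface(true_model)

        rng = np.random.default_rng(11)
        # two synthetic quality indices, both monotone in the latent
        # surface value, plus small noise; OD reconstructs the ordering
        latent = simulate_bbd_responses(
            design, SurfaceTruth(TRUTH_COEF, 0.005), seed=11)["response"]
        idx = np.column_stack([
            10 * latent + rng.normal(0, 0.01, 17),
            3 + 5 * latent + rng.normal(0, 0.01, 17),
        ])
        od = compute_desirability(
            idx, DesirabilitySpec.all_larger_better(["a", "b"])).od
        model = fit_quadratic(design, od)
        opt = maximize_surface(model)
        assert np.all(np.abs(opt.coded - true_opt.coded) <= 0.05)


class TestWavelengthSchedule:
    def test_default_schedule_covers_28_min_run(self):
        assert DEFAULT_SCHEDULE.run_end == 28.0
        assert len(DEFAULT_SCHEDULE.segments) == 6
        assert DEFAULT_SCHEDULE.wavelength_at(5.0) == 348.0
        assert DEFAULT_SCHEDULE.wavelength_at(7.3) == 284.0  # boundary → later
        assert DEFAULT_SCHEDULE.wavelength_at(27.9) == 280.0

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            WavelengthSchedule(((0, 5, 300), (6, 10, 310)))

    def test_must_start_at_zero(self):
        with pytest.raises(ValueError, match="t=0"):
            WavelengthSchedule(((1, 5, 300),))


class TestSimulateChromatogram:
    def test_flat_zero_without_peaks_or_noise(self):
        chrom = simulate_chromatogram([], baseline_sd=0.0)
        assert np.all(chrom.signal == 0.0)
        assert chrom.time_min[0] == 0.0 and chrom.time_min[-1] == 28.0

    def test_unit_area_gaussian_integrates_to_one(self):
        """A unit-area Gaussian fully inside one segment integrates to
        1 within 0.1 % on a 0.001-min grid."""
        sigma = 0.05
        peak = GaussianPeak(rt_min=5.0, height=1 / (sigma * np.sqrt(2 * np.pi)),
                            sigma_min=sigma)
        chrom = simulate_chromatogram([peak], step_min=0.001)
        area = integrate_peaks(chrom, [(5 - 5 * sigma, 5 + 5 * sigma)])[0]
        assert area == pytest.approx(1.0, rel=1e-3)

    def test_integration_converges_with_step(self):
        sigma = 0.05
        peak = GaussianPeak(5.0, 1 / (sigma * np.sqrt(2 * np.pi)), sigma)
        errs = []
        for step in (0.02, 0.005, 0.001):
            chrom = simulate_chromatogram([peak], step_min=step)
            area = integrate_peaks(chrom, [(4.75, 5.25)])[0]
            errs.append(abs(area - 1.0))
        assert errs[0] >= errs[1] >= errs[2]

    def test_height_scales_at_segment_switch(self):
        """A peak straddling a wavelength switch with response ratio
        5:1 integrates between the two single-segment areas."""
        sigma = 0.1
        h = 1 / (sigma * np.sqrt(2 * np.pi))
        peak_lo = GaussianPeak(7.3, h * 0.2, sigma)
        peak_hi = GaussianPeak(7.3, h, sigma)
        split = GaussianPeak(7.3, h, sigma, ref_wavelength=348.0,
                             response_factors={284.0: 0.2})
        window = (7.3 - 5 * sigma, 7.3 + 5 * sigma)
        a_lo = integrate_peaks(
            simulate_chromatogram([peak_lo], step_min=0.001), [window])[0]
        a_hi = integrate_peaks(
            simulate_chromatogram([peak_hi], step_min=0.001), [window])[0]
        a_split = integrate_peaks(
            simulate_chromatogram([split], step_min=0.001), [window])[0]
        assert a_lo < a_split < a_hi

    def test_doubling_height_doubles_area(self):
        sigma = 0.05
        p1 = GaussianPeak(15.0, 2.0, sigma)
        p2 = GaussianPeak(15.0, 4.0, sigma)
        w = [(14.5, 15.5)]
        a1 = integrate_peaks(simulate_chromatogram([p1]), w)[0]
        a2 = integrate_peaks(simulate_chromatogram([p2]), w)[0]
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_empty_window_area_near_zero(self):
        sd = 0.01
        chrom = simulate_chromatogram(
            [GaussianPeak(5.0, 1.0, 0.05)], baseline_sd=sd, seed=3)
        area = integrate_peaks(chrom, [(20.0, 21.0)])[0]
        assert abs(area) < 3 * sd * 1.0

    def test_peak_outside_run_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_chromatogram([GaussianPeak(30.0, 1.0, 0.1)])

    def test_overlapping_windows_rejected(self):
        chrom = simulate_chromatogram([])
        with pytest.raises(ValueError, match="overlap"):
            integrate_peaks(chrom, [(1.0, 3.0), (2.0, 4.0)])

    def test_seeded_noise_reproducible(self):
        a = simulate_chromatogram([], baseline_sd=0.01, seed=5)
        b = simulate_chromatogram([], baseline_sd=0.01, seed=5)
        assert np.array_equal(a.signal, b.signal)


class TestSimulateCalibration:
    def test_noiseless_points_on_published_line(self):
        from uaeqc.validation import fit_calibration
        pts = simulate_calibration(13.984, -3.0103,
                                   [2.86, 10, 50, 143], 0.0, seed=0)
        curve = fit_calibration(pts["concentration_ug_ml"], pts["peak_area"])
        assert curve.slope == pytest.approx(13.984, abs=1e-10)

    def test_seeded_reproducibility(self):
        a = simulate_calibration(2.0, 1.0, [1, 2, 3], 0.5, seed=9)
        b = simulate_calibration(2.0, 1.0, [1, 2, 3], 0.5, seed=9)
        assert a.equals(b)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            simulate_calibration(1.0, 0.0, [1, 2], 0.0, seed=0)
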