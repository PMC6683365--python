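"""Calibration: spot detection, preprocessing, mixed-effects fit,
inverse prediction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from surfmsi import calibrate, msi_io, simgen, workflow
from surfmsi.calibrate import CalibrationFit
from surfmsi.msi_io import IonImage
from surfmsi.preprocess import LogIonImage


def jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


class TestDetectSpots:
    def test_recovers_stamped_pixel_sets(self, calib_params):
        ds, truth = simgen.generate_calibration_slide(calib_params, 0, 0)
        mel = msi_io.extract_ion_image(ds, simgen.MZ_MELITTIN)
        spots = calibrate.detect_spots(mel, expected_n=6)
        assert len(spots) == 6
        for found, true in zip(spots, truth.spot_pixels):
            assert jaccard(found, true) >= 0.9

    def test_zero_melittin_is_error(self):
        img = IonImage(values=np.zeros((5, 5)), target_mz=simgen.MZ_MELITTIN,
                       tolerance=1.0)
        with pytest.raises(ValueError, match="no signal|found 0"):
            calibrate.detect_spots(img, expected_n=6)

    def test_touching_spots_merge_into_too_few_components(self):
        """Two drops that ran together form one blob: detection reports the
        shortfall instead of guessing a split."""
        v = np.ones((7, 12))
        v[2:5, 2:6] = 1000.0
        v[2:5, 5:9] = 1000.0  # touches the first blob
        img = IonImage(values=v, target_mz=simgen.MZ_MELITTIN, tolerance=1.0)
        with pytest.raises(ValueError, match="found 1"):
            calibrate.detect_spots(img, expected_n=2)

    def test_spots_ordered_by_column(self, calib_params):
        ds, truth = simgen.generate_calibration_slide(calib_params, 0, 0)
        mel = msi_io.extract_ion_image(ds, simgen.MZ_MELITTIN)
        spots = calibrate.detect_spots(mel, expected_n=6)
        cols = [np.mean([x for x, _ in s]) for s in spots]
        assert cols == sorted(cols)


class TestSlideProcessing:
    def test_background_subtraction_is_uniform_shift(self):
        img = LogIonImage(values=np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = calibrate.spot_background_subtract(img, 0.4)
        np.testing.assert_allclose(out.values, img.values - 0.4)

    def test_equal_true_signal_gives_equal_adjusted_means_across_slides(self):
        """Slides with different background offsets yield the same adjusted
        spot means once the slide background is subtracted (noise off)."""
        p = simgen.CalibSimParams(exp_sd=0.0, pixel_sd=0.0,
                                  slide_offset_sd=0.5, seed=3)
        means = []
        for r in (0, 1):
            ds, truth = simgen.generate_calibration_slide(p, 0, r)
            spots = calibrate.process_calibration_slide(
                msi_io.extract_ion_image(ds, simgen.MZ_SPC),
                msi_io.extract_ion_image(ds, simgen.MZ_MELITTIN),
                list(p.amounts), "e0", f"r{r}")
            means.append([s.mean_signal for s in spots])
        np.testing.assert_allclose(means[0], means[1], atol=0.02)

    def test_c_pixel_is_amount_over_pixel_count(self):
        spot = calibrate.CalibrationSpot(
            experiment_id="e0", replicate_id="r0", nominal_amount=10.0,
            pixel_set=frozenset((x, 0) for x in range(20)), mean_signal=1.0)
        assert spot.c_pixel == pytest.approx(0.5)

    def test_table_shape_for_study_design(self, calib_params):
        _, table = workflow.run_calibration(calib_params)
        assert len(table) == 3 * 2 * 6
        assert set(table.columns) >= {"experiment_id", "replicate_id",
                                      "amount_ng", "n_pixels", "c_pixel",
                                      "mean_signal"}

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate.build_calibration_table([])


class TestFitCalibration:
    def make_table(self, slope=3.1, intercept=0.2, exp_sd=0.0, noise_sd=0.0,
                   n_exp=3, n_rep=2, seed=0):
        rng = np.random.default_rng(seed)
        c = np.array([1, 2.5, 5, 10, 25, 50]) / 21.0
        rows = []
        for e in range(n_exp):
            u = rng.normal(0, exp_sd) if exp_sd else 0.0
            for r in range(n_rep):
                for cc in c:
                    y = slope * cc + intercept + u + (
                        rng.normal(0, noise_sd) if noise_sd else 0.0)
                    rows.append((f"e{e}", f"r{r}", cc * 21, 21, cc, y))
        return pd.DataFrame(rows, columns=["experiment_id", "replicate_id",
                                           "amount_ng", "n_pixels", "c_pixel",
                                           "mean_signal"])

    def test_noise_free_exact_recovery(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = calibrate.fit_calibration(self.make_table())
        assert fit.slope == pytest.approx(3.1, abs=1e-8)
        assert fit.intercept == pytest.approx(0.2, abs=1e-8)

    def test_noise_free_full_pipeline_recovery(self):
        """End-to-end: noise-free slides through spot detection and fitting
        reproduce the generating line almost exactly (the only residual is
        the log-domain pseudocount)."""
        p = simgen.CalibSimParams(exp_sd=0.0, pixel_sd=0.0,
                                  slide_offset_sd=0.0, background_sigma=0.0,
                                  seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, _ = workflow.run_calibration(p)
        assert fit.slope == pytest.approx(3.1, rel=1e-3)
        assert fit.intercept == pytest.approx(0.2, abs=5e-3)

    def test_single_experiment_rejected(self):
        with pytest.raises(ValueError, match="experiments"):
            calibrate.fit_calibration(self.make_table(n_exp=1))

    def test_too_few_amounts_rejected(self):
        t = self.make_table()
        t = t[t["amount_ng"].isin([1.0, 2.5])]
        with pytest.raises(ValueError, match="amounts"):
            calibrate.fit_calibration(t)

    def test_relabeling_experiments_leaves_fixed_effects(self):
        t = self.make_table(exp_sd=0.05, noise_sd=0.02, seed=5)
        fit1 = calibrate.fit_calibration(t)
        remap = {"e0": "eB", "e1": "eC", "e2": "eA"}
        t2 = t.assign(experiment_id=t["experiment_id"].map(remap))
        t2 = t2.sort_values("experiment_id").reset_index(drop=True)
        fit2 = calibrate.fit_calibration(t2)
        assert fit1.slope == pytest.approx(fit2.slope, abs=1e-8)
        assert fit1.intercept == pytest.approx(fit2.intercept, abs=1e-8)

    def test_zero_between_experiment_variance_falls_back_to_ols(self):
        # seed chosen so the REML variance estimate hits the zero boundary
        with pytest.warns(UserWarning, match="singular"):
            fit = calibrate.fit_calibration(self.make_table(noise_sd=0.02,
                                                            exp_sd=0.0,
                                                            seed=2))
        assert fit.method == "ols-fallback"
        assert fit.exp_var == 0.0

    def test_ci_coverage_at_study_design(self):
        """95% fixed-effect intervals cover the generating values at an
        observed rate of 90–99% across 200 simulated experiments."""
        n = 200
        cov_s = cov_i = 0
        for s in range(n):
            t = self.make_table(exp_sd=0.05, noise_sd=0.022, seed=1000 + s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = calibrate.fit_calibration(t)
            cov_s += fit.slope_ci[0] <= 3.1 <= fit.slope_ci[1]
            cov_i += fit.intercept_ci[0] <= 0.2 <= fit.intercept_ci[1]
        assert 0.90 * n <= cov_s <= 0.99 * n
        assert 0.90 * n <= cov_i <= 0.99 * n


class TestQuantify:
    FIT = CalibrationFit(slope=3.1, intercept=0.2, slope_ci=(3.0, 3.2),
                         intercept_ci=(0.1, 0.3), exp_var=0.0,
                         residual_var=0.0)

    def corrected(self, values):
        return LogIonImage(values=np.asarray(values, dtype=float))

    def test_inverts_printed_line(self):
        img = self.corrected([[3.3]])
        qm = calibrate.quantify(img, self.FIT, np.ones((1, 1), dtype=bool))
        assert qm.amount[0, 0] == pytest.approx(1.0)
        assert qm.amount_lo[0, 0] <= 1.0 <= qm.amount_hi[0, 0]

    def test_signal_at_intercept_gives_zero(self):
        img = self.corrected([[0.2]])
        qm = calibrate.quantify(img, self.FIT, np.ones((1, 1), dtype=bool))
        assert qm.amount[0, 0] == 0.0
        assert not qm.clamped[0, 0]

    def test_below_intercept_clamped_and_flagged(self):
        img = self.corrected([[0.05]])
        qm = calibrate.quantify(img, self.FIT, np.ones((1, 1), dtype=bool))
        assert qm.amount[0, 0] == 0.0
        assert qm.clamped[0, 0]

    def test_below_noise_pixels_undefined(self):
        img = self.corrected([[3.3, 3.3]])
        mask = np.array([[True, False]])
        qm = calibrate.quantify(img, self.FIT, mask)
        assert np.isnan(qm.amount[0, 1])

    def test_envelope_brackets_estimate(self):
        rng = np.random.default_rng(0)
        img = self.corrected(rng.uniform(0.3, 8.0, (6, 6)))
        qm = calibrate.quantify(img, self.FIT, np.ones((6, 6), dtype=bool))
        assert np.all(qm.amount_lo <= qm.amount)
        assert np.all(qm.amount <= qm.amount_hi)

    def test_round_trip_from_fit_is_exact(self):
        """Signals generated from the fitted line invert to the original
        amounts exactly in the noise-free limit."""
        amounts = np.array([[0.1, 0.5], [1.0, 2.4]])
        img = self.corrected(self.FIT.intercept + self.FIT.slope * amounts)
        qm = calibrate.quantify(img, self.FIT, np.ones((2, 2), dtype=bool))
        np.testing.assert_allclose(qm.amount, amounts, atol=1e-12)

    def test_nonpositive_slope_rejected(self):
        bad = replace(self.FIT, slope=0.0)
        with pytest.raises(ValueError):
            calibrate.quantify(self.corrected([[1.0]]), bad,
                               np.ones((1, 1), dtype=bool))
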