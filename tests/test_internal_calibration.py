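"""CH2 homologous-series detection and internal recalibration."""

import numpy as np
import pytest

from fticrms.internal_calibration import (
    CH2,
    CalibrationModel,
    apply_calibration,
    calibrate_sample,
    find_series,
    fit_calibration,
)
from fticrms.peaklist_io import SamplePeakList
from fticrms.synthetic_data import SyntheticSpec, generate_sample

CH2_MASS = 14.015650


class TestFindSeries:
    def test_exact_ladder_detected_whole(self):
        mz = [200.0 + k * CH2_MASS for k in range(4)]
        series = find_series(np.array(mz), tol_ppm=1.0)
        assert len(series) == 1
        assert len(series[0]) == 4

    def test_wrong_spacings_yield_nothing(self):
        assert find_series(np.array([200.0, 215.0, 231.0])) == []

    def test_perturbed_member_splits_chain(self):
        mz = [200.0 + k * CH2_MASS for k in range(6)]
        mz[3] *= 1 + 5e-6  # +5 ppm outlier breaks the ladder
        series = find_series(np.array(mz), tol_ppm=1.0)
        lengths = sorted(len(s) for s in series)
        assert lengths == [3]  # head segment survives; tail is too short

    def test_chains_shorter_than_three_discarded(self):
        assert find_series(np.array([200.0, 200.0 + CH2_MASS])) == []

    def test_kendrick_defect_constant_along_series(self):
        mz = [311.16857 + k * CH2_MASS for k in range(5)]
        (ser,) = find_series(np.array(mz))
        exact, nominal = CH2.mass, 14
        km = np.asarray(mz) * nominal / exact
        defects = np.round(km) - km
        assert np.ptp(defects) < 5e-3
        assert ser.kendrick_defect == pytest.approx(defects[0], abs=1e-9)


class TestFitCalibration:
    def test_uniform_offset_recovered_as_intercept(self):
        ref = np.array([200.0, 400.0, 600.0, 800.0])
        obs = ref * (1 + 3e-6)
        model = fit_calibration(obs, ref)
        assert model.intercept == pytest.approx(3.0, abs=1e-6)
        assert model.slope == pytest.approx(0.0, abs=1e-8)
        assert model.residual_rms_ppm < 1e-6

    def test_exact_calibrants_give_identity_model(self):
        ref = np.array([200.0, 500.0, 900.0])
        model = fit_calibration(ref, ref)
        assert model.intercept == pytest.approx(0.0, abs=1e-4)
        assert model.slope == pytest.approx(0.0, abs=1e-7)

    def test_two_point_linear_drift_recovered_at_endpoints(self):
        ref = np.array([200.0, 1000.0])
        err = np.array([2.0, 6.0])
        obs = ref * (1 + err * 1e-6)
        model = fit_calibration(obs, ref)
        for mz_val, e in zip(obs, err):
            assert model.error_ppm(mz_val) == pytest.approx(e, abs=0.1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([300.0], [300.0])
        with pytest.raises(ValueError):
            fit_calibration([300.0, 300.0], [300.0, 300.0])

    def test_fit_never_increases_residual_rms(self):
        rng = np.random.default_rng(5)
        ref = np.sort(rng.uniform(150, 900, 30))
        obs = ref * (1 + (1.0 + 0.002 * ref + rng.normal(0, 0.2, 30)) * 1e-6)
        model = fit_calibration(obs, ref)
        assert model.residual_rms_ppm <= model.prefit_rms_ppm


class TestApplyCalibration:
    def test_identity_model_changes_nothing(self):
        sample = SamplePeakList.from_arrays("s", [200.0, 300.0])
        out = apply_calibration(sample, CalibrationModel.identity())
        assert list(out.mz) == [200.0, 300.0]

    def test_flat_three_ppm_correction(self):
        sample = SamplePeakList.from_arrays("s", [300.0])
        out = apply_calibration(sample, CalibrationModel(slope=0.0, intercept=3.0))
        assert out.mz[0] == pytest.approx(299.999100, abs=1e-6)

    def test_order_and_intensities_preserved(self):
        sample = SamplePeakList.from_arrays("s", [200.0, 500.0, 800.0], [1, 2, 3], [7, 8, 9])
        out = apply_calibration(sample, CalibrationModel(slope=0.004, intercept=-2.0))
        assert list(out.mz) == sorted(out.mz)
        assert list(out.intensity) == [1, 2, 3]
        assert list(out.sn) == [7, 8, 9]


class TestEndToEndCalibration:
    def test_accurate_sample_calibrates_to_identity(self):
        spec = SyntheticSpec(
            seed=11, n_compounds=200, jitter_ppm=0.0, n_series=6, contaminant_fraction=0.0
        )
        peaks, truth = generate_sample(spec)
        cal, report = calibrate_sample(peaks)
        err = (cal.mz - truth["true_mz"].to_numpy()) / truth["true_mz"].to_numpy() * 1e6
        assert float(np.sqrt(np.mean(err**2))) < 1e-4

    def test_five_ppm_drift_reduced_below_half_ppm(self):
        spec = SyntheticSpec(
            seed=3,
            n_compounds=300,
            jitter_ppm=0.2,
            drift_a=5.0,
            n_series=8,
            contaminant_fraction=0.0,
        )
        peaks, truth = generate_sample(spec)
        cal, report = calibrate_sample(peaks)
        true_mz = truth["true_mz"].to_numpy()
        err = (cal.mz - true_mz) / true_mz * 1e6
        assert float(np.sqrt(np.mean(err**2))) < 0.5
        assert float(np.median(np.abs(err))) < 0.5
        assert report.n_series >= 6

    def test_mass_dependent_drift_also_removed(self):
        spec = SyntheticSpec(
            seed=4,
            n_compounds=300,
            jitter_ppm=0.2,
            drift_a=2.0,
            drift_b=0.004,
            n_series=8,
            contaminant_fraction=0.0,
        )
        peaks, truth = generate_sample(spec)
        cal, _ = calibrate_sample(peaks)
        true_mz = truth["true_mz"].to_numpy()
        err = (cal.mz - true_mz) / true_mz * 1e6
        assert float(np.sqrt(np.mean(err**2))) < 0.5

    def test_calibration_never_reorders_peaks(self):
        spec = SyntheticSpec(seed=5, n_compounds=150, n_series=5, contaminant_fraction=0.0)
        peaks, _ = generate_sample(spec)
        cal, _ = calibrate_sample(peaks)
        assert list(cal.mz) == sorted(cal.mz)

    def test_sample_without_series_returned_unchanged(self):
        sample = SamplePeakList.from_arrays("s", [200.0, 215.0, 260.0])
        cal, report = calibrate_sample(sample)
        assert list(cal.mz) == [200.0, 215.0, 260.0]
        assert report.n_calibrants < 2
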