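"""Formula-level checks: sorting, tension, radius, calibrations, time courses.

Hand-evaluated expectations are computed independently of the implementation
(plain arithmetic in the test) before being asserted.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubesort.biophysics import (
    CalibrationSet,
    DensityCalibration,
    LowSignalError,
    SortingResult,
    fit_ktub,
    label_surface_density,
    membrane_tension,
    radius_from_force,
    sorting_ratio,
    surface_density,
    timecourse_analysis,
    tube_radius_from_fluorescence,
)
from tubesort.imaging import IntensityMeasurement
from tubesort.synthetic import generate_calibration_pulls


def meas(pt, mt, pg, mg):
    return IntensityMeasurement(
        I_prot_tube=pt, I_mem_tube=mt, I_prot_guv=pg, I_mem_guv=mg
    )


class TestSortingRatio:
    def test_hand_evaluated_case(self):
        assert sorting_ratio(meas(200, 100, 50, 100)) == pytest.approx(4.0)

    def test_equal_ratios_give_unity(self):
        assert sorting_ratio(meas(30, 60, 15, 30)) == pytest.approx(1.0)

    def test_zero_tube_protein_gives_zero(self):
        assert sorting_ratio(meas(0, 100, 50, 100)) == 0.0

    @pytest.mark.parametrize("bad", [(10, 0, 5, 5), (10, 5, -1, 5), (10, 5, 5, 0)])
    def test_nonpositive_denominator_flagged(self, bad):
        with pytest.raises(LowSignalError):
            sorting_ratio(meas(*bad))

    @settings(max_examples=50, deadline=None)
    @given(
        i=st.tuples(*[st.floats(1.0, 1e4) for _ in range(4)]),
        g_prot=st.floats(0.01, 100.0),
        g_mem=st.floats(0.01, 100.0),
    )
    def test_gain_invariance(self, i, g_prot, g_mem):
        """Independent rescaling of the two channels cancels in S."""
        pt, mt, pg, mg = i
        s0 = sorting_ratio(meas(pt, mt, pg, mg))
        s1 = sorting_ratio(meas(pt * g_prot, mt * g_mem, pg * g_prot, mg * g_mem))
        assert s1 == pytest.approx(s0, rel=1e-9)


class TestRadiusFromFluorescence:
    def test_unit_ratio(self):
        assert tube_radius_from_fluorescence(meas(1, 100, 1, 100), 200.0) == 200.0

    def test_quarter_ratio(self):
        assert tube_radius_from_fluorescence(meas(1, 25, 1, 100), 200.0) == 50.0

    def test_bad_inputs(self):
        with pytest.raises(LowSignalError):
            tube_radius_from_fluorescence(meas(1, 0, 1, 100), 200.0)
        with pytest.raises(ValueError):
            tube_radius_from_fluorescence(meas(1, 25, 1, 100), -1.0)


class TestTensionAndForce:
    def test_zero_pressure_zero_tension(self):
        assert membrane_tension(0.0, 2.0, 10.0) == 0.0

    def test_hand_evaluated_tension(self):
        # sigma = 100 Pa * 2e-6 m / 2 * (1 - 0.2) = 8.0e-5 N/m
        assert membrane_tension(100.0, 2.0, 10.0) == pytest.approx(8.0e-5)

    def test_tension_linear_in_pressure(self):
        assert membrane_tension(200.0, 2.0, 10.0) == pytest.approx(
            2 * membrane_tension(100.0, 2.0, 10.0)
        )

    def test_undefined_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            membrane_tension(100.0, 10.0, 10.0)

    def test_zero_force_zero_radius(self):
        assert radius_from_force(0.0, 8e-5) == 0.0

    def test_hand_evaluated_radius(self):
        # R = 10e-12 N / (4 pi 8e-5 N/m) = 9.947e-9 m
        expect = 10e-12 / (4 * math.pi * 8e-5) * 1e9
        assert radius_from_force(10.0, 8.0e-5) == pytest.approx(expect)
        assert expect == pytest.approx(9.95, abs=0.01)

    def test_inverse_proportionality(self):
        assert radius_from_force(10.0, 1.6e-4) == pytest.approx(
            radius_from_force(10.0, 8e-5) / 2
        )

    def test_dimensional_consistency(self):
        """F = 4 pi sigma * (1 nm) must invert to exactly R = 1 nm."""
        sigma = 3.3e-5
        F_pN = 4 * math.pi * sigma * 1e-9 * 1e12
        assert radius_from_force(F_pN, sigma) == pytest.approx(1.0, rel=1e-12)


class TestKtubFit:
    def test_noiseless_round_trip_machine_precision(self):
        cal = generate_calibration_pulls(20, k_tub_true_nm=200.0, seed=0)
        fit = fit_ktub(cal)
        assert fit.k_tub_nm == pytest.approx(200.0, rel=1e-10)
        assert abs(fit.intercept_nm) < 1e-8
        assert fit.r_squared == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(50.0, 500.0), seed=st.integers(0, 1000))
    def test_round_trip_any_ktub(self, k, seed):
        cal = generate_calibration_pulls(10, k_tub_true_nm=k, seed=seed)
        assert fit_ktub(cal).k_tub_nm == pytest.approx(k, rel=1e-9)

    def test_two_points_exact_interpolation(self):
        cal = generate_calibration_pulls(2, k_tub_true_nm=120.0, seed=1)
        assert fit_ktub(cal).k_tub_nm == pytest.approx(120.0, rel=1e-10)

    def test_noisy_recovery_within_5_percent(self):
        cal = generate_calibration_pulls(50, 200.0, noise=0.05, seed=2)
        assert fit_ktub(cal).k_tub_nm == pytest.approx(200.0, rel=0.05)

    def test_through_origin_option(self):
        cal = generate_calibration_pulls(20, 200.0, seed=3)
        fit = fit_ktub(cal, through_origin=True)
        assert fit.k_tub_nm == pytest.approx(200.0, rel=1e-10)
        assert fit.intercept_nm == 0.0

    def test_rank_deficient_rejected(self):
        rec = pd.DataFrame(
            {
                "dP_Pa": [100.0, 100.0],
                "r_pip_um": [2.0, 2.0],
                "r_guv_um": [10.0, 10.0],
                "F_pN": [10.0, 10.0],
                "ratio": [0.5, 0.5],
            }
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_ktub(CalibrationSet(rec))


class TestSurfaceDensity:
    def test_reference_label_density(self):
        # 2 leaflets * 0.003 / 0.7 nm^2 = 8.571e-3 nm^-2 = 8.571e3 um^-2
        expect = 2 * 0.003 / 0.7 * 1e6
        assert label_surface_density(0.003) == pytest.approx(expect)
        assert expect == pytest.approx(8.57e3, rel=1e-3)

    def test_zero_intensity_zero_density(self):
        cal = DensityCalibration(1.0, 1.0, 1.0)
        assert surface_density(0.0, cal) == 0.0

    def test_slope_ratio_correction_and_dimers(self):
        cal = DensityCalibration(
            guv_intensity_vs_density=0.5,
            slope_protein_fluor=2.0,
            slope_lipid_fluor=1.0,
        )
        assert surface_density(100.0, cal) == pytest.approx(100.0 / 0.5 * 0.5)
        assert surface_density(100.0, cal, per_dimer=True) == pytest.approx(50.0)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            DensityCalibration(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            DensityCalibration(1.0, 1.0, 1.0, leaflet_factor=3)


def series(phis, radii, times=None):
    times = times if times is not None else list(range(len(phis)))
    return [
        SortingResult(S=np.nan, R_nm=r, phi_tube=p, timestamp_s=float(t))
        for p, r, t in zip(phis, radii, times)
    ]


class TestTimecourseAnalysis:
    def test_constant_series_is_flat(self):
        rec = timecourse_analysis(series([500] * 6, [40] * 6))
        assert rec.slope_phi_per_nm == 0.0
        assert "flat" in rec.flags

    def test_ramp_endpoints_and_negative_slope(self):
        phis = np.linspace(600, 1700, 12)
        radii = np.linspace(50, 25, 12)
        rec = timecourse_analysis(series(phis, radii))
        assert rec.phi_initial == pytest.approx(phis[:3].mean())
        assert rec.phi_final == pytest.approx(phis[-3:].mean())
        assert rec.slope_phi_per_nm < 0

    def test_constant_radius_flagged_infinite(self):
        phis = [100, 400, 900, 1600, 2500, 3600]
        rec = timecourse_analysis(series(phis, [40] * 6))
        assert math.isinf(rec.slope_phi_per_nm) and rec.slope_phi_per_nm > 0
        assert "constant-radius" in rec.flags
        assert rec.phi_initial == pytest.approx(np.mean(phis[:3]))
        assert rec.phi_final == pytest.approx(np.mean(phis[-3:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            timecourse_analysis(series([100], [40]))

    def test_unordered_timestamps_are_sorted(self):
        rec = timecourse_analysis(
            series([300, 100, 200], [30, 50, 40], times=[2, 0, 1]),
            head_window=1,
            tail_window=1,
        )
        assert rec.phi_initial == 100 and rec.phi_final == 300
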