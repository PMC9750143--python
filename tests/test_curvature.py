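"""Fourier height field, shape-operator curvature, sampling, insertion depth."""

import math

import numpy as np
import pytest

from tubesort.curvature import (
    EmptySampleError,
    MembraneSurface,
    fit_membrane_profile,
    insertion_depth,
    sample_probe_curvature,
    true_mean_curvature_1d,
)
from tubesort.synthetic import BuckleGroundTruth, generate_buckled_membrane

A, LX, LY = 3.0, 63.0, 28.0


def sine_points(n=3000, amplitude=A, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, LX, n)
    y = rng.uniform(0, LY, n)
    z = amplitude * np.sin(2 * np.pi * x / LX) + rng.normal(0, jitter, n) * (
        jitter > 0
    )
    return np.column_stack([x, y, z])


def fd_mean_curvature(surface, x, y, h=1e-3):
    """Independent central-finite-difference shape operator."""
    f = surface.height
    hx = (f(x + h, y) - f(x - h, y)) / (2 * h)
    hy = (f(x, y + h) - f(x, y - h)) / (2 * h)
    hxx = (f(x + h, y) - 2 * f(x, y) + f(x - h, y)) / h**2
    hyy = (f(x, y + h) - 2 * f(x, y) + f(x, y - h)) / h**2
    hxy = (
        f(x + h, y + h) - f(x + h, y - h) - f(x - h, y + h) + f(x - h, y - h)
    ) / (4 * h**2)
    return -((1 + hy**2) * hxx - 2 * hx * hy * hxy + (1 + hx**2) * hyy) / (
        2 * (1 + hx**2 + hy**2) ** 1.5
    )


class TestSurfaceFit:
    def test_exact_sine_reproduced_to_machine_precision(self):
        surf = MembraneSurface.fit(sine_points(), (LX, LY), orders=(2, 1))
        xg = np.linspace(0, LX, 40)
        yg = np.full_like(xg, LY / 3)
        np.testing.assert_allclose(
            surf.height(xg, yg), A * np.sin(2 * np.pi * xg / LX), atol=1e-10
        )
        assert surf.residual_rms < 1e-10

    def test_flat_jittered_sheet(self):
        pts = sine_points(amplitude=0.0, jitter=0.3, seed=1)
        surf = MembraneSurface.fit(pts, (LX, LY))
        assert np.all(np.abs(surf.coefficients[1:]) < 0.1)
        assert surf.residual_rms == pytest.approx(0.3, rel=0.15)

    def test_jittered_sine_recovers_height_field(self):
        pts = sine_points(n=4000, jitter=0.3, seed=2)
        surf = MembraneSurface.fit(pts, (LX, LY))
        xg = np.linspace(0, LX, 50)
        err = surf.height(xg, np.full_like(xg, LY / 2)) - A * np.sin(
            2 * np.pi * xg / LX
        )
        assert np.abs(err).max() < 0.15  # jitter-limited

    def test_periodicity(self):
        surf = MembraneSurface.fit(sine_points(), (LX, LY))
        assert surf.height(1.3, 2.0) == pytest.approx(
            surf.height(1.3 + LX, 2.0 + LY), rel=1e-12
        )

    def test_underdetermined_and_degenerate_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            MembraneSurface.fit(sine_points(n=10), (LX, LY), orders=(6, 2))
        with pytest.raises(ValueError, match="box"):
            MembraneSurface.fit(sine_points(), (0.0, LY))

    def test_residual_never_increases_with_order(self):
        pts = sine_points(n=2000, jitter=0.3, seed=3)
        rms = [
            MembraneSurface.fit(pts, (LX, LY), orders=(nx, ny)).residual_rms
            for nx, ny in [(1, 0), (2, 1), (4, 2), (6, 2), (8, 3)]
        ]
        assert all(b <= a + 1e-12 for a, b in zip(rms, rms[1:]))


class TestMeanCurvature:
    def test_flat_surface_zero_everywhere(self):
        pts = sine_points(amplitude=0.0)
        surf = MembraneSurface.fit(pts, (LX, LY))
        rng = np.random.default_rng(0)
        H = surf.mean_curvature(rng.uniform(0, LX, 200), rng.uniform(0, LY, 200))
        assert np.abs(H).max() < 1e-6

    def test_crest_matches_closed_form(self):
        surf = MembraneSurface.fit(sine_points(), (LX, LY))
        crest = surf.mean_curvature(LX / 4, LY / 2)
        assert crest == pytest.approx(2 * math.pi**2 * A / LX**2, rel=1e-9)
        assert crest > 0  # crest bulges toward the binding side

    def test_closed_form_profile_everywhere(self):
        surf = MembraneSurface.fit(sine_points(), (LX, LY))
        x = np.linspace(0, LX, 30)
        np.testing.assert_allclose(
            surf.mean_curvature(x, np.full_like(x, 5.0)),
            true_mean_curvature_1d(x, A, LX),
            atol=1e-9,
        )

    def test_agrees_with_finite_difference_oracle(self):
        pts = sine_points(n=3000, jitter=0.3, seed=4)
        surf = MembraneSurface.fit(pts, (LX, LY))
        rng = np.random.default_rng(1)
        for _ in range(100):
            x, y = rng.uniform(0, LX), rng.uniform(0, LY)
            assert surf.mean_curvature(x, y) == pytest.approx(
                fd_mean_curvature(surf, x, y), abs=1e-4
            )

    def test_translation_and_offset_invariance(self):
        pts = sine_points()
        surf = MembraneSurface.fit(pts, (LX, LY))
        shifted = pts.copy()
        shifted[:, 0] = (shifted[:, 0] + 11.0) % LX
        shifted[:, 2] += 5.0  # constant height offset
        surf2 = MembraneSurface.fit(shifted, (LX, LY))
        x, y = 7.3, 12.1
        assert surf2.mean_curvature((x + 11.0) % LX, y) == pytest.approx(
            surf.mean_curvature(x, y), abs=1e-9
        )

    def test_mean_curvature_integrates_to_zero_over_period(self):
        surf = MembraneSurface.fit(sine_points(), (LX, LY))
        x = np.linspace(0, LX, 2001)
        H = surf.mean_curvature(x, np.full_like(x, LY / 2))
        assert abs(np.trapezoid(H, x)) < 1e-6


class TestCurvatureSampling:
    def test_unbiased_probe_indistinguishable_from_random(self):
        gt = BuckleGroundTruth(probe_bias_nm=0.0, n_frames=330, lipid_count=400, seed=7)
        traj = generate_buckled_membrane(gt)
        cs = sample_probe_curvature(traj, equilibration_cut_ns=330.0, seed=8)
        assert cs.ks_pvalue > 0.05
        assert abs(cs.mean_shift) < 0.002

    def test_bias_shifts_probe_mean_monotonically(self):
        shifts = []
        for bias in (30.0, 100.0, 300.0):
            gt = BuckleGroundTruth(
                probe_bias_nm=bias, n_frames=230, lipid_count=400, seed=11
            )
            traj = generate_buckled_membrane(gt)
            cs = sample_probe_curvature(traj, equilibration_cut_ns=230.0, seed=12)
            shifts.append(cs.mean_shift)
        assert shifts[0] > 0
        assert shifts[0] < shifts[1] < shifts[2]

    def test_histograms_are_normalised(self, small_buckle):
        _, traj = small_buckle
        cs = sample_probe_curvature(traj, seed=1)
        assert cs.hist_probe.sum() == pytest.approx(1.0)
        assert cs.hist_random.sum() == pytest.approx(1.0)

    def test_equilibration_gating(self, small_buckle):
        gt, traj = small_buckle
        total = gt.n_frames * gt.frame_interval_ns
        with pytest.raises(EmptySampleError):
            sample_probe_curvature(traj, equilibration_cut_ns=total)

    def test_sampling_interval_thins_frames(self, small_buckle):
        gt, traj = small_buckle
        cs_all = sample_probe_curvature(traj, seed=1)
        cs_thin = sample_probe_curvature(
            traj, sampling_interval_ns=3 * gt.frame_interval_ns, seed=1
        )
        assert len(cs_thin.probe_H) < len(cs_all.probe_H)


class TestInsertionDepth:
    def test_probe_at_phosphate_level(self):
        gt = BuckleGroundTruth(
            probe_depth_nm=0.0, probe_depth_sd_nm=0.0, height_jitter_nm=0.0,
            amplitude_nm=0.0, n_frames=30, seed=2,
        )
        prof = insertion_depth(generate_buckled_membrane(gt))
        assert prof.mean_offset_nm == pytest.approx(0.0, abs=0.02)
        assert prof.depth_fraction_percent == pytest.approx(0.0, abs=1.0)

    def test_hand_evaluated_depth_fraction(self):
        from tubesort.curvature import InsertionDepthProfile

        prof = InsertionDepthProfile(np.full(10, -0.4), 2.0)
        assert prof.depth_fraction_percent == pytest.approx(-20.0)

    def test_generator_imposed_offset_recovered(self):
        gt = BuckleGroundTruth(probe_depth_nm=-0.4, n_frames=300, seed=5)
        prof = insertion_depth(generate_buckled_membrane(gt))
        assert prof.mean_offset_nm == pytest.approx(-0.4, rel=0.05)

    def test_no_neighbours_raises(self, small_buckle):
        _, traj = small_buckle
        with pytest.raises(EmptySampleError):
            insertion_depth(traj, neighbour_radius_nm=1e-6)
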