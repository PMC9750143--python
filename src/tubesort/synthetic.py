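"""Ground-truthed synthetic inputs for every pipeline stage.

Two families of generators:

* **Imaging** — two-channel confocal-like frames of a GUV (equatorial
  optical section, rendered as a bright ring) with a pulled nanotube
  (a dim, slightly tilted line).  Structures are idealised as infinitely
  thin curves convolved with an isotropic Gaussian PSF, so per-pixel
  intensity is amplitude x exp(-d^2 / 2 sigma^2) with d the distance to the
  curve.  The tube's membrane amplitude encodes its radius linearly
  (thin-tube limit): amplitude ratio tube/GUV = R / k_tub.  The protein
  channel is the membrane geometry scaled by labelled-protein density and,
  on the tube, by the imposed sorting ratio.  Optional Poisson or Gaussian
  noise on top of a camera offset.

* **Buckled membranes** — lipid-headgroup point clouds on the surface
  z = A sin(2 pi x / Lx) in a periodic box, with thermal height jitter, a
  lower leaflet offset by the monolayer thickness, and a probe whose x
  positions are drawn with weight exp(bias * H_true(x)).  bias = 0 gives a
  probe statistically identical to a random lipid; bias > 0 concentrates
  the probe at positively curved regions (crests, bulging toward the
  binding side +z).

Calibration tables (aspiration pulls, bulk fluorophore standard curves,
dye-lipid density standards) complete the set.  Every generator takes all
randomness from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biophysics import (
    CalibrationSet,
    label_surface_density,
    membrane_tension,
)
from .curvature import BuckleFrame, BuckleTrajectory, true_mean_curvature_1d
from .imaging import TubeFrame

__all__ = [
    "ImagingGroundTruth",
    "BuckleGroundTruth",
    "generate_tube_frame",
    "generate_guv_frame",
    "generate_timecourse",
    "make_induction_schedule",
    "generate_calibration_pulls",
    "generate_standard_curves",
    "generate_density_standard_frames",
    "generate_buckled_membrane",
]


# ---------------------------------------------------------------------------
# imaging ground truth


@dataclass(frozen=True)
class ImagingGroundTruth:
    """All parameters of one synthetic GUV + tube frame.

    Lengths: tube radius in nm, GUV radius in um, pixel size and PSF sigma
    in nm.  ``sorting`` is the imposed sorting ratio S >= 0, ``density_guv``
    the labelled-protein density on the GUV (um^-2).  ``k_tub_nm`` is the
    constant by which the generator encodes radius into the tube/GUV
    membrane amplitude ratio, i.e. the ground-truth calibration constant.
    """

    tube_radius_nm: float = 50.0
    guv_radius_um: float = 10.0
    sorting: float = 4.0
    density_guv: float = 1000.0
    label_fraction: float = 0.003
    pixel_size_nm: float = 100.0
    psf_sigma_nm: float = 120.0
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_scale: float = 1.0
    seed: int = 0
    # rendering details
    k_tub_nm: float = 200.0
    tube_length_um: float = 10.0
    tube_tilt_deg: float = 2.0
    membrane_peak: float = 2000.0
    protein_intensity_per_density: float = 0.5  # counts per um^-2
    brightness_protein: float = 1.0
    brightness_dye: float = 0.6
    offset: float = 100.0
    timestamp_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tube_radius_nm <= 0:
            raise ValueError("tube radius must be positive")
        if self.guv_radius_um <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("all lengths must be positive")
        if self.tube_radius_nm >= 0.1 * self.guv_radius_um * 1e3:
            raise ValueError("tube radius must be << GUV radius")
        if self.sorting < 0:
            raise ValueError("sorting must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0 <= self.label_fraction <= 1:
            raise ValueError("label_fraction is a mole fraction")


def _segment_distance(xx, yy, p0, p1):
    """Euclidean distance from each pixel to the segment p0-p1."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    t = ((xx - p0[0]) * vx + (yy - p0[1]) * vy) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(xx - (p0[0] + t * vx), yy - (p0[1] + t * vy))


def _apply_noise(clean: np.ndarray, gt: ImagingGroundTruth, rng) -> np.ndarray:
    if gt.noise_model == "none":
        return clean.copy()
    if gt.noise_model == "poisson":
        lam = np.clip(clean * gt.noise_scale, 0, None)
        return rng.poisson(lam).astype(float) / gt.noise_scale
    noisy = clean + rng.normal(0.0, gt.noise_scale, clean.shape)
    return np.clip(noisy, 0.0, None)


def _render(
    gt: ImagingGroundTruth,
    include_tube: bool,
    protein_guv_amp: float,
    shape: Optional[tuple[int, int]] = None,
    rng=None,
    timestamp_s: Optional[float] = None,
    frame_id: Optional[str] = None,
) -> TubeFrame:
    px = gt.pixel_size_nm
    sigma_px = gt.psf_sigma_nm / px
    r_px = gt.guv_radius_um * 1e3 / px
    tube_len_px = gt.tube_length_um * 1e3 / px
    margin = 20.0
    cx, cy = margin + r_px, margin + r_px
    if shape is None:
        ny = int(round(2 * (r_px + margin)))
        nx = int(round(cx + r_px + tube_len_px + margin))
    else:
        ny, nx = shape
    tilt = math.radians(gt.tube_tilt_deg)
    p0 = (cx + r_px, cy)
    p1 = (p0[0] + tube_len_px * math.cos(tilt), cy - tube_len_px * math.sin(tilt))
    if include_tube and (p1[0] > nx - 2 or p1[1] < 1):
        raise ValueError("tube extends beyond the image extent")

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    d_ring = np.abs(np.hypot(xx - cx, yy - cy) - r_px)
    g_ring = np.exp(-0.5 * (d_ring / sigma_px) ** 2)

    rel_tube = gt.tube_radius_nm / gt.k_tub_nm
    mem = gt.membrane_peak * g_ring
    prot = protein_guv_amp * g_ring
    if include_tube:
        g_tube = np.exp(-0.5 * (_segment_distance(xx, yy, p0, p1) / sigma_px) ** 2)
        mem = mem + gt.membrane_peak * rel_tube * g_tube
        prot = prot + protein_guv_amp * gt.sorting * rel_tube * g_tube

    clean_mem = mem + gt.offset
    clean_prot = prot + gt.offset
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    meta = {
        "ground_truth": gt,
        "clean_membrane": clean_mem,
        "clean_protein": clean_prot,
        "frame_id": frame_id,
        "geometry": {
            "guv_center_px": (cy, cx),
            "guv_radius_px": r_px,
            "psf_sigma_px": sigma_px,
            "tube_start_px": p0,
            "tube_end_px": p1,
            "has_tube": include_tube,
        },
    }
    return TubeFrame(
        membrane_channel=_apply_noise(clean_mem, gt, rng),
        protein_channel=_apply_noise(clean_prot, gt, rng),
        pixel_size_nm=px,
        timestamp_s=gt.timestamp_s if timestamp_s is None else timestamp_s,
        meta=meta,
    )


def generate_tube_frame(
    gt: ImagingGroundTruth,
    shape: Optional[tuple[int, int]] = None,
    rng=None,
) -> TubeFrame:
    """Render one GUV + tube frame from its ground truth.

    The protein-channel GUV amplitude is
    ``protein_intensity_per_density * density_guv``; tube amplitudes carry
    the extra factors ``sorting`` (protein) and ``R / k_tub`` (both
    channels, the projected membrane area per pixel in the thin-tube
    limit).  Noise-free output is reproducible bit-for-bit.
    """
    amp = gt.protein_intensity_per_density * gt.density_guv
    return _render(gt, True, amp, shape=shape, rng=rng)


def generate_guv_frame(
    gt: ImagingGroundTruth,
    protein_guv_amp: Optional[float] = None,
    rng=None,
    frame_id: Optional[str] = None,
) -> TubeFrame:
    """Render a GUV-only frame (no tube), e.g. for density standards."""
    if protein_guv_amp is None:
        protein_guv_amp = gt.protein_intensity_per_density * gt.density_guv
    return _render(gt, False, protein_guv_amp, rng=rng, frame_id=frame_id)


# ---------------------------------------------------------------------------
# time courses


def generate_timecourse(
    gt_series: Sequence[ImagingGroundTruth],
    rng=None,
) -> list[TubeFrame]:
    """Render a frame sequence from per-frame ground truths.

    The tube protein density (sorting x GUV density) must be monotone
    non-decreasing across the series — the protein diffuses onto the tube
    from the GUV reservoir and approaches equilibrium, it does not unbind
    on this time scale.  All frames draw noise from one generator seeded by
    the first frame's seed.
    """
    gt_series = list(gt_series)
    if not gt_series:
        raise ValueError("empty ground-truth series")
    dens = [g.sorting * g.density_guv for g in gt_series]
    if any(b < a * (1 - 1e-9) for a, b in zip(dens, dens[1:])):
        raise ValueError("tube protein density must be monotone non-decreasing")
    if rng is None:
        rng = np.random.default_rng(gt_series[0].seed)
    frames = []
    for i, g in enumerate(gt_series):
        t = g.timestamp_s if g.timestamp_s is not None else float(i)
        frames.append(
            _render(
                g,
                True,
                g.protein_intensity_per_density * g.density_guv,
                rng=rng,
                timestamp_s=t,
                frame_id=f"frame{i:03d}",
            )
        )
    return frames


def make_induction_schedule(
    n_frames: int = 40,
    duration_s: float = 78.0,
    phi_tube: tuple[float, float] = (600.0, 1700.0),
    radius_nm: tuple[float, float] = (50.0, 25.0),
    phi_guv: float = 300.0,
    shape: str = "linear",
    seed: int = 0,
    **gt_kwargs,
) -> list[ImagingGroundTruth]:
    """Coupled density-up / radius-down schedule for an induction run.

    Defaults mimic a tube whose protein density climbs from ~600 to ~1700
    per um^2 while the radius drops from 50 to 25 nm over ~80 s.  ``shape``
    is ``"linear"`` or ``"saturating"`` (exponential approach to the final
    value with time constant duration/3).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    t = np.linspace(0.0, duration_s, n_frames)
    if shape == "linear":
        u = t / duration_s if duration_s > 0 else np.zeros_like(t)
    elif shape == "saturating":
        tau = duration_s / 3.0
        u = (1 - np.exp(-t / tau)) / (1 - math.exp(-duration_s / tau))
    else:
        raise ValueError("shape must be 'linear' or 'saturating'")
    phis = phi_tube[0] + (phi_tube[1] - phi_tube[0]) * u
    radii = radius_nm[0] + (radius_nm[1] - radius_nm[0]) * u
    return [
        ImagingGroundTruth(
            tube_radius_nm=float(r),
            sorting=float(p / phi_guv),
            density_guv=phi_guv,
            seed=seed,
            timestamp_s=float(ti),
            **gt_kwargs,
        )
        for r, p, ti in zip(radii, phis, t)
    ]


# ---------------------------------------------------------------------------
# calibration tables


def generate_calibration_pulls(
    n: int,
    k_tub_true_nm: float = 200.0,
    noise: float = 0.0,
    seed: int = 0,
    radius_range_nm: tuple[float, float] = (20.0, 150.0),
) -> CalibrationSet:
    """Aspiration-pull records for the k_tub regression.

    Pipette/GUV radii and aspiration pressures are drawn from plausible
    experimental ranges; the tube radius is drawn from ``radius_range_nm``;
    tension follows from aspiration, the trap force is back-computed as
    ``F = 4 pi sigma R``, and the fluorescence ratio is ``R / k_tub_true``
    with multiplicative Gaussian noise of relative s.d. ``noise``.
    """
    if n < 2:
        raise ValueError("need at least 2 pull records")
    if k_tub_true_nm <= 0:
        raise ValueError("k_tub_true must be positive")
    rng = np.random.default_rng(seed)
    r_pip = rng.uniform(1.0, 3.0, n)
    r_guv = rng.uniform(6.0, 15.0, n)
    dP = rng.uniform(20.0, 200.0, n)
    R = np.linspace(*radius_range_nm, n) if noise == 0 else rng.uniform(
        *radius_range_nm, n
    )
    sigma = np.array(
        [membrane_tension(p, rp, rg) for p, rp, rg in zip(dP, r_pip, r_guv)]
    )
    F_pN = 4.0 * math.pi * sigma * (R * 1e-9) * 1e12
    ratio = R / k_tub_true_nm
    if noise > 0:
        ratio = ratio * (1.0 + noise * rng.standard_normal(n))
    ratio = np.clip(ratio, 1e-6, None)
    records = pd.DataFrame(
        {
            "dP_Pa": dP,
            "r_pip_um": r_pip,
            "r_guv_um": r_guv,
            "F_pN": F_pN,
            "ratio": ratio,
        }
    )
    return CalibrationSet(records)


def generate_standard_curves(
    brightness_protein: float = 1.0,
    brightness_dye: float = 0.6,
    n_points: int = 8,
    max_conc_uM: float = 10.0,
    counts_per_uM: float = 50.0,
    noise: float = 0.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Bulk-solution serial-dilution standard curves for the two fluorophores.

    Returns ``{"protein": df, "lipid_dye": df}`` with columns
    ``concentration_uM, intensity``; the slope ratio encodes the relative
    brightness used by the density-calibration correction.
    """
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.0, max_conc_uM, n_points)
    out = {}
    for name, b in (("protein", brightness_protein), ("lipid_dye", brightness_dye)):
        inten = counts_per_uM * b * conc
        if noise > 0:
            inten = inten + noise * counts_per_uM * b * max_conc_uM * rng.standard_normal(
                n_points
            )
        out[name] = pd.DataFrame(
            {"concentration_uM": conc, "intensity": np.clip(inten, 0, None)}
        )
    return out


def generate_density_standard_frames(
    fractions: Sequence[float] = (0.0001, 0.0003, 0.001, 0.003, 0.01),
    base: Optional[ImagingGroundTruth] = None,
    seed: int = 0,
) -> tuple[list[TubeFrame], list[float]]:
    """GUV-only frames with known dye-lipid mole fractions (0.01-1 mol%).

    The protein-channel amplitude is proportional to the dye surface density
    through the dye brightness, exactly as the protein frames are through
    the protein-label brightness; measuring these frames with the same
    pipeline yields the intensity-per-density slope.  Returns the frames and
    the true dye densities (um^-2).
    """
    if base is None:
        base = ImagingGroundTruth()
    rng = np.random.default_rng(seed)
    kappa = base.protein_intensity_per_density / base.brightness_protein
    frames, densities = [], []
    for i, f in enumerate(fractions):
        phi_dye = label_surface_density(f)
        gt = replace(base, label_fraction=f, seed=seed)
        frames.append(
            generate_guv_frame(
                gt,
                protein_guv_amp=kappa * base.brightness_dye * phi_dye,
                rng=rng,
                frame_id=f"standard-{i:02d}",
            )
        )
        densities.append(phi_dye)
    return frames, densities


# ---------------------------------------------------------------------------
# buckled membranes


@dataclass(frozen=True)
class BuckleGroundTruth:
    """Parameters of a sine-buckled bilayer with a curvature-biased probe.

    The bilayer midplane is z = A sin(2 pi x / Lx) in a periodic (Lx, Ly,
    Lz) box; phosphate positions sit one monolayer thickness above/below it
    with Gaussian height jitter.  The probe's x coordinate is drawn with
    weight exp(probe_bias_nm * H_true(x)); probe_bias_nm = 0 is uniform.
    ``probe_depth_nm`` offsets the probe height from the local upper
    phosphate level (negative = inserted below it).  The first
    ``equilibration_fraction`` of frames are flagged pre-equilibration and
    have an unbiased probe (the helix has not yet found its preferred
    region).
    """

    amplitude_nm: float = 3.0
    box_nm: tuple[float, float, float] = (63.0, 28.0, 38.0)
    lipid_count: int = 800
    monolayer_thickness_nm: float = 2.0
    probe_bias_nm: float = 0.0
    probe_depth_nm: float = 0.0
    probe_depth_sd_nm: float = 0.05
    height_jitter_nm: float = 0.3
    frame_interval_ns: float = 10.0
    n_frames: int = 200
    equilibration_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.box_nm):
            raise ValueError("box dimensions must be positive")
        if not 0 <= self.amplitude_nm < self.box_nm[2] / 2:
            raise ValueError("amplitude must satisfy 0 <= A < Lz/2")
        if self.lipid_count <= 0 or self.n_frames <= 0:
            raise ValueError("lipid_count and n_frames must be positive")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame interval must be positive")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction in [0, 1)")


def _probe_x_sampler(gt: BuckleGroundTruth, n_grid: int = 4096):
    """Inverse-CDF sampler for the exponentially tilted probe x marginal."""
    Lx = gt.box_nm[0]
    xg = np.linspace(0.0, Lx, n_grid, endpoint=False)
    H = true_mean_curvature_1d(xg, gt.amplitude_nm, Lx)
    w = np.exp(gt.probe_bias_nm * (H - H.max()))
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    dx = Lx / n_grid

    def draw(rng, size=None):
        u = rng.random(size)
        idx = np.searchsorted(cdf, u)
        return (xg[idx] + rng.random(size) * dx) % Lx

    return draw


def generate_buckled_membrane(gt: BuckleGroundTruth) -> BuckleTrajectory:
    """Generate headgroup frames plus a probe trajectory with known bias.

    Per frame: ``lipid_count`` phosphates per leaflet, in-plane uniform,
    heights on the sine surface offset by +/- the monolayer thickness with
    Gaussian jitter; one probe whose x follows the exponential curvature
    tilt (after equilibration) and whose height tracks the local upper
    phosphate level plus the imposed insertion offset.
    """
    Lx, Ly, Lz = gt.box_nm
    rng = np.random.default_rng(gt.seed)
    draw_biased = _probe_x_sampler(gt)
    n_eq = int(round(gt.equilibration_fraction * gt.n_frames))
    k = 2.0 * math.pi / Lx
    t_mono = gt.monolayer_thickness_nm

    frames = []
    for i in range(gt.n_frames):
        x = rng.uniform(0.0, Lx, gt.lipid_count)
        y = rng.uniform(0.0, Ly, gt.lipid_count)
        h = gt.amplitude_nm * np.sin(k * x)
        z_up = h + t_mono + rng.normal(0.0, gt.height_jitter_nm, gt.lipid_count)
        x2 = rng.uniform(0.0, Lx, gt.lipid_count)
        y2 = rng.uniform(0.0, Ly, gt.lipid_count)
        z_lo = (
            gt.amplitude_nm * np.sin(k * x2)
            - t_mono
            + rng.normal(0.0, gt.height_jitter_nm, gt.lipid_count)
        )
        if i < n_eq:
            px = rng.uniform(0.0, Lx)
        else:
            px = float(draw_biased(rng))
        py = rng.uniform(0.0, Ly)
        pz = (
            gt.amplitude_nm * math.sin(k * px)
            + t_mono
            + gt.probe_depth_nm
            + rng.normal(0.0, gt.probe_depth_sd_nm)
        )
        frames.append(
            BuckleFrame(
                upper=np.column_stack([x, y, z_up]),
                lower=np.column_stack([x2, y2, z_lo]),
                probe=np.array([px, py, pz]),
                time_ns=i * gt.frame_interval_ns,
                equilibrated=i >= n_eq,
            )
        )
    return BuckleTrajectory(
        frames=frames,
        box_nm=gt.box_nm,
        frame_interval_ns=gt.frame_interval_ns,
        monolayer_thickness_nm=t_mono,
        ground_truth=gt,
    )
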