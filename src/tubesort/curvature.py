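"""Buckled-membrane curvature analysis.

A periodic two-dimensional Fourier height field is fitted to lipid
headgroup positions by linear least squares; local mean curvature is then
evaluated anywhere from the shape operator of the fitted Monge-gauge
profile using analytic derivatives of the Fourier series.

Sign convention: **H > 0 where the membrane bulges toward +z**, the side
the probe binds.  For the sine buckle z = A sin(2 pi x / Lx) the crest is
convex toward the binding leaflet and has H = +2 pi^2 A / Lx^2, so a
curvature-seeking probe yields positively shifted mean-curvature samples.

Curvature preference is quantified by comparing H sampled at the probe
centre of mass against H at randomly chosen lipid phosphate positions of
the same frames (drawn per frame), after discarding an equilibration
period.  Insertion depth is the probe height relative to the local
phosphate level of its binding leaflet, as a percentage of the monolayer
thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BuckleFrame",
    "BuckleTrajectory",
    "MembraneSurface",
    "CurvatureSamples",
    "InsertionDepthProfile",
    "EmptySampleError",
    "fit_membrane_profile",
    "mean_curvature",
    "sample_probe_curvature",
    "insertion_depth",
    "true_mean_curvature_1d",
]


class EmptySampleError(ValueError):
    """No frames (or no neighbours) left to sample after gating."""


@dataclass
class BuckleFrame:
    """One trajectory frame: phosphate positions per leaflet plus a probe."""

    upper: np.ndarray  # (N, 3) binding-leaflet phosphates, nm
    lower: np.ndarray  # (N, 3)
    probe: np.ndarray  # (3,) probe centre of mass, nm
    time_ns: float
    equilibrated: bool = True


@dataclass
class BuckleTrajectory:
    frames: list
    box_nm: tuple[float, float, float]
    frame_interval_ns: float
    monolayer_thickness_nm: float
    ground_truth: object = None


def true_mean_curvature_1d(x, amplitude_nm: float, Lx_nm: float):
    """Closed-form H of the 1D sine profile z = A sin(2 pi x / Lx).

    ``H = + A k^2 sin(k x) / (2 (1 + (A k cos(k x))^2)^{3/2})`` with
    k = 2 pi / Lx: positive at the crest (bulge toward +z), magnitude
    2 pi^2 A / Lx^2 there.
    """
    k = 2.0 * math.pi / Lx_nm
    x = np.asarray(x, dtype=float)
    s, c = np.sin(k * x), np.cos(k * x)
    return amplitude_nm * k * k * s / (2.0 * (1.0 + (amplitude_nm * k * c) ** 2) ** 1.5)


# ---------------------------------------------------------------------------
# Fourier height field


class MembraneSurface:
    """Periodic Fourier height field h(x, y) on a (Lx, Ly) box.

    Basis: products of {1, cos(2 pi m x / Lx), sin(...)} up to order Nx in x
    with the analogous functions up to Ny in y.  Each mode is stored as
    cos(kx x + phx) cos(ky y + phy) so that analytic derivatives are phase
    shifts — exact first and second derivatives everywhere, no grids.
    """

    def __init__(self, coefficients, kx, phx, ky, phy, box_nm, orders,
                 residual_rms: float, n_points: int, frame_id=None):
        self.coefficients = np.asarray(coefficients, dtype=float)
        self._kx, self._phx = np.asarray(kx), np.asarray(phx)
        self._ky, self._phy = np.asarray(ky), np.asarray(phy)
        self.box_nm = tuple(box_nm)
        self.orders = tuple(orders)
        self.residual_rms = float(residual_rms)
        self.n_points = int(n_points)
        self.frame_id = frame_id

    # -- construction -----------------------------------------------------

    @staticmethod
    def _modes(box_nm, orders):
        Lx, Ly = box_nm
        Nx, Ny = orders
        kx, phx, ky, phy = [], [], [], []
        xmodes = [(0.0, 0.0)] + [
            (2.0 * math.pi * m / Lx, ph)
            for m in range(1, Nx + 1)
            for ph in (0.0, -math.pi / 2.0)  # cos, sin
        ]
        ymodes = [(0.0, 0.0)] + [
            (2.0 * math.pi * n / Ly, ph)
            for n in range(1, Ny + 1)
            for ph in (0.0, -math.pi / 2.0)
        ]
        for kxx, pxx in xmodes:
            for kyy, pyy in ymodes:
                kx.append(kxx)
                phx.append(pxx)
                ky.append(kyy)
                phy.append(pyy)
        return (np.array(kx), np.array(phx), np.array(ky), np.array(phy))

    @classmethod
    def fit(cls, positions, box_nm, orders=(6, 2), frame_id=None):
        """Least-squares fit of the height field to (x, y, z) points.

        ``positions`` is (N, 3) with x, y wrapped into the box (wrapping is
        applied here regardless — the basis is periodic, so it only matters
        for validation).  Requires at least as many points as basis
        functions; the residual RMS (nm) is stored on the result.
        """
        pos = np.asarray(positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        Lx, Ly = box_nm[0], box_nm[1]
        if Lx <= 0 or Ly <= 0:
            raise ValueError("degenerate box")
        kx, phx, ky, phy = cls._modes((Lx, Ly), orders)
        n_basis = len(kx)
        if len(pos) < n_basis:
            raise ValueError(
                f"underdetermined fit: {len(pos)} points < {n_basis} basis functions"
            )
        x, y, z = pos[:, 0] % Lx, pos[:, 1] % Ly, pos[:, 2]
        A = np.cos(np.outer(x, kx) + phx) * np.cos(np.outer(y, ky) + phy)
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        rms = float(np.sqrt(np.mean((A @ coef - z) ** 2)))
        return cls(coef, kx, phx, ky, phy, (Lx, Ly), orders, rms, len(pos), frame_id)

    # -- evaluation -------------------------------------------------------

    def _design(self, x, y, dx: int = 0, dy: int = 0):
        """Mixed partial derivative d^dx/dx^dx d^dy/dy^dy of each basis mode."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        fx = (self._kx**dx) * np.cos(
            np.outer(x, self._kx) + self._phx + dx * math.pi / 2.0
        )
        fy = (self._ky**dy) * np.cos(
            np.outer(y, self._ky) + self._phy + dy * math.pi / 2.0
        )
        return fx * fy

    def _eval(self, x, y, dx=0, dy=0):
        out = self._design(x, y, dx, dy) @ self.coefficients
        return out

    def height(self, x, y):
        """h(x, y) in nm; accepts scalars or arrays, periodic in both axes."""
        scalar = np.isscalar(x) and np.isscalar(y)
        h = self._eval(x, y)
        return float(h[0]) if scalar else h

    def gradient(self, x, y):
        return self._eval(x, y, 1, 0), self._eval(x, y, 0, 1)

    def hessian(self, x, y):
        return (
            self._eval(x, y, 2, 0),
            self._eval(x, y, 1, 1),
            self._eval(x, y, 0, 2),
        )

    def mean_curvature(self, x, y):
        """Shape-operator mean curvature H (nm^-1) at (x, y).

        Monge gauge: ``H = -[(1 + h_y^2) h_xx - 2 h_x h_y h_xy
        + (1 + h_x^2) h_yy] / (2 (1 + h_x^2 + h_y^2)^{3/2})``, the half
        trace of the shape operator with the sign fixed so H > 0 where the
        surface bulges toward +z (the probe-binding side).  Invariant under
        translating the coordinate origin and under adding a constant to
        the height field (only derivatives enter).
        """
        scalar = np.isscalar(x) and np.isscalar(y)
        hx, hy = self.gradient(x, y)
        hxx, hxy, hyy = self.hessian(x, y)
        num = (1.0 + hy**2) * hxx - 2.0 * hx * hy * hxy + (1.0 + hx**2) * hyy
        H = -num / (2.0 * (1.0 + hx**2 + hy**2) ** 1.5)
        return float(H[0]) if scalar else H


def fit_membrane_profile(positions, box_nm, orders=(6, 2), frame_id=None):
    """Functional wrapper over :meth:`MembraneSurface.fit`."""
    return MembraneSurface.fit(positions, box_nm, orders=orders, frame_id=frame_id)


def mean_curvature(surface: MembraneSurface, position):
    """H at one (x, y) position of a fitted surface."""
    x, y = position
    return surface.mean_curvature(x, y)


# ---------------------------------------------------------------------------
# curvature-preference sampling


@dataclass
class CurvatureSamples:
    """Paired probe vs random-lipid curvature distributions.

    Histograms share binning and are normalised to unit probability mass.
    ``ks_pvalue`` is the two-sample Kolmogorov-Smirnov p-value for the null
    that probe and random samples come from the same distribution.
    """

    probe_H: np.ndarray
    random_H: np.ndarray
    bin_edges: np.ndarray
    hist_probe: np.ndarray
    hist_random: np.ndarray
    equilibration_cut_ns: float
    sampling_interval_ns: float
    mean_probe: float = field(init=False)
    mean_random: float = field(init=False)
    ks_statistic: float = field(init=False)
    ks_pvalue: float = field(init=False)

    def __post_init__(self):
        self.mean_probe = float(np.mean(self.probe_H))
        self.mean_random = float(np.mean(self.random_H))
        ks = stats.ks_2samp(self.probe_H, self.random_H)
        self.ks_statistic = float(ks.statistic)
        self.ks_pvalue = float(ks.pvalue)

    @property
    def mean_shift(self) -> float:
        return self.mean_probe - self.mean_random


def _local_level(phos: np.ndarray, probe, box_nm, radius_nm: float):
    """Mean phosphate z within a periodic xy radius of the probe (NaN if none)."""
    Lx, Ly = box_nm[0], box_nm[1]
    dx = np.abs(phos[:, 0] - probe[0])
    dx = np.minimum(dx, Lx - dx)
    dy = np.abs(phos[:, 1] - probe[1])
    dy = np.minimum(dy, Ly - dy)
    near = np.hypot(dx, dy) <= radius_nm
    if not np.any(near):
        return math.nan
    return float(phos[near, 2].mean())


def _select_leaflet(
    frame: BuckleFrame, box_nm, radius_nm: float = 5.0
) -> np.ndarray:
    """Binding-leaflet phosphates: the leaflet whose *local* phosphate level
    (mean z within ``radius_nm`` of the probe in the periodic xy plane) is
    nearer the probe height.  A buckled membrane makes the global mean z
    useless — a probe on a trough of the upper leaflet sits below the
    box-wide midplane — so the comparison must be local.
    """
    lu = _local_level(frame.upper, frame.probe, box_nm, radius_nm)
    ll = _local_level(frame.lower, frame.probe, box_nm, radius_nm)
    if math.isnan(lu) and math.isnan(ll):
        raise EmptySampleError("no phosphates near the probe in either leaflet")
    if math.isnan(ll):
        return frame.upper
    if math.isnan(lu):
        return frame.lower
    du = abs(float(frame.probe[2]) - lu)
    dl = abs(float(frame.probe[2]) - ll)
    return frame.upper if du <= dl else frame.lower


def sample_probe_curvature(
    traj: BuckleTrajectory,
    equilibration_cut_ns: float = 0.0,
    n_random: int = 1,
    orders=(6, 2),
    sampling_interval_ns: Optional[float] = None,
    n_bins: int = 40,
    seed: int = 0,
    surfaces: Optional[Sequence[MembraneSurface]] = None,
) -> CurvatureSamples:
    """Accumulate H at the probe vs at random lipid phosphates.

    Frames before ``equilibration_cut_ns`` (or flagged un-equilibrated by
    the generator) are discarded.  For each retained frame — thinned to one
    per ``sampling_interval_ns`` if given — the binding-leaflet phosphates
    are fitted with the periodic Fourier field and H is evaluated at the
    probe (x, y) and at ``n_random`` phosphate positions drawn per frame.
    Pre-fitted ``surfaces`` (one per retained frame, in order) can be
    supplied to skip refitting.
    """
    rng = np.random.default_rng(seed)
    stride = 1
    if sampling_interval_ns is not None:
        stride = max(int(round(sampling_interval_ns / traj.frame_interval_ns)), 1)
    kept = [
        f
        for i, f in enumerate(traj.frames)
        if f.equilibrated and f.time_ns >= equilibration_cut_ns and i % stride == 0
    ]
    if not kept:
        raise EmptySampleError("all frames fall in the equilibration period")
    if surfaces is not None and len(surfaces) != len(kept):
        raise ValueError("need one pre-fitted surface per retained frame")

    probe_H, random_H = [], []
    for j, f in enumerate(kept):
        phos = _select_leaflet(f, traj.box_nm)
        surf = (
            surfaces[j]
            if surfaces is not None
            else MembraneSurface.fit(phos, traj.box_nm[:2], orders=orders)
        )
        probe_H.append(surf.mean_curvature(f.probe[0], f.probe[1]))
        idx = rng.integers(0, len(phos), size=n_random)
        random_H.extend(np.atleast_1d(surf.mean_curvature(phos[idx, 0], phos[idx, 1])))
    probe_H = np.asarray(probe_H)
    random_H = np.asarray(random_H)

    lo = min(probe_H.min(), random_H.min())
    hi = max(probe_H.max(), random_H.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(probe_H, bins=edges)
    hr, _ = np.histogram(random_H, bins=edges)
    return CurvatureSamples(
        probe_H=probe_H,
        random_H=random_H,
        bin_edges=edges,
        hist_probe=hp / hp.sum(),
        hist_random=hr / hr.sum(),
        equilibration_cut_ns=equilibration_cut_ns,
        sampling_interval_ns=sampling_interval_ns or traj.frame_interval_ns,
    )


# ---------------------------------------------------------------------------
# insertion depth


@dataclass
class InsertionDepthProfile:
    """Probe height relative to the local phosphate level, per frame.

    ``z_offsets_nm`` < 0 means the probe centre sits below the phosphate
    level (inserted deeper); ``depth_fraction_percent`` expresses the mean
    offset as a percentage of the monolayer thickness.
    """

    z_offsets_nm: np.ndarray
    monolayer_thickness_nm: float
    mean_offset_nm: float = field(init=False)
    depth_fraction_percent: float = field(init=False)

    def __post_init__(self):
        self.z_offsets_nm = np.asarray(self.z_offsets_nm, dtype=float)
        self.mean_offset_nm = float(self.z_offsets_nm.mean())
        if self.monolayer_thickness_nm <= 0:
            raise ValueError("monolayer thickness must be positive")
        self.depth_fraction_percent = (
            100.0 * self.mean_offset_nm / self.monolayer_thickness_nm
        )


def insertion_depth(
    traj: BuckleTrajectory,
    neighbour_radius_nm: float = 5.0,
    equilibration_cut_ns: float = 0.0,
    monolayer_thickness_nm: Optional[float] = None,
) -> InsertionDepthProfile:
    """Per-frame probe height relative to the local phosphate level.

    The local level is the mean z of binding-leaflet phosphates within
    ``neighbour_radius_nm`` of the probe in the periodic xy plane; a frame
    with no phosphate in range raises :class:`EmptySampleError`.
    """
    Lx, Ly = traj.box_nm[0], traj.box_nm[1]
    t_mono = (
        monolayer_thickness_nm
        if monolayer_thickness_nm is not None
        else traj.monolayer_thickness_nm
    )
    offsets = []
    for f in traj.frames:
        if not f.equilibrated or f.time_ns < equilibration_cut_ns:
            continue
        phos = _select_leaflet(f, traj.box_nm, neighbour_radius_nm)
        dx = np.abs(phos[:, 0] - f.probe[0])
        dx = np.minimum(dx, Lx - dx)
        dy = np.abs(phos[:, 1] - f.probe[1])
        dy = np.minimum(dy, Ly - dy)
        near = np.hypot(dx, dy) <= neighbour_radius_nm
        if not np.any(near):
            raise EmptySampleError(
                f"no phosphates within {neighbour_radius_nm} nm of the probe "
                f"at t = {f.time_ns} ns"
            )
        offsets.append(float(f.probe[2] - phos[near, 2].mean()))
    if not offsets:
        raise EmptySampleError("no frames after the equilibration cut")
    return InsertionDepthProfile(np.asarray(offsets), t_mono)
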