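"""Tether biophysics: sorting ratio, tube radius, tension, and calibrations.

Formulas implemented here are the standard optical-trap tether relations:

* sorting ratio ``S = (I_prot,tube / I_mem,tube) / (I_prot,GUV / I_mem,GUV)``,
  the protein surface density on the tube relative to the GUV, computed from
  fluorescence normalised by the membrane signal;
* tube radius from fluorescence ``R = k_tub * (I_mem,tube / I_mem,GUV)``,
  with ``k_tub`` an empirically calibrated constant (nm);
* membrane tension from micropipette aspiration
  ``sigma = dP * r_pip / 2 * (1 - r_pip / r_GUV)``;
* tube radius from trap force ``R = F / (4 pi sigma)``;
* protein surface density on the GUV from a dye-lipid standard curve
  corrected by the bulk brightness ratio of the two fluorophores.

Units are fixed at the module boundary: pressures in Pa, pipette/GUV radii
in um, forces in pN, tube radii in nm, tension in N/m, surface densities in
proteins per um^2.  Conversions are explicit below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationSet",
    "KtubFit",
    "DensityCalibration",
    "SortingResult",
    "InductionRecord",
    "LowSignalError",
    "sorting_ratio",
    "tube_radius_from_fluorescence",
    "membrane_tension",
    "radius_from_force",
    "fit_ktub",
    "label_surface_density",
    "fit_standard_curve",
    "surface_density",
    "calibrate_density",
    "timecourse_analysis",
    "quantify_frame",
]

UM_TO_M = 1e-6
PN_TO_N = 1e-12
M_TO_NM = 1e9
NM2_TO_UM2 = 1e-6  # 1 nm^2 = 1e-6 um^2


class LowSignalError(ValueError):
    """A denominator intensity is zero or negative; no ratio is defined."""


# ---------------------------------------------------------------------------
# core printed formulas


def sorting_ratio(m) -> float:
    """Protein enrichment on the tube, S.

    ``S = (I_prot,tube / I_mem,tube) / (I_prot,GUV / I_mem,GUV)``.  S is
    invariant under independent rescaling of the two channels: detector gain
    cancels between tube and GUV.  A zero protein signal on the tube gives
    S = 0; a non-positive denominator raises :class:`LowSignalError` rather
    than returning NaN.
    """
    for name in ("I_mem_tube", "I_prot_guv", "I_mem_guv"):
        v = getattr(m, name)
        if not np.isfinite(v) or v <= 0:
            raise LowSignalError(f"{name} = {v!r} is not positive")
    if not np.isfinite(m.I_prot_tube) or m.I_prot_tube < 0:
        raise LowSignalError(f"I_prot_tube = {m.I_prot_tube!r} is not valid")
    return (m.I_prot_tube / m.I_mem_tube) / (m.I_prot_guv / m.I_mem_guv)


def tube_radius_from_fluorescence(m, k_tub_nm: float) -> float:
    """Tube radius in nm, ``R = k_tub * (I_mem,tube / I_mem,GUV)``."""
    if k_tub_nm <= 0:
        raise ValueError("k_tub must be positive")
    if not np.isfinite(m.I_mem_guv) or m.I_mem_guv <= 0:
        raise LowSignalError("I_mem_guv must be positive")
    if not np.isfinite(m.I_mem_tube) or m.I_mem_tube <= 0:
        raise LowSignalError("I_mem_tube must be positive")
    return k_tub_nm * (m.I_mem_tube / m.I_mem_guv)


def membrane_tension(dP_Pa: float, r_pip_um: float, r_guv_um: float) -> float:
    """Membrane tension (N/m) from aspiration pressure and geometry.

    ``sigma = dP * r_pip / 2 * (1 - r_pip / r_GUV)`` with dP in Pa and radii
    in um.  Requires 0 < r_pip < r_GUV (the aspirated tongue geometry).
    """
    if r_pip_um <= 0 or r_guv_um <= 0:
        raise ValueError("radii must be positive")
    if r_pip_um >= r_guv_um:
        raise ValueError("undefined geometry: r_pip must be < r_GUV")
    if dP_Pa < 0:
        raise ValueError("aspiration pressure difference must be >= 0")
    return dP_Pa * (r_pip_um * UM_TO_M) / 2.0 * (1.0 - r_pip_um / r_guv_um)


def radius_from_force(F_pN: float, sigma_N_per_m: float) -> float:
    """Tube radius in nm from trap force, ``R = F / (4 pi sigma)``."""
    if sigma_N_per_m <= 0:
        raise ValueError("tension must be positive")
    if F_pN < 0:
        raise ValueError("force must be >= 0")
    return (F_pN * PN_TO_N) / (4.0 * math.pi * sigma_N_per_m) * M_TO_NM


# ---------------------------------------------------------------------------
# k_tub calibration


@dataclass
class CalibrationSet:
    """Pull records used to regress the fluorescence-to-radius constant.

    ``records`` columns: ``dP_Pa, r_pip_um, r_guv_um, F_pN, ratio`` (tube/GUV
    membrane-fluorescence ratio).  After :func:`fit_ktub`, ``k_tub_nm`` and
    fit statistics are populated.
    """

    records: pd.DataFrame
    k_tub_nm: Optional[float] = None
    fit: Optional["KtubFit"] = None

    REQUIRED = ("dP_Pa", "r_pip_um", "r_guv_um", "F_pN", "ratio")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"calibration table missing columns {missing}")
        rec = self.records
        if (rec["r_pip_um"] >= rec["r_guv_um"]).any():
            raise ValueError("r_pip must be < r_GUV in every record")
        if (rec["ratio"] <= 0).any():
            raise ValueError("intensity ratios must be positive")
        if (rec["dP_Pa"] < 0).any():
            raise ValueError("dP must be >= 0")

    def radii_nm(self) -> np.ndarray:
        """Force-derived tube radius per record (tension -> R = F/4 pi sigma)."""
        sig = [
            membrane_tension(p, rp, rg)
            for p, rp, rg in zip(
                self.records["dP_Pa"],
                self.records["r_pip_um"],
                self.records["r_guv_um"],
            )
        ]
        return np.array(
            [radius_from_force(f, s) for f, s in zip(self.records["F_pN"], sig)]
        )


@dataclass
class KtubFit:
    k_tub_nm: float
    intercept_nm: float
    stderr_nm: float
    ci95_nm: tuple[float, float]
    r_squared: float
    n: int
    through_origin: bool


def fit_ktub(cal: CalibrationSet, through_origin: bool = False) -> KtubFit:
    """Calibrate k_tub: regress force-derived R against the intensity ratio.

    Ordinary least squares of R (nm) on the tube/GUV membrane-fluorescence
    ratio; the slope is k_tub.  By default the intercept is fitted and
    reported as a QC quantity (it should be ~0); ``through_origin=True``
    forces the line through zero.
    """
    ratio = np.asarray(cal.records["ratio"], dtype=float)
    R = cal.radii_nm()
    n = len(ratio)
    if n < 2 or np.ptp(ratio) == 0:
        raise ValueError("need >= 2 records with distinct ratios")

    if through_origin:
        slope = float(np.dot(ratio, R) / np.dot(ratio, ratio))
        resid = R - slope * ratio
        dof = max(n - 1, 1)
        s2 = float(resid @ resid) / dof
        stderr = math.sqrt(s2 / float(ratio @ ratio))
        ss_tot = float(((R - R.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        intercept = 0.0
    else:
        res = stats.linregress(ratio, R)
        slope, intercept, stderr = float(res.slope), float(res.intercept), float(
            res.stderr if np.isfinite(res.stderr) else 0.0
        )
        r2 = float(res.rvalue**2)
        dof = max(n - 2, 1)
    tval = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    ci = (slope - tval * stderr, slope + tval * stderr)
    fit = KtubFit(slope, intercept, stderr, ci, r2, n, through_origin)
    cal.k_tub_nm = slope
    cal.fit = fit
    return fit


# ---------------------------------------------------------------------------
# surface density calibration


@dataclass
class DensityCalibration:
    """Converts protein-channel GUV intensity to proteins per um^2.

    ``guv_intensity_vs_density`` is the slope of GUV rim intensity versus
    dye-lipid surface density (intensity per um^-2), measured through the
    same imaging pipeline as the protein frames.  The bulk-solution standard
    curve slopes correct for the brightness difference between the dye on
    the standard lipid and the protein label:
    ``phi = I / guv_intensity_vs_density * (slope_lipid / slope_protein)``.
    """

    guv_intensity_vs_density: float
    slope_protein_fluor: float
    slope_lipid_fluor: float
    lipid_area_nm2: float = 0.7
    leaflet_factor: int = 2

    def __post_init__(self) -> None:
        for name in (
            "guv_intensity_vs_density",
            "slope_protein_fluor",
            "slope_lipid_fluor",
            "lipid_area_nm2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.leaflet_factor not in (1, 2):
            raise ValueError("leaflet_factor must be 1 or 2")


def label_surface_density(
    mole_fraction: float, lipid_area_nm2: float = 0.7, leaflet_factor: int = 2
) -> float:
    """Dye-lipid surface density (um^-2) for a given mole fraction.

    With 0.7 nm^2 per lipid and both leaflets contributing in an equatorial
    section (leaflet_factor 2), 0.3 mol% dye gives ~8.57e3 um^-2.
    """
    if not 0 <= mole_fraction <= 1:
        raise ValueError("mole_fraction must be in [0, 1]")
    return leaflet_factor * mole_fraction / (lipid_area_nm2 * NM2_TO_UM2)


def fit_standard_curve(table: pd.DataFrame) -> float:
    """Slope of a bulk fluorophore standard curve (intensity per uM).

    ``table`` columns: ``concentration_uM, intensity``; OLS through the data
    with intercept, slope returned.
    """
    res = stats.linregress(table["concentration_uM"], table["intensity"])
    return float(res.slope)


def surface_density(
    I_prot_guv: float, cal: DensityCalibration, per_dimer: bool = False
) -> float:
    """Protein surface density on the GUV (um^-2) from label intensity.

    ``per_dimer=True`` divides by 2 to report dimer density (one label per
    protomer assumed).  Zero intensity maps to zero density.
    """
    if I_prot_guv < 0:
        raise LowSignalError("negative protein intensity")
    phi = (
        I_prot_guv
        / cal.guv_intensity_vs_density
        * (cal.slope_lipid_fluor / cal.slope_protein_fluor)
    )
    return phi / 2.0 if per_dimer else phi


def calibrate_density(
    frames,
    densities,
    standard_curves: dict,
    lipid_area_nm2: float = 0.7,
    leaflet_factor: int = 2,
    guv_hint="auto",
) -> DensityCalibration:
    """Build a :class:`DensityCalibration` from dye-standard GUV frames.

    ``frames`` are GUV-only images of vesicles carrying known dye-lipid
    surface densities (``densities``, um^-2); their protein-channel rim
    intensity is measured through the same segmentation pipeline as protein
    frames, so mask-geometry factors cancel in the final density estimate.
    ``standard_curves`` maps ``"protein"`` and ``"lipid_dye"`` to bulk
    serial-dilution tables (see :func:`fit_standard_curve`).
    """
    from .imaging import measure_intensities, segment_rois

    if len(frames) != len(densities) or len(frames) < 2:
        raise ValueError("need >= 2 standard frames with matching densities")
    intens = []
    for fr in frames:
        rois = segment_rois(fr, tube_hint=None, guv_hint=guv_hint)
        intens.append(measure_intensities(fr, rois).I_prot_guv)
    res = stats.linregress(np.asarray(densities, float), np.asarray(intens))
    return DensityCalibration(
        guv_intensity_vs_density=float(res.slope),
        slope_protein_fluor=fit_standard_curve(standard_curves["protein"]),
        slope_lipid_fluor=fit_standard_curve(standard_curves["lipid_dye"]),
        lipid_area_nm2=lipid_area_nm2,
        leaflet_factor=leaflet_factor,
    )


# ---------------------------------------------------------------------------
# per-frame quantification and time-course analysis


@dataclass
class SortingResult:
    """Per-frame quantification: sorting ratio, radius, densities, flags."""

    S: float
    R_nm: float
    phi_guv: float = np.nan
    phi_tube: float = np.nan
    timestamp_s: Optional[float] = None
    frame_id: Optional[str] = None
    flags: list = field(default_factory=list)


def quantify_frame(
    frame,
    k_tub_nm: float,
    density_cal: Optional[DensityCalibration] = None,
    tube_hint="auto",
    guv_hint="auto",
    per_dimer: bool = False,
    trim_psf_sigmas: float = 5.0,
) -> SortingResult:
    """Image -> (S, R, phi): segment, measure, apply the printed formulas.

    ``phi_tube = S * phi_guv`` (the sorting ratio is by definition the tube
    to GUV density ratio).  Frames that fail segmentation or have
    non-positive denominators come back flagged with NaNs rather than
    raising, so cohort runs keep going.
    """
    from .imaging import SegmentationError, measure_intensities, segment_rois

    flags: list = []
    try:
        rois = segment_rois(
            frame, tube_hint, guv_hint, trim_psf_sigmas=trim_psf_sigmas
        )
        m = measure_intensities(frame, rois)
    except SegmentationError as exc:
        return SortingResult(
            np.nan, np.nan, timestamp_s=frame.timestamp_s,
            frame_id=frame.meta.get("frame_id"), flags=[f"segmentation: {exc}"],
        )
    try:
        S = sorting_ratio(m)
        R = tube_radius_from_fluorescence(m, k_tub_nm)
    except LowSignalError as exc:
        return SortingResult(
            np.nan, np.nan, timestamp_s=frame.timestamp_s,
            frame_id=m.frame_id, flags=[f"low-signal: {exc}"],
        )
    phi_guv = phi_tube = np.nan
    if density_cal is not None:
        phi_guv = surface_density(m.I_prot_guv, density_cal, per_dimer=per_dimer)
        phi_tube = S * phi_guv
    if m.low_signal:
        flags.append("low-signal")
    return SortingResult(
        S, R, phi_guv, phi_tube, frame.timestamp_s, m.frame_id, flags
    )


@dataclass
class InductionRecord:
    """Summary of a curvature-induction time course.

    Initial/final values are means over head/tail windows; the slope is
    d(phi_tube)/dR over the endpoint change.  ``flags`` marks degenerate
    geometry: ``flat`` (no change at all) or ``constant-radius`` (density
    changes at fixed R, slope unbounded).
    """

    phi_initial: float
    phi_final: float
    R_initial_nm: float
    R_final_nm: float
    slope_phi_per_nm: float
    series: pd.DataFrame
    flags: list = field(default_factory=list)


def timecourse_analysis(
    results: Sequence[SortingResult],
    head_window: int = 3,
    tail_window: int = 3,
    radius_tol_nm: float = 1e-9,
) -> InductionRecord:
    """Endpoint and slope analysis of a tube's enrichment time course."""
    valid = [
        r for r in results if np.isfinite(r.phi_tube) and np.isfinite(r.R_nm)
    ]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid time points")
    t = np.array(
        [r.timestamp_s if r.timestamp_s is not None else i
         for i, r in enumerate(valid)],
        dtype=float,
    )
    order = np.argsort(t, kind="stable")
    valid = [valid[i] for i in order]
    t = t[order]
    phi = np.array([r.phi_tube for r in valid])
    R = np.array([r.R_nm for r in valid])
    S = np.array([r.S for r in valid])

    h = min(head_window, len(valid))
    w = min(tail_window, len(valid))
    phi_i, phi_f = float(phi[:h].mean()), float(phi[-w:].mean())
    R_i, R_f = float(R[:h].mean()), float(R[-w:].mean())

    flags = []
    dR, dphi = R_f - R_i, phi_f - phi_i
    if abs(dR) <= radius_tol_nm and abs(dphi) <= max(1e-9, 1e-9 * abs(phi_i)):
        slope = 0.0
        flags.append("flat")
    elif abs(dR) <= radius_tol_nm:
        slope = math.inf if dphi > 0 else -math.inf
        flags.append("constant-radius")
    else:
        slope = dphi / dR

    series = pd.DataFrame(
        {"time_s": t, "phi_tube": phi, "R_nm": R, "S": S}
    )
    return InductionRecord(phi_i, phi_f, R_i, R_f, slope, series, flags)
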