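"""Segmentation and intensity measurement for GUV + nanotube images.

A :class:`TubeFrame` holds the two confocal channels (membrane dye and
protein label) of a GUV with a pulled membrane tube.  Regions of interest
are rectangular hint boxes, one containing a segment of the tube and one
containing a segment of the GUV rim; within each box the membrane channel
is thresholded with Otsu's method and the resulting foreground mask defines
the structure, while the remaining box pixels define the local background.
Mean intensities are background subtracted per box and per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "TubeFrame",
    "ROISet",
    "IntensityMeasurement",
    "SegmentationError",
    "segment_rois",
    "measure_intensities",
    "auto_hints",
]


class SegmentationError(ValueError):
    """Raised when a region cannot be segmented (degenerate or empty)."""


@dataclass
class TubeFrame:
    """One two-channel image of a GUV + tube system.

    Both channels share shape and pixel calibration.  ``meta`` may carry
    generator ground truth and geometry (used by :func:`auto_hints`).
    """

    membrane_channel: np.ndarray
    protein_channel: np.ndarray
    pixel_size_nm: float
    timestamp_s: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membrane_channel = np.asarray(self.membrane_channel, dtype=float)
        self.protein_channel = np.asarray(self.protein_channel, dtype=float)
        if self.membrane_channel.shape != self.protein_channel.shape:
            raise ValueError("channel shapes differ")
        if self.membrane_channel.ndim != 2:
            raise ValueError("channels must be 2D arrays")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.any(self.membrane_channel < 0) or np.any(self.protein_channel < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.membrane_channel.shape


@dataclass
class ROISet:
    """Disjoint masks for the tube and GUV structures and their backgrounds.

    All masks are full-frame boolean rasters.  Background masks are the
    non-foreground pixels of the same hint box, so background estimates are
    local to each structure.
    """

    tube_mask: np.ndarray
    guv_mask: np.ndarray
    tube_background_mask: np.ndarray
    guv_background_mask: np.ndarray
    tube_hint: Optional[tuple] = None
    guv_hint: Optional[tuple] = None

    @property
    def background_mask(self) -> np.ndarray:
        return self.tube_background_mask | self.guv_background_mask

    def __post_init__(self) -> None:
        pairs = [
            (self.tube_mask, self.guv_mask),
            (self.tube_mask, self.tube_background_mask),
            (self.guv_mask, self.guv_background_mask),
        ]
        for a, b in pairs:
            if a is not None and b is not None and np.any(a & b):
                raise ValueError("ROI masks must be pairwise disjoint")


@dataclass
class IntensityMeasurement:
    """Background-subtracted mean intensities feeding S and R.

    ``I_*`` values are means over the structure mask minus the mean over the
    matching background mask.  ``low_signal`` flags measurements where a
    subtracted mean needed downstream as a denominator is not positive.
    """

    I_prot_tube: float
    I_mem_tube: float
    I_prot_guv: float
    I_mem_guv: float
    background_prot_tube: float = np.nan
    background_mem_tube: float = np.nan
    background_prot_guv: float = np.nan
    background_mem_guv: float = np.nan
    n_pixels_tube: int = 0
    n_pixels_guv: int = 0
    low_signal: bool = False
    frame_id: Optional[str] = None


def _as_slices(hint) -> tuple[slice, slice]:
    """Normalise a hint box ((r0, r1), (c0, c1)) to a pair of slices."""
    (r0, r1), (c0, c1) = hint
    return slice(int(r0), int(r1)), slice(int(c0), int(c1))


def auto_hints(frame: TubeFrame, trim_psf_sigmas: float = 5.0):
    """Derive tube/GUV hint boxes from generator geometry in ``frame.meta``.

    Mirrors the manual ROI drawing done on real images: a box on the tube a
    safe distance past the tube-GUV junction (``trim_psf_sigmas`` PSF widths,
    to avoid GUV light bleeding into the tube measurement) and a box on the
    far side of the GUV rim.  Requires ``frame.meta["geometry"]`` as written
    by the synthetic generator.
    """
    geo = frame.meta.get("geometry")
    if geo is None:
        raise ValueError("frame has no generator geometry; pass explicit hints")
    cy, cx = geo["guv_center_px"]
    r = geo["guv_radius_px"]
    sigma_px = geo["psf_sigma_px"]
    x0, y0 = geo["tube_start_px"]  # (col, row) at the junction
    x1, y1 = geo["tube_end_px"]
    ny, nx = frame.shape

    trim = trim_psf_sigmas * max(sigma_px, 1.0)
    half_h = 15
    length = 60
    # tube box: follows the (slightly tilted) tube centre line
    tx0 = x0 + trim
    tx1 = min(tx0 + length, x1 - 2)
    frac0 = (tx0 - x0) / (x1 - x0)
    frac1 = (tx1 - x0) / (x1 - x0)
    ty = 0.5 * (y0 + frac0 * (y1 - y0) + y0 + frac1 * (y1 - y0))
    tube_hint = (
        (max(int(ty - half_h), 0), min(int(ty + half_h), ny)),
        (int(tx0), int(tx1)),
    )
    # GUV box: vertical rim segment on the side opposite the tube
    gx = cx - r
    guv_hint = (
        (max(int(cy - length / 2), 0), min(int(cy + length / 2), ny)),
        (max(int(gx - half_h), 0), min(int(gx + half_h), nx)),
    )
    return tube_hint, guv_hint


def _segment_region(
    channel: np.ndarray, hint, min_pixels: int, what: str,
    min_contrast: float = 0.05,
):
    rows, cols = _as_slices(hint)
    region = channel[rows, cols]
    if region.size == 0:
        raise SegmentationError(f"{what} hint box is empty")
    if np.ptp(region) == 0:
        raise SegmentationError(
            f"{what} region is single-valued; Otsu threshold undefined"
        )
    thr = threshold_otsu(region)
    fg = region > thr
    if fg.sum() < min_pixels:
        raise SegmentationError(
            f"no {what} detected in hint box ({int(fg.sum())} px above threshold)"
        )
    # an Otsu split of pure background yields classes whose separation is
    # tiny relative to the baseline — reject rather than return noise masks
    fg_mean, bg_mean = region[fg].mean(), region[~fg].mean()
    if fg_mean - bg_mean < min_contrast * max(bg_mean, 1e-12):
        raise SegmentationError(
            f"no {what} detected: foreground/background contrast "
            f"{fg_mean - bg_mean:.3g} below threshold"
        )
    mask = np.zeros(channel.shape, dtype=bool)
    bg = np.zeros(channel.shape, dtype=bool)
    mask[rows, cols] = fg
    bg[rows, cols] = ~fg
    return mask, bg


def segment_rois(
    frame: TubeFrame,
    tube_hint="auto",
    guv_hint="auto",
    min_pixels: int = 10,
    trim_psf_sigmas: float = 5.0,
) -> ROISet:
    """Segment tube and GUV foreground masks from the membrane channel.

    Each hint is ``((row0, row1), (col0, col1))`` in pixels, or ``"auto"``
    to derive boxes from generator geometry.  ``tube_hint=None`` skips the
    tube (GUV-only frames, e.g. density-calibration standards).  Thresholds
    are computed per box with Otsu's method on the membrane channel only, so
    segmentation is independent of the protein channel and invariant to a
    positive rescaling of the membrane channel.
    """
    if tube_hint == "auto" or guv_hint == "auto":
        a_tube, a_guv = auto_hints(frame, trim_psf_sigmas=trim_psf_sigmas)
        if tube_hint == "auto":
            tube_hint = a_tube
        if guv_hint == "auto":
            guv_hint = a_guv

    guv_mask, guv_bg = _segment_region(
        frame.membrane_channel, guv_hint, min_pixels, "GUV"
    )
    if tube_hint is None:
        empty = np.zeros(frame.shape, dtype=bool)
        return ROISet(empty, guv_mask, empty.copy(), guv_bg, None, guv_hint)
    tube_mask, tube_bg = _segment_region(
        frame.membrane_channel, tube_hint, min_pixels, "tube"
    )
    if np.any(tube_mask & guv_mask):
        raise SegmentationError("tube and GUV hint boxes overlap on foreground")
    return ROISet(tube_mask, guv_mask, tube_bg, guv_bg, tube_hint, guv_hint)


def _mean(channel: np.ndarray, mask: np.ndarray) -> float:
    if not np.any(mask):
        raise SegmentationError("empty mask in intensity measurement")
    return float(channel[mask].mean())


def measure_intensities(frame: TubeFrame, rois: ROISet) -> IntensityMeasurement:
    """Mean intensity over each mask minus its local background mean.

    Adding a constant offset to both channels leaves the result unchanged
    (the offset enters foreground and background means equally).  Tube
    values are NaN for GUV-only ROI sets.
    """
    mem, prot = frame.membrane_channel, frame.protein_channel

    bg_mem_guv = _mean(mem, rois.guv_background_mask)
    bg_prot_guv = _mean(prot, rois.guv_background_mask)
    i_mem_guv = _mean(mem, rois.guv_mask) - bg_mem_guv
    i_prot_guv = _mean(prot, rois.guv_mask) - bg_prot_guv
    n_guv = int(rois.guv_mask.sum())

    if np.any(rois.tube_mask):
        bg_mem_tube = _mean(mem, rois.tube_background_mask)
        bg_prot_tube = _mean(prot, rois.tube_background_mask)
        i_mem_tube = _mean(mem, rois.tube_mask) - bg_mem_tube
        i_prot_tube = _mean(prot, rois.tube_mask) - bg_prot_tube
        n_tube = int(rois.tube_mask.sum())
    else:
        bg_mem_tube = bg_prot_tube = np.nan
        i_mem_tube = i_prot_tube = np.nan
        n_tube = 0

    low = (i_mem_guv <= 0) or (n_tube > 0 and i_mem_tube <= 0)
    ts = frame.timestamp_s
    return IntensityMeasurement(
        I_prot_tube=i_prot_tube,
        I_mem_tube=i_mem_tube,
        I_prot_guv=i_prot_guv,
        I_mem_guv=i_mem_guv,
        background_prot_tube=bg_prot_tube,
        background_mem_tube=bg_mem_tube,
        background_prot_guv=bg_prot_guv,
        background_mem_guv=bg_mem_guv,
        n_pixels_tube=n_tube,
        n_pixels_guv=n_guv,
        low_signal=bool(low),
        frame_id=frame.meta.get("frame_id", None if ts is None else f"t={ts:g}s"),
    )
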