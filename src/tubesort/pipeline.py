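"""Reproducible pipelines: configuration, cohort runs, reports and plots.

Two composite runs tie the stages together.  The sorting pipeline turns a
cohort of tube frames into a per-tube table (S, R, 1/R, surface densities,
flags), splits tubes into high/low GUV-density groups at a configurable
threshold, and fits S against curvature (1/R) per group by ordinary least
squares.  The curvature pipeline turns a buckled-membrane trajectory into
probe-vs-random mean-curvature histograms, summary means and an
insertion-depth profile.  Both are deterministic for a fixed config + seed
and tag every output row with the frame id and a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .biophysics import (
    DensityCalibration,
    InductionRecord,
    SortingResult,
    quantify_frame,
    timecourse_analysis,
)
from .curvature import (
    BuckleTrajectory,
    CurvatureSamples,
    InsertionDepthProfile,
    insertion_depth,
    sample_probe_curvature,
)

log = logging.getLogger("tubesort")

__all__ = [
    "PipelineConfig",
    "run_sorting_pipeline",
    "run_curvature_pipeline",
    "run_timecourse",
    "plot_sorting_vs_curvature",
    "plot_curvature_histograms",
    "plot_timecourse",
    "plot_induction_vectors",
]


@dataclass
class PipelineConfig:
    """All tunable constants of a run; round-trips losslessly through YAML."""

    seed: int = 0
    k_tub_nm: float = 200.0
    lipid_area_nm2: float = 0.7
    leaflet_factor: int = 2
    density_split: float = 800.0  # um^-2; phi_guv above this = "high" group
    head_window: int = 3
    tail_window: int = 3
    fourier_orders: tuple = (6, 2)
    equilibration_cut_ns: float = 0.0
    sampling_interval_ns: Optional[float] = None
    n_random: int = 1
    neighbour_radius_nm: float = 5.0
    trim_psf_sigmas: float = 5.0
    per_dimer: bool = False
    input_frames: list = field(default_factory=list)
    trajectory_path: Optional[str] = None
    output_dir: str = "tubesort_out"

    def __post_init__(self) -> None:
        self.fourier_orders = tuple(self.fourier_orders)
        for name in ("k_tub_nm", "lipid_area_nm2", "density_split"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def hash(self) -> str:
        """Hash of the analysis-relevant fields (the output sink is excluded,
        so re-running the same analysis into another directory is traceable
        to the same configuration)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:10]


# ---------------------------------------------------------------------------
# sorting pipeline


def _density_group(phi_guv: float, split: float) -> str:
    if not np.isfinite(phi_guv):
        return "ungrouped"
    return "high" if phi_guv >= split else "low"


def run_sorting_pipeline(
    config: PipelineConfig,
    frames: Optional[Sequence] = None,
    density_cal: Optional[DensityCalibration] = None,
    make_plots: bool = True,
):
    """Cohort of tube frames -> per-tube table + per-group S(1/R) fits.

    Frames may be passed directly or named in ``config.input_frames``
    (TIFFs with sidecars).  Returns ``(results_df, fits_df)`` and writes
    ``results.csv``, ``fits.csv`` and the sorting-vs-curvature plot under
    ``config.output_dir``.
    """
    if frames is None:
        from .io import load_frame_tiff

        if not config.input_frames:
            raise ValueError("no input frames given")
        frames = [load_frame_tiff(p) for p in config.input_frames]
    frames = list(frames)
    if not frames:
        raise ValueError("no input frames given")

    rows = []
    for i, fr in enumerate(frames):
        res = quantify_frame(
            fr,
            config.k_tub_nm,
            density_cal=density_cal,
            per_dimer=config.per_dimer,
            trim_psf_sigmas=config.trim_psf_sigmas,
        )
        fid = res.frame_id or f"frame{i:03d}"
        if res.flags:
            log.warning("config %s frame %s flagged: %s", config.hash, fid, res.flags)
        rows.append(
            {
                "frame_id": fid,
                "config_hash": config.hash,
                "S": res.S,
                "R_nm": res.R_nm,
                "curvature_per_nm": 1.0 / res.R_nm if res.R_nm else np.nan,
                "phi_guv": res.phi_guv,
                "phi_tube": res.phi_tube,
                "group": _density_group(res.phi_guv, config.density_split),
                "flags": ";".join(res.flags),
            }
        )
    df = pd.DataFrame(rows)
    valid = df[np.isfinite(df["S"]) & np.isfinite(df["R_nm"])]
    if valid.empty:
        raise ValueError("no valid tubes in cohort")

    fit_rows = []
    groups = valid.groupby("group") if density_cal is not None else [("all", valid)]
    for name, grp in groups:
        if len(grp) < 2 or np.ptp(grp["curvature_per_nm"].to_numpy()) == 0:
            continue
        res = stats.linregress(grp["curvature_per_nm"], grp["S"])
        fit_rows.append(
            {
                "group": name,
                "n": len(grp),
                "slope_nm": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
            }
        )
    fits = pd.DataFrame(fit_rows)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "results.csv", index=False)
    fits.to_csv(out / "fits.csv", index=False)
    if make_plots:
        plot_sorting_vs_curvature(df, fits, out / "sorting_vs_curvature.png")
    return df, fits


def run_timecourse(
    config: PipelineConfig,
    frames: Sequence,
    density_cal: DensityCalibration,
    make_plots: bool = True,
) -> InductionRecord:
    """Time-ordered frames of one tube -> curvature-induction record."""
    results = [
        quantify_frame(
            fr,
            config.k_tub_nm,
            density_cal=density_cal,
            per_dimer=config.per_dimer,
            trim_psf_sigmas=config.trim_psf_sigmas,
        )
        for fr in frames
    ]
    record = timecourse_analysis(
        results, head_window=config.head_window, tail_window=config.tail_window
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record.series.to_csv(out / "timecourse.csv", index=False)
    if make_plots:
        plot_timecourse(record, out / "timecourse.png")
    return record


# ---------------------------------------------------------------------------
# curvature pipeline


def run_curvature_pipeline(
    config: PipelineConfig,
    traj: Optional[BuckleTrajectory] = None,
    make_plots: bool = True,
):
    """Buckled-membrane trajectory -> curvature histograms + insertion depth.

    Returns ``(samples, depth_profile, summary)`` and writes the shared-bin
    histogram table, a summary JSON and the histogram figure.
    """
    if traj is None:
        if not config.trajectory_path:
            raise ValueError("no trajectory given")
        from .io import trajectory_from_csv, trajectory_from_xyz

        p = Path(config.trajectory_path)
        if not p.exists():
            raise FileNotFoundError(p)
        traj = (
            trajectory_from_xyz(p)
            if p.suffix == ".xyz"
            else trajectory_from_csv(p)
        )
    samples = sample_probe_curvature(
        traj,
        equilibration_cut_ns=config.equilibration_cut_ns,
        n_random=config.n_random,
        orders=config.fourier_orders,
        sampling_interval_ns=config.sampling_interval_ns,
        seed=config.seed,
    )
    depth = insertion_depth(
        traj,
        neighbour_radius_nm=config.neighbour_radius_nm,
        equilibration_cut_ns=config.equilibration_cut_ns,
    )
    summary = {
        "config_hash": config.hash,
        "n_probe": int(len(samples.probe_H)),
        "n_random": int(len(samples.random_H)),
        "mean_H_probe_per_nm": samples.mean_probe,
        "mean_H_random_per_nm": samples.mean_random,
        "mean_shift_per_nm": samples.mean_shift,
        "ks_pvalue": samples.ks_pvalue,
        "mean_insertion_offset_nm": depth.mean_offset_nm,
        "depth_fraction_percent": depth.depth_fraction_percent,
    }
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    centers = 0.5 * (samples.bin_edges[:-1] + samples.bin_edges[1:])
    pd.DataFrame(
        {
            "H_per_nm": centers,
            "p_probe": samples.hist_probe,
            "p_random": samples.hist_random,
        }
    ).to_csv(out / "curvature_histogram.csv", index=False)
    (out / "curvature_summary.json").write_text(json.dumps(summary, indent=1))
    if make_plots:
        plot_curvature_histograms(samples, out / "curvature_histogram.png")
    return samples, depth, summary


# ---------------------------------------------------------------------------
# plots


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_sorting_vs_curvature(df: pd.DataFrame, fits: pd.DataFrame, path):
    """Per-tube S against 1/R, one colour per density group, with OLS lines."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, grp in df.groupby("group"):
        ax.plot(grp["curvature_per_nm"], grp["S"], "o", label=f"{name} (n={len(grp)})")
    for _, row in fits.iterrows():
        x = np.linspace(df["curvature_per_nm"].min(), df["curvature_per_nm"].max(), 50)
        ax.plot(
            x,
            row["intercept"] + row["slope_nm"] * x,
            "-",
            alpha=0.7,
            label=f"{row['group']}: r$^2$={row['r_squared']:.2f}",
        )
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("curvature 1/R (nm$^{-1}$)")
    ax.set_ylabel("sorting ratio S")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timecourse(record: InductionRecord, path):
    """Tube protein density and radius against time on twin axes."""
    plt = _pyplot()
    fig, ax1 = plt.subplots(figsize=(5, 4))
    s = record.series
    ax1.plot(s["time_s"], s["phi_tube"], "o-", color="teal")
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel(r"$\phi_{tube}$ ($\mu$m$^{-2}$)", color="teal")
    ax2 = ax1.twinx()
    ax2.plot(s["time_s"], s["R_nm"], "s-", color="magenta")
    ax2.set_ylabel("tube radius (nm)", color="magenta")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_induction_vectors(records: Sequence[InductionRecord], path):
    """Initial -> final (R, phi) arrows, coloured by the density/radius slope."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    slopes = [
        r.slope_phi_per_nm if np.isfinite(r.slope_phi_per_nm) else 0.0
        for r in records
    ]
    vmax = max(1e-9, max(abs(s) for s in slopes))
    cmap = plt.get_cmap("viridis")
    for rec, s in zip(records, slopes):
        ax.annotate(
            "",
            xy=(rec.R_final_nm, rec.phi_final),
            xytext=(rec.R_initial_nm, rec.phi_initial),
            arrowprops=dict(arrowstyle="->", color=cmap(0.5 + 0.5 * s / vmax)),
        )
    ax.set_xlabel("tube radius (nm)")
    ax.set_ylabel(r"$\phi_{tube}$ ($\mu$m$^{-2}$)")
    ax.relim()
    all_R = [r.R_initial_nm for r in records] + [r.R_final_nm for r in records]
    all_p = [r.phi_initial for r in records] + [r.phi_final for r in records]
    ax.set_xlim(min(all_R) * 0.9, max(all_R) * 1.1)
    ax.set_ylim(min(all_p) * 0.9, max(all_p) * 1.1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_curvature_histograms(samples: CurvatureSamples, path):
    """Probe vs random-lipid mean-curvature probability histograms."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    centers = 0.5 * (samples.bin_edges[:-1] + samples.bin_edges[1:])
    width = samples.bin_edges[1] - samples.bin_edges[0]
    ax.bar(centers, samples.hist_random, width=width, color="0.7", label="random lipids")
    ax.step(centers, samples.hist_probe, where="mid", color="teal", label="probe")
    ax.axvline(samples.mean_probe, color="teal", ls="--", lw=0.8)
    ax.set_xlabel("local mean curvature H (nm$^{-1}$)")
    ax.set_ylabel("probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
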