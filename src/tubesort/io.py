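"""File formats: TIFF frames with sidecars, coordinate tables, CSV tables.

Images are written as two-channel TIFF stacks (channel 0 = membrane dye,
channel 1 = protein label) with a JSON sidecar carrying pixel calibration
and, for synthetic frames, the ground truth.  Buckled-membrane frames go to
plain-text XYZ (element P = phosphate, C = probe; box in the comment line)
or a long CSV table.  Calibration pulls round-trip through the standard
five-column CSV (dP_Pa, r_pip_um, r_guv_um, F_pN, ratio).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .biophysics import CalibrationSet
from .curvature import BuckleFrame, BuckleTrajectory
from .imaging import TubeFrame

__all__ = [
    "save_frame_tiff",
    "load_frame_tiff",
    "save_calibration_csv",
    "load_calibration_csv",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trajectory_to_xyz",
    "trajectory_from_xyz",
    "read_membrane_coordinates",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return None  # rasters are not serialised into sidecars
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_frame_tiff(frame: TubeFrame, path) -> Path:
    """Write a frame as a (2, H, W) float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack(
        [frame.membrane_channel, frame.protein_channel]
    ).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {
        "pixel_size_nm": frame.pixel_size_nm,
        "timestamp_s": frame.timestamp_s,
        "meta": {
            k: _jsonable(v)
            for k, v in frame.meta.items()
            if not isinstance(v, np.ndarray)
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_frame_tiff(path) -> TubeFrame:
    """Read a two-channel TIFF written by :func:`save_frame_tiff`.

    The sidecar, if present, restores pixel size, timestamp and metadata
    (ground-truth rasters are not round-tripped).
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError("expected a (2, H, W) channel stack")
    pixel_size, timestamp, meta = 100.0, None, {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        pixel_size = info.get("pixel_size_nm", pixel_size)
        timestamp = info.get("timestamp_s")
        meta = info.get("meta", {})
    return TubeFrame(
        membrane_channel=np.asarray(stack[0], dtype=float),
        protein_channel=np.asarray(stack[1], dtype=float),
        pixel_size_nm=pixel_size,
        timestamp_s=timestamp,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# calibration tables


def save_calibration_csv(cal: CalibrationSet, path) -> Path:
    path = Path(path)
    cal.records.to_csv(path, index=False)
    return path


def load_calibration_csv(path) -> CalibrationSet:
    return CalibrationSet(pd.read_csv(path))


# ---------------------------------------------------------------------------
# coordinate frames


def trajectory_to_csv(traj: BuckleTrajectory, path) -> Path:
    """Long-format table: frame, time_ns, kind, x, y, z (+ box header line)."""
    path = Path(path)
    rows = []
    for i, f in enumerate(traj.frames):
        for kind, arr in (("upper", f.upper), ("lower", f.lower)):
            for x, y, z in arr:
                rows.append((i, f.time_ns, kind, int(f.equilibrated), x, y, z))
        rows.append((i, f.time_ns, "probe", int(f.equilibrated), *f.probe))
    df = pd.DataFrame(
        rows, columns=["frame", "time_ns", "kind", "equilibrated", "x", "y", "z"]
    )
    with open(path, "w") as fh:
        fh.write(
            "# box_nm %.6f %.6f %.6f interval_ns %.6f monolayer_nm %.6f\n"
            % (*traj.box_nm, traj.frame_interval_ns, traj.monolayer_thickness_nm)
        )
        df.to_csv(fh, index=False)
    return path


def trajectory_from_csv(path) -> BuckleTrajectory:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        box = tuple(float(v) for v in header[2:5])
        interval = float(header[6])
        mono = float(header[8])
        df = pd.read_csv(fh)
    frames = []
    for i, grp in df.groupby("frame", sort=True):
        up = grp[grp["kind"] == "upper"][["x", "y", "z"]].to_numpy()
        lo = grp[grp["kind"] == "lower"][["x", "y", "z"]].to_numpy()
        pr = grp[grp["kind"] == "probe"][["x", "y", "z"]].to_numpy()
        frames.append(
            BuckleFrame(
                upper=up,
                lower=lo,
                probe=pr[0],
                time_ns=float(grp["time_ns"].iloc[0]),
                equilibrated=bool(grp["equilibrated"].iloc[0]),
            )
        )
    return BuckleTrajectory(frames, box, interval, mono)


def trajectory_to_xyz(traj: BuckleTrajectory, path) -> Path:
    """Multi-frame XYZ: P = phosphate, C = probe; box in the comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in traj.frames:
            n = len(f.upper) + len(f.lower) + 1
            fh.write(f"{n}\n")
            fh.write(
                "box %.6f %.6f %.6f time_ns %.6f equilibrated %d\n"
                % (*traj.box_nm, f.time_ns, int(f.equilibrated))
            )
            for tag, arr in (("P", f.upper), ("P", f.lower)):
                for x, y, z in arr:
                    fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")
            fh.write("C %.6f %.6f %.6f\n" % tuple(f.probe))
    return path


def trajectory_from_xyz(
    path, monolayer_thickness_nm: float = 2.0
) -> BuckleTrajectory:
    """Read XYZ frames written by :func:`trajectory_to_xyz`.

    Leaflets are re-assigned by splitting phosphates at the frame's median
    z (the writer pools them), which is exact for the sine-buckle geometry
    whenever the amplitude is below the monolayer offset.
    """
    frames = []
    box = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            hdr = fh.readline().split()
            box = tuple(float(v) for v in hdr[1:4])
            time_ns = float(hdr[5])
            equilibrated = bool(int(hdr[7]))
            phos, probe = [], None
            for _ in range(n):
                tag, x, y, z = fh.readline().split()
                p = (float(x), float(y), float(z))
                if tag == "C":
                    probe = np.array(p)
                else:
                    phos.append(p)
            phos = np.asarray(phos)
            med = np.median(phos[:, 2])
            frames.append(
                BuckleFrame(
                    upper=phos[phos[:, 2] >= med],
                    lower=phos[phos[:, 2] < med],
                    probe=probe,
                    time_ns=time_ns,
                    equilibrated=equilibrated,
                )
            )
    if not frames:
        raise ValueError(f"no frames in {path}")
    interval = (
        frames[1].time_ns - frames[0].time_ns if len(frames) > 1 else 1.0
    )
    return BuckleTrajectory(frames, box, interval, monolayer_thickness_nm)


def read_membrane_coordinates(
    path,
    phosphate_selection: str = "name P*",
    probe_selection: Optional[str] = None,
    length_scale: float = 0.1,
):
    """Read a structure file (GRO/PDB/...) via MDAnalysis.

    Returns ``(phosphate_positions_nm, probe_com_nm_or_None, box_nm)``.
    ``length_scale`` converts from the file's Angstrom convention to nm.
    Phosphate particles are selected by name pattern (configurable for
    coarse-grained naming schemes such as PO4 beads).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    phos = u.select_atoms(phosphate_selection)
    if len(phos) == 0:
        raise ValueError(f"selection {phosphate_selection!r} matched no atoms")
    probe = None
    if probe_selection:
        sel = u.select_atoms(probe_selection)
        if len(sel):
            probe = sel.center_of_geometry() * length_scale
    box = u.dimensions[:3] * length_scale if u.dimensions is not None else None
    return phos.positions * length_scale, probe, box
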