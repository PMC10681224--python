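"""Reading and writing marker trajectories and cohort manifests.

Two on-disk trajectory formats are supported:

* TRC — the tab-separated motion-capture text format (header lines with
  DataRate/NumFrames/Units followed by per-frame rows). Planar data, so
  each marker carries X/Y columns only.
* tabular — a flat delimited table with columns ``time_s`` and
  ``<marker>_x_m`` / ``<marker>_y_m`` per marker.

Marker names are matched case-insensitively and common anatomical or
joint-level aliases (shoulder, hip, knee, ankle) are accepted. Units are
converted to meters per the TRC header. Isolated gaps up to 0.1 s are
linearly interpolated with a logged warning; a marker missing more than
5% of its frames is rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import MARKER_NAMES, MarkerTrajectorySet

logger = logging.getLogger(__name__)

ALIASES = {
    "acromion": "acromion",
    "shoulder": "acromion",
    "trochanter": "trochanter",
    "trochanter_major": "trochanter",
    "hip": "trochanter",
    "epicondyle": "epicondyle",
    "epicondylus": "epicondyle",
    "epicondylus_lateralis": "epicondyle",
    "knee": "epicondyle",
    "malleolus": "malleolus",
    "malleolus_lateralis": "malleolus",
    "ankle": "malleolus",
    "toe": "toe",
    "caput_metatarsalis": "toe",
    "metatarsal": "toe",
}

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}

MAX_GAP_S = 0.1
MAX_MISSING_FRAC = 0.05


class MissingMarkerError(ValueError):
    """A required marker has no column in the input file."""


def _canon(name: str) -> str | None:
    return ALIASES.get(name.strip().lower().replace(" ", "_"))


def _fill_gaps(arr: np.ndarray, fs: float, marker: str) -> np.ndarray:
    """Interpolate isolated NaN gaps <= MAX_GAP_S; reject larger losses."""
    out = arr.copy()
    for col in range(arr.shape[1]):
        x = out[:, col]
        bad = ~np.isfinite(x)
        if not bad.any():
            continue
        if bad.mean() > MAX_MISSING_FRAC:
            raise ValueError(
                f"marker {marker!r}: {bad.mean():.1%} of frames missing (>5%)"
            )
        # longest contiguous gap
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
        if runs.size and runs.max() / fs > MAX_GAP_S:
            raise ValueError(
                f"marker {marker!r}: gap of {runs.max() / fs:.2f} s exceeds "
                f"{MAX_GAP_S} s"
            )
        idx = np.arange(len(x))
        out[:, col] = np.interp(idx, idx[~bad], x[~bad])
        logger.warning(
            "marker %s: interpolated %d missing frame(s)", marker, int(bad.sum())
        )
    return out


def write_trc(traj: MarkerTrajectorySet, path: str | Path) -> None:
    """Write a planar TRC file (units meters)."""
    path = Path(path)
    fs = traj.sampling_rate_hz
    n = traj.n_frames
    names = list(MARKER_NAMES)
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{fs:g}\t{fs:g}\t{n}\t{len(names)}\tm\t{fs:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t".join(names) + "\n")
        axes = "\t".join(f"X{i + 1}\tY{i + 1}" for i in range(len(names)))
        fh.write("\t\t" + axes + "\n")
        t = traj.time_s
        for k in range(n):
            cells = [str(k + 1), f"{t[k]:.6f}"]
            for m in names:
                x, y = traj.markers[m][k]
                cells += [f"{x:.9f}", f"{y:.9f}"]
            fh.write("\t".join(cells) + "\n")


def write_tabular(traj: MarkerTrajectorySet, path: str | Path) -> None:
    """Write the flat tabular format (tab-separated, meters)."""
    data = {"time_s": traj.time_s}
    for m in MARKER_NAMES:
        data[f"{m}_x_m"] = traj.markers[m][:, 0]
        data[f"{m}_y_m"] = traj.markers[m][:, 1]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9f")


def _read_trc(path: Path) -> MarkerTrajectorySet:
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path}: not a TRC file (too short)")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    fs = float(meta["DataRate"])
    unit = meta.get("Units", "m").strip().lower()
    if unit not in _UNIT_SCALE:
        raise ValueError(f"{path}: unknown units {unit!r}")
    scale = _UNIT_SCALE[unit]

    header_names = [c for c in lines[3].split("\t")[2:] if c.strip()]
    canon = []
    for raw in header_names:
        c = _canon(raw)
        if c is None:
            raise ValueError(f"{path}: unrecognised marker column {raw!r}")
        canon.append(c)
    missing = [m for m in MARKER_NAMES if m not in canon]
    if missing:
        raise MissingMarkerError(f"{path}: missing marker(s) {', '.join(missing)}")

    rows = [ln.split("\t") for ln in lines[5:] if ln.strip()]
    data = np.array(
        [[float(c) if c.strip() else np.nan for c in r[2:]] for r in rows]
    )
    markers = {}
    for j, name in enumerate(canon):
        arr = data[:, 2 * j : 2 * j + 2] * scale
        markers[name] = _fill_gaps(arr, fs, name)
    return MarkerTrajectorySet(sampling_rate_hz=fs, markers=markers)


def _read_tabular(path: Path) -> MarkerTrajectorySet:
    df = pd.read_csv(path, sep=None, engine="python")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: tabular format requires a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 frames")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling interval")
    fs = 1.0 / float(np.median(dt))

    markers = {}
    for m in MARKER_NAMES:
        pair = None
        for col in df.columns:
            base = col.lower().removesuffix("_x_m").removesuffix("_y_m")
            if col.lower().endswith("_x_m") and _canon(base) == m:
                ycol = next(
                    (c for c in df.columns
                     if c.lower() == col.lower().replace("_x_m", "_y_m")),
                    None,
                )
                if ycol is not None:
                    pair = (col, ycol)
                    break
        if pair is None:
            raise MissingMarkerError(f"{path}: missing marker {m!r}")
        arr = df[list(pair)].to_numpy(dtype=float)
        markers[m] = _fill_gaps(arr, fs, m)
    return MarkerTrajectorySet(sampling_rate_hz=fs, markers=markers)


def read_trajectories(path: str | Path, format: str | None = None) -> MarkerTrajectorySet:
    """Read a trajectory file; format inferred from the extension.

    ``format`` may be "trc" or "tabular"; ``None`` infers ``.trc`` as
    TRC and anything else as tabular.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "trc" if path.suffix.lower() == ".trc" else "tabular"
    if format == "trc":
        return _read_trc(path)
    if format == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown format {format!r}")


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Cohort manifest: participant_id, llmr_pct, condition, file."""
    pd.DataFrame(rows, columns=["participant_id", "llmr_pct", "condition", "file"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"participant_id", "llmr_pct", "condition", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return df
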