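"""Repetition detection and velocity-region metrics.

A squat repetition runs from standing through the deepest position back
to standing: the descent is the flexion phase, the ascent the extension
phase. Each phase is split at its peak vertical-velocity frame of a
reference joint (hip by default), giving the four regions

* V1down: flexion start -> peak descent velocity  (descent acceleration)
* V2down: peak descent velocity -> deepest frame  (descent deceleration)
* V1up:   deepest frame -> peak ascent velocity   (ascent acceleration)
* V2up:   peak ascent velocity -> extension end   (ascent deceleration)

Mean velocities and accelerations are averaged per region; peak
velocities, the joint angles at the peak-velocity frames, ROMs and
durations are pointwise. All reported values follow the absolute-value
convention (magnitudes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import JointKinematics

logger = logging.getLogger(__name__)

LINEAR_JOINTS = ("shoulder", "hip", "knee")
ANGULAR_JOINTS = ("hip", "knee")

#: variable name -> (region label, units) for the long-format table
_LINEAR_VARS = {
    "V1down": ("V1down", "m.s-1"),
    "Vdownpeak": ("V1down", "m.s-1"),
    "V2down": ("V2down", "m.s-1"),
    "Vflex": ("Vflex", "m.s-1"),
    "V1up": ("V1up", "m.s-1"),
    "Vuppeak": ("V1up", "m.s-1"),
    "V2up": ("V2up", "m.s-1"),
    "Vext": ("Vext", "m.s-1"),
    "Descent_Acc": ("V1down", "m.s-2"),
    "Descent_Dec": ("V2down", "m.s-2"),
    "Ascent_Acc": ("V1up", "m.s-2"),
    "Ascent_Dec": ("V2up", "m.s-2"),
}
_ANGULAR_VARS = {
    "Vdownpeak_Angle": ("V1down", "deg"),
    "Vuppeak_Angle": ("V1up", "deg"),
    "ROM_Flex": ("Vflex", "deg"),
    "ROM_Ext": ("Vext", "deg"),
    "V1down_Deg_Velo": ("V1down", "rad.s-1"),
    "V2down_Deg_Velo": ("V2down", "rad.s-1"),
    "Flex_Deg_Velo": ("Vflex", "rad.s-1"),
    "V1up_Deg_Velo": ("V1up", "rad.s-1"),
    "V2up_Deg_Velo": ("V2up", "rad.s-1"),
    "Ext_Deg_Velo": ("Vext", "rad.s-1"),
}
_DURATION_VARS = ("t_V1down", "t_V2down", "t_Vflex", "t_V1up", "t_V2up", "t_Vext", "t_total")


@dataclass(frozen=True)
class SquatCycle:
    """Frame indices delimiting one repetition.

    Flexion spans [start_idx, bottom_idx], extension [bottom_idx,
    end_idx]; the deepest (minimum hip height) frame belongs to both.
    """

    start_idx: int
    bottom_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if not self.start_idx < self.bottom_idx < self.end_idx:
            raise ValueError(
                f"need start < bottom < end, got "
                f"{self.start_idx}, {self.bottom_idx}, {self.end_idx}"
            )


@dataclass(frozen=True)
class RegionBoundaries:
    """Peak-velocity frames splitting each phase into its two regions."""

    downpeak_idx: int
    uppeak_idx: int


@dataclass
class RegionMetrics:
    """The full per-repetition variable set, flat and long-format.

    ``values`` maps ``"<variable>_<joint>"`` (or a duration name) to a
    magnitude; ``to_rows`` emits the long-format table consumed by the
    statistics layer.
    """

    values: dict[str, float]
    degenerate: bool = False

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_rows(self, participant_id: str = "", condition: str = "") -> pd.DataFrame:
        rows = []
        for joint in LINEAR_JOINTS:
            for var, (region, units) in _LINEAR_VARS.items():
                rows.append(
                    (participant_id, condition, joint, var, region,
                     self.values[f"{var}_{joint}"], units)
                )
        for joint in ANGULAR_JOINTS:
            for var, (region, units) in _ANGULAR_VARS.items():
                rows.append(
                    (participant_id, condition, joint, var, region,
                     self.values[f"{var}_{joint}"], units)
                )
        for var in _DURATION_VARS:
            region = var[2:] if var != "t_total" else "total"
            rows.append((participant_id, condition, "", var, region, self.values[var], "s"))
        return pd.DataFrame(
            rows,
            columns=["participant_id", "condition", "joint", "variable",
                     "region", "value", "units"],
        )


def detect_repetitions(
    kin: JointKinematics,
    v_eps: float = 0.05,
    min_depth_m: float = 0.10,
) -> list[SquatCycle]:
    """Detect squat repetitions from the hip vertical velocity.

    Frames where the hip vertical velocity leaves a hysteresis band
    ``(-v_eps, +v_eps)`` form descent (v < -v_eps) and ascent
    (v > +v_eps) runs; each descent run paired with the next ascent run
    is one candidate repetition, kept if the hip drops at least
    ``min_depth_m`` below its starting height. The boundaries are then
    extended outward along the hip height to the nearest standing
    plateau or turnaround (the local height maximum), so back-to-back
    repetitions at a no-rest tempo span their full period and adjacent
    cycles share at most the single turnaround frame. The deepest hip
    frame inside the pair is the bottom. Returns cycles in temporal
    order; an empty list (with a warning) if nothing exceeds the
    minimum depth.
    """
    v = kin.vy_hip
    y = kin.y_hip
    state = np.zeros(len(v), dtype=int)
    state[v < -v_eps] = -1
    state[v > v_eps] = 1

    # contiguous runs of -1 (descent) and +1 (ascent)
    runs: list[tuple[int, int, int]] = []  # (state, first, last)
    i = 0
    while i < len(state):
        if state[i] != 0:
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i]:
                j += 1
            runs.append((state[i], i, j))
            i = j + 1
        else:
            i += 1

    cycles: list[SquatCycle] = []
    k = 0
    while k < len(runs) - 1:
        s0, a0, _ = runs[k]
        s1, _, b1 = runs[k + 1]
        if s0 == -1 and s1 == 1:
            start, end = a0, b1
            # extend outward to the standing plateau / turnaround height max
            while start > 0 and y[start - 1] > y[start]:
                start -= 1
            while end + 1 < len(y) and y[end + 1] > y[end]:
                end += 1
            bottom = start + int(np.argmin(y[start : end + 1]))
            if y[start] - y[bottom] >= min_depth_m and start < bottom < end:
                cycles.append(SquatCycle(start, bottom, end))
            k += 2
        else:
            k += 1
    if not cycles:
        warnings.warn("no repetition exceeding the minimum depth was found", stacklevel=2)
    return cycles


def select_analysis_reps(cycles: list[SquatCycle]) -> tuple[SquatCycle, SquatCycle]:
    """Pick the analysis repetitions: the third and the next-to-last.

    The third repetition after initiation characterises the non-fatigued
    movement pattern; the repetition before the last accomplished one
    characterises the fatigued pattern. Both must exist and be distinct.
    """
    n = len(cycles)
    if n < 4:
        raise ValueError(f"need at least 4 repetitions, got {n}")
    third, penultimate = 3, n - 1  # 1-based
    if third == penultimate:
        raise ValueError(
            "third and next-to-last repetition coincide; need at least 5 repetitions"
        )
    return cycles[third - 1], cycles[penultimate - 1]


def find_regions(
    cycle: SquatCycle, kin: JointKinematics, reference_joint: str = "hip"
) -> RegionBoundaries:
    """Locate the peak-velocity frames of both phases (earliest on ties)."""
    speed = np.abs(kin.vy(reference_joint))
    down = cycle.start_idx + int(
        np.argmax(speed[cycle.start_idx : cycle.bottom_idx + 1])
    )
    up = cycle.bottom_idx + int(np.argmax(speed[cycle.bottom_idx : cycle.end_idx + 1]))
    return RegionBoundaries(downpeak_idx=down, uppeak_idx=up)


def _mean_speed(v: np.ndarray, lo: int, hi: int) -> float:
    """Mean |v| over frames lo..hi inclusive."""
    return float(np.mean(np.abs(v[lo : hi + 1])))


def _endpoint_acc(v: np.ndarray, lo: int, hi: int, fs: float) -> float:
    """|Delta v / Delta t| between the region's endpoint frames.

    Identical to the mean of the instantaneous (central-difference)
    acceleration over the region, up to the one-sided end stencils.
    """
    dt = (hi - lo) / fs
    if dt <= 0:
        return float("nan")
    return float(abs(v[hi] - v[lo]) / dt)


def region_metrics(
    cycle: SquatCycle,
    bounds: RegionBoundaries,
    kin: JointKinematics,
    rom_ext_mode: str = "bottom",
) -> RegionMetrics:
    """Compute the full per-repetition metric set.

    Durations use the shared-boundary half-open convention
    (``t_V1down = (downpeak - start) / fs`` etc.), so the four region
    durations add up to the repetition duration exactly. Mean speeds
    average magnitudes over the region's frames (endpoints inclusive);
    peaks and angles are read at the boundary frames. ROM_Flex is
    ``180 - angle`` at the deepest frame; ROM_Ext by default mirrors it
    (``rom_ext_mode="bottom"``, the magnitude of bottom angle minus 180);
    ``rom_ext_mode="end"`` instead uses the excursion recovered by the
    extension end, which need not return exactly to 180.
    """
    if rom_ext_mode not in ("bottom", "end"):
        raise ValueError(f"unknown rom_ext_mode {rom_ext_mode!r}")
    fs = kin.sampling_rate_hz
    s, b, e = cycle.start_idx, cycle.bottom_idx, cycle.end_idx
    dp, up = bounds.downpeak_idx, bounds.uppeak_idx

    regions = {
        "V1down": (s, dp), "V2down": (dp, b),
        "V1up": (b, up), "V2up": (up, e),
        "Vflex": (s, b), "Vext": (b, e),
    }
    degenerate = any(hi - lo < 2 for lo, hi in
                     (regions["V1down"], regions["V2down"],
                      regions["V1up"], regions["V2up"]))
    if degenerate:
        logger.warning(
            "degenerate region (<2 frames) in cycle %d-%d-%d", s, b, e
        )

    vals: dict[str, float] = {}
    for joint in LINEAR_JOINTS:
        v = kin.vy(joint)
        for name, (lo, hi) in regions.items():
            vals[f"{name}_{joint}"] = _mean_speed(v, lo, hi)
        vals[f"Vdownpeak_{joint}"] = float(abs(v[dp]))
        vals[f"Vuppeak_{joint}"] = float(abs(v[up]))
        vals[f"Descent_Acc_{joint}"] = _endpoint_acc(v, s, dp, fs)
        vals[f"Descent_Dec_{joint}"] = _endpoint_acc(v, dp, b, fs)
        vals[f"Ascent_Acc_{joint}"] = _endpoint_acc(v, b, up, fs)
        vals[f"Ascent_Dec_{joint}"] = _endpoint_acc(v, up, e, fs)

    for joint in ANGULAR_JOINTS:
        ang = kin.angle(joint)
        w = kin.angvel(joint)
        vals[f"Vdownpeak_Angle_{joint}"] = float(ang[dp])
        vals[f"Vuppeak_Angle_{joint}"] = float(ang[up])
        vals[f"ROM_Flex_{joint}"] = float(180.0 - ang[b])
        if rom_ext_mode == "bottom":
            vals[f"ROM_Ext_{joint}"] = float(abs(ang[b] - 180.0))
        else:
            vals[f"ROM_Ext_{joint}"] = float(ang[e] - ang[b])
        for name, (lo, hi) in regions.items():
            key = {"Vflex": "Flex", "Vext": "Ext"}.get(name, name)
            vals[f"{key}_Deg_Velo_{joint}"] = float(np.mean(w[lo : hi + 1]))

    vals["t_V1down"] = (dp - s) / fs
    vals["t_V2down"] = (b - dp) / fs
    vals["t_Vflex"] = (b - s) / fs
    vals["t_V1up"] = (up - b) / fs
    vals["t_V2up"] = (e - up) / fs
    vals["t_Vext"] = (e - b) / fs
    vals["t_total"] = (e - s) / fs
    return RegionMetrics(values=vals, degenerate=degenerate)
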