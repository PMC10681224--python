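"""Sticking-region detection on ascent vertical-velocity traces.

A sticking region is a transient deceleration followed by re-acceleration
during the ascent: the velocity rises from V0 (ascent start) to a first
peak Vmax1, dips to a local minimum Vmin without reversing direction, and
rises again to a second peak Vmax2. The pre-sticking region spans
V0->Vmax1, the sticking region Vmax1->Vmin, post-sticking Vmin->Vmax2.

The detector declares a sticking region only when the dip is deep enough
(fractional depth >= ``min_depth_frac``), long enough
(>= ``min_dip_s``), the velocity at the minimum stays positive and
above a floor fraction of the trace maximum (``min_floor_frac``), and
the second peak re-accelerates to a substantial fraction of the first
(``min_vmax2_frac``); a strictly unimodal ascent never fires. The floor
and re-acceleration criteria separate a genuine mid-ascent dip from the
low-velocity wiggles around the terminal deceleration into standing.
These numeric thresholds are detection choices (defaults 5%, 0.03 s,
10% and 50%), set so that a worked-example dip of 0.1 s is found while
noise around the movement endpoints is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass
class StickingEvent:
    """Landmarks and durations of one (possible) sticking region."""

    detected: bool
    v0_idx: int | None = None
    vmax1_idx: int | None = None
    vmin_idx: int | None = None
    vmax2_idx: int | None = None
    t_pre_s: float | None = None
    t_stick_s: float | None = None
    t_total_s: float | None = None
    dip_depth_frac: float | None = None
    angles_at_landmarks: dict[str, dict[str, float]] = field(default_factory=dict)


def detect_sticking(
    ascent_velocity: np.ndarray,
    sampling_rate_hz: float,
    kin_angles: Mapping[str, np.ndarray] | None = None,
    min_depth_frac: float = 0.05,
    min_dip_s: float = 0.03,
    min_floor_frac: float = 0.10,
    min_vmax2_frac: float = 0.50,
) -> StickingEvent:
    """Find the first qualifying Vmax1 -> Vmin -> Vmax2 pattern.

    ``ascent_velocity`` covers one ascent starting at (approximately)
    zero velocity; V0 is its first frame. Interior local maxima and the
    subsequent minima are scanned in temporal order and the first pair
    satisfying the depth, duration and positivity criteria — with a
    further local maximum after the minimum — is reported. When
    ``kin_angles`` maps joint names to per-frame angle series, the angles
    at V0, Vmax1 and Vmin are included.
    """
    v = np.asarray(ascent_velocity, dtype=float)
    if v.size < 3:
        raise ValueError("ascent trace must have at least 3 frames")
    fs = sampling_rate_hz

    peaks, _ = find_peaks(v)
    troughs, _ = find_peaks(-v)
    for p in peaks:
        later_troughs = troughs[troughs > p]
        if later_troughs.size == 0:
            continue
        m = int(later_troughs[0])
        later_peaks = peaks[peaks > m]
        if later_peaks.size == 0:
            continue
        p2 = int(later_peaks[0])
        if v[p] <= 0:
            continue
        depth = (v[p] - v[m]) / v[p]
        deep_enough = depth >= min_depth_frac
        long_enough = (m - p) / fs >= min_dip_s
        above_floor = v[m] > 0 and v[m] >= min_floor_frac * v.max()
        reaccelerates = v[p2] >= min_vmax2_frac * v[p]
        if deep_enough and long_enough and above_floor and reaccelerates:
            angles = {}
            if kin_angles is not None:
                for joint, series in kin_angles.items():
                    series = np.asarray(series, dtype=float)
                    angles[joint] = {
                        "v0": float(series[0]),
                        "vmax1": float(series[p]),
                        "vmin": float(series[m]),
                    }
            return StickingEvent(
                detected=True,
                v0_idx=0,
                vmax1_idx=int(p),
                vmin_idx=m,
                vmax2_idx=p2,
                t_pre_s=p / fs,
                t_stick_s=(m - p) / fs,
                t_total_s=m / fs,
                dip_depth_frac=float(depth),
                angles_at_landmarks=angles,
            )
    return StickingEvent(detected=False)


def batch_sticking_report(
    traces: Iterable[tuple[str, str, np.ndarray, float]],
    kin_angles: Mapping[tuple[str, str], Mapping[str, np.ndarray]] | None = None,
    min_depth_frac: float = 0.05,
    min_dip_s: float = 0.03,
    min_floor_frac: float = 0.10,
) -> tuple[pd.DataFrame, float]:
    """Run the detector over a cohort's ascent traces.

    ``traces`` yields ``(participant_id, condition, ascent_velocity,
    sampling_rate_hz)``. Returns one row per participant x condition with
    the verdict and landmark quantities, plus the detection prevalence:
    the fraction of participants showing a sticking region in at least
    one condition.
    """
    rows = []
    detected_by: set[str] = set()
    participants: set[str] = set()
    for pid, condition, v, fs in traces:
        angles = kin_angles.get((pid, condition)) if kin_angles else None
        ev = detect_sticking(
            v, fs, kin_angles=angles,
            min_depth_frac=min_depth_frac, min_dip_s=min_dip_s,
            min_floor_frac=min_floor_frac,
        )
        participants.add(pid)
        if ev.detected:
            detected_by.add(pid)
        rows.append(
            {
                "participant_id": pid,
                "condition": condition,
                "detected": ev.detected,
                "t_pre_s": ev.t_pre_s,
                "t_stick_s": ev.t_stick_s,
                "t_total_s": ev.t_total_s,
                "dip_depth_frac": ev.dip_depth_frac,
            }
        )
    prevalence = len(detected_by) / len(participants) if participants else 0.0
    return pd.DataFrame(rows), prevalence
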