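"""Joint-angle and linear/angular kinematics from 2-D marker trajectories.

The marker set follows the standard right-side sagittal convention for a
squat: acromion (shoulder), trochanter major (hip), epicondylus lateralis
(knee), malleolus lateralis (ankle) and caput metatarsalis (toe).
Coordinates are x anterior, y vertical up, in meters.

Joint angles are interior three-point angles:

* hip   = angle(acromion, trochanter, epicondyle)
* knee  = angle(trochanter, epicondyle, malleolus)
* ankle = angle(epicondyle, malleolus, toe)

so that a neutral standing posture reads hip 180 deg, knee 180 deg,
ankle 90 deg. Angular velocities are reported as magnitudes in rad/s;
vertical linear velocities and accelerations are taken from the y
coordinates of the shoulder, hip and knee markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

MARKER_NAMES = ("acromion", "trochanter", "epicondyle", "malleolus", "toe")

#: joint name -> (marker a, vertex marker b, marker c)
JOINT_DEFS = {
    "hip": ("acromion", "trochanter", "epicondyle"),
    "knee": ("trochanter", "epicondyle", "malleolus"),
    "ankle": ("epicondyle", "malleolus", "toe"),
}

#: vertical-velocity "joints" -> marker whose y coordinate is tracked
LINEAR_JOINTS = {
    "shoulder": "acromion",
    "hip": "trochanter",
    "knee": "epicondyle",
}


class ParameterError(ValueError):
    """Invalid numeric parameter (non-finite, wrong sign, out of range)."""


@dataclass
class MarkerTrajectorySet:
    """Per-frame 2-D positions of the five sagittal squat markers.

    Attributes
    ----------
    sampling_rate_hz : float
        Uniform capture rate (the study design targets 100 Hz).
    markers : dict[str, np.ndarray]
        Maps each name in :data:`MARKER_NAMES` to an ``(n_frames, 2)``
        array of ``(x, y)`` positions in meters.
    participant_id, condition : str
        Free-form labels carried through the pipeline.
    """

    sampling_rate_hz: float
    markers: dict[str, np.ndarray]
    participant_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise ValueError(f"missing marker(s): {', '.join(missing)}")
        n = {len(v) for v in self.markers.values()}
        if len(n) != 1:
            raise ValueError("marker arrays have unequal lengths")
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"marker {name!r} must be (n_frames, 2)")
            if not np.isfinite(arr).all():
                raise ValueError(f"marker {name!r} contains non-finite values")
            self.markers[name] = arr
        if not (np.isfinite(self.sampling_rate_hz) and self.sampling_rate_hz > 0):
            raise ParameterError("sampling_rate_hz must be positive and finite")

    @property
    def n_frames(self) -> int:
        return len(self.markers[MARKER_NAMES[0]])

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate_hz

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            sampling_rate_hz=self.sampling_rate_hz,
            markers={k: v.copy() for k, v in self.markers.items()},
            participant_id=self.participant_id,
            condition=self.condition,
        )


@dataclass
class JointKinematics:
    """Derived per-frame kinematics for one trial.

    Angles are interior angles in degrees; ``*_angvel`` are angular speed
    magnitudes in rad/s; ``vy_*`` are signed vertical velocities in m/s
    (negative while descending); ``ay_*`` vertical accelerations in m/s^2.
    Filtered vertical positions ``y_*`` are kept because repetition
    detection needs them.
    """

    sampling_rate_hz: float
    time_s: np.ndarray
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    ankle_deg: np.ndarray
    hip_angvel: np.ndarray
    knee_angvel: np.ndarray
    vy_shoulder: np.ndarray
    vy_hip: np.ndarray
    vy_knee: np.ndarray
    ay_shoulder: np.ndarray
    ay_hip: np.ndarray
    ay_knee: np.ndarray
    y_shoulder: np.ndarray
    y_hip: np.ndarray
    y_knee: np.ndarray
    participant_id: str = ""
    condition: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def angle(self, joint: str) -> np.ndarray:
        return {"hip": self.hip_deg, "knee": self.knee_deg, "ankle": self.ankle_deg}[joint]

    def vy(self, joint: str) -> np.ndarray:
        return {"shoulder": self.vy_shoulder, "hip": self.vy_hip, "knee": self.vy_knee}[joint]

    def ay(self, joint: str) -> np.ndarray:
        return {"shoulder": self.ay_shoulder, "hip": self.ay_hip, "knee": self.ay_knee}[joint]

    def angvel(self, joint: str) -> np.ndarray:
        return {"hip": self.hip_angvel, "knee": self.knee_angvel}[joint]

    def to_frame(self) -> pd.DataFrame:
        """Tabular per-frame export; column names carry the units."""
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "hip_deg": self.hip_deg,
                "knee_deg": self.knee_deg,
                "ankle_deg": self.ankle_deg,
                "hip_angvel_rad_s": self.hip_angvel,
                "knee_angvel_rad_s": self.knee_angvel,
                "vy_shoulder_m_s": self.vy_shoulder,
                "vy_hip_m_s": self.vy_hip,
                "vy_knee_m_s": self.vy_knee,
                "ay_shoulder_m_s2": self.ay_shoulder,
                "ay_hip_m_s2": self.ay_hip,
                "ay_knee_m_s2": self.ay_knee,
            }
        )


def lowpass(series: np.ndarray, cutoff_hz: float, sampling_rate_hz: float) -> np.ndarray:
    """Zero-lag low-pass filter (effective 4th-order Butterworth).

    A 2nd-order Butterworth applied forward and backward (``filtfilt``),
    the standard smoothing for human-movement signals. Returns a filtered
    copy; the input is untouched.
    """
    series = np.asarray(series, dtype=float)
    nyq = sampling_rate_hz / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    b, a = signal.butter(2, cutoff_hz / nyq)
    return signal.filtfilt(b, a, series)


def joint_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at vertex ``b`` between rays b->a and b->c, degrees.

    All inputs are ``(n, 2)`` point arrays; the result lies in [0, 180].
    """
    a, b, c = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = np.flatnonzero((nu == 0) | (nv == 0))
    if bad.size:
        raise ValueError(f"coincident points at frame {bad[0]}")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def differentiate(series: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Time derivative: central differences inside, one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series) * sampling_rate_hz


def compute_kinematics(
    traj: MarkerTrajectorySet, cutoff_hz: float | None = 6.0
) -> JointKinematics:
    """Full kinematic derivation for one trial.

    Marker positions are low-pass filtered (pass ``cutoff_hz=None`` to
    skip smoothing, e.g. on noise-free synthetic data), joint angles are
    computed from the filtered positions, angular speed is the magnitude
    of the angle derivative in rad/s, and vertical velocities and
    accelerations come from the shoulder/hip/knee marker y coordinates.
    """
    fs = traj.sampling_rate_hz
    if cutoff_hz is None:
        pos = {m: traj.markers[m] for m in MARKER_NAMES}
    else:
        pos = {
            m: np.column_stack(
                [lowpass(traj.markers[m][:, 0], cutoff_hz, fs),
                 lowpass(traj.markers[m][:, 1], cutoff_hz, fs)]
            )
            for m in MARKER_NAMES
        }

    angles = {
        j: joint_angle(pos[a], pos[b], pos[c]) for j, (a, b, c) in JOINT_DEFS.items()
    }
    angvel = {
        j: np.abs(np.radians(differentiate(angles[j], fs))) for j in ("hip", "knee")
    }
    ys = {j: pos[m][:, 1] for j, m in LINEAR_JOINTS.items()}
    vy = {j: differentiate(ys[j], fs) for j in ys}
    ay = {j: differentiate(vy[j], fs) for j in ys}

    return JointKinematics(
        sampling_rate_hz=fs,
        time_s=traj.time_s,
        hip_deg=angles["hip"],
        knee_deg=angles["knee"],
        ankle_deg=angles["ankle"],
        hip_angvel=angvel["hip"],
        knee_angvel=angvel["knee"],
        vy_shoulder=vy["shoulder"],
        vy_hip=vy["hip"],
        vy_knee=vy["knee"],
        ay_shoulder=ay["shoulder"],
        ay_hip=ay["hip"],
        ay_knee=ay["knee"],
        y_shoulder=ys["shoulder"],
        y_hip=ys["hip"],
        y_knee=ys["knee"],
        participant_id=traj.participant_id,
        condition=traj.condition,
    )
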