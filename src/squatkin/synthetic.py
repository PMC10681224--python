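"""Forward-kinematic synthetic squat motion.

Generates marker trajectories for body-weight squat trials so the whole
pipeline (kinematics -> segmentation -> sticking -> statistics) can be
exercised and validated without motion-capture data.

Model
-----
The body is a planar four-segment chain (foot, shank, thigh, trunk) seen
from the right side; x anterior, y vertical up, meters. The ankle
(malleolus) is fixed at the origin and the toe at ``(foot_m, 0)`` —
a closed-chain squat with the foot flat on the ground. Per repetition the
interior hip and knee angles follow a raised-cosine profile from the
standing pose (hip 180 deg, knee 180 deg, ankle 90 deg) down to
``180 - ROM`` and back, one full cosine cycle per repetition, which gives
smooth bounded derivatives and a single velocity peak per phase. The
shank forward-lean angle is chosen in closed form so the hip stays
vertically above the ankle (balance closure; no sliding), and the ankle
angle follows from it. The acromion rides rigidly on the trunk segment —
arm motion is not modeled.

Fatigue within a trial is a per-repetition multiplicative drift applied
linearly from the first to the last repetition on the hip/knee excursion
(at fixed tempo this scales velocities in proportion). Marker jitter is
i.i.d. Gaussian noise per frame and coordinate. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinematics import (
    MARKER_NAMES,
    MarkerTrajectorySet,
    ParameterError,
    compute_kinematics,
)

STANDING_HIP_DEG = 180.0
STANDING_KNEE_DEG = 180.0
STANDING_ANKLE_DEG = 90.0


@dataclass(frozen=True)
class SegmentLengths:
    """Body segment lengths in meters (plausible adult anthropometry)."""

    trunk_m: float = 0.52
    thigh_m: float = 0.45
    shank_m: float = 0.43
    foot_m: float = 0.15

    def __post_init__(self) -> None:
        for name in ("trunk_m", "thigh_m", "shank_m", "foot_m"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class TrialParams:
    """One squat trial: tempo, depth, drift, noise and sampling.

    ``tempo_bpm`` is the metronome cadence of the 1:0:1:0 tempo (one
    count down, one count up, no pauses), so a repetition lasts
    ``2 * 60 / tempo_bpm`` seconds. ``rom_hip_deg``/``rom_knee_deg`` are
    the flexion excursions: at the bottom the joint reads ``180 - ROM``.
    ``fatigue_drift`` is the fractional increase of the excursion reached
    by the final repetition (0 = no drift). ``noise_sd_m`` is the marker
    jitter standard deviation.
    """

    tempo_bpm: float = 45.0
    n_reps: int = 8
    rom_hip_deg: float = 100.0
    rom_knee_deg: float = 95.0
    fatigue_drift: float = 0.0
    noise_sd_m: float = 0.002
    sampling_rate_hz: float = 100.0
    seed: int = 0
    lead_s: float = 0.5  # standing plateau before and after the reps

    def __post_init__(self) -> None:
        checks = {
            "tempo_bpm": self.tempo_bpm > 0,
            "n_reps": self.n_reps >= 3,
            "rom_hip_deg": 0 <= self.rom_hip_deg < 180,
            "rom_knee_deg": 0 <= self.rom_knee_deg < 180,
            "fatigue_drift": self.fatigue_drift > -1,
            "noise_sd_m": self.noise_sd_m >= 0,
            "sampling_rate_hz": self.sampling_rate_hz > 0,
            "lead_s": self.lead_s >= 0,
        }
        for name, ok in checks.items():
            v = getattr(self, name)
            if not (np.all(np.isfinite(v)) and ok):
                raise ParameterError(f"invalid {name}: {v!r}")

    @property
    def rep_period_s(self) -> float:
        return 2.0 * 60.0 / self.tempo_bpm


@dataclass(frozen=True)
class StickingDipParams:
    """Shape of an injected ascent velocity dip.

    ``t_pre_s``: ascent start (V0) to first velocity peak (Vmax1);
    ``t_dip_s``: Vmax1 to the local minimum (Vmin);
    ``dip_depth_frac``: (Vmax1 - Vmin) / Vmax1, in (0, 1);
    ``t_recover_s``: Vmin to the second peak (Vmax2).
    """

    t_pre_s: float = 0.06
    t_dip_s: float = 0.10
    dip_depth_frac: float = 0.30
    t_recover_s: float = 0.20

    def __post_init__(self) -> None:
        for name in ("t_pre_s", "t_dip_s", "t_recover_s"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive, got {v}")
        if not (np.isfinite(self.dip_depth_frac) and 0 < self.dip_depth_frac < 1):
            raise ParameterError(
                f"dip_depth_frac must be in (0, 1), got {self.dip_depth_frac}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """A two-condition cohort with a low/high muscle-ratio group structure.

    ``llmr_values`` are lower-limb muscle ratio percentages, one per
    participant; the median split assigns the lower half to the "low"
    group. ``group_effects`` maps group label -> additive offsets on
    :class:`TrialParams` fields; ``condition_effects`` maps field ->
    offset applied to the fatigue trial only (a ``(add, mul)`` tuple is
    also accepted). Between-participant variation is a Gaussian offset on
    both excursions (``rom_sd_deg``); trial-to-trial variation adds an
    independent ``trial_rom_sd_deg`` per trial. Hip and knee excursion
    offsets are drawn with correlation ``rom_correlation`` — people who
    squat deeper flex both joints more, which is what couples shoulder
    and hip velocities across a cohort.
    """

    n_participants: int
    llmr_values: tuple[float, ...]
    group_effects: dict = field(default_factory=dict)
    condition_effects: dict = field(default_factory=dict)
    seed: int = 0
    rom_sd_deg: float = 8.0
    trial_rom_sd_deg: float = 2.0
    rom_correlation: float = 0.8

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ParameterError("need at least 2 participants")
        if len(self.llmr_values) != self.n_participants:
            raise ParameterError("llmr_values length must equal n_participants")
        if not all(0 < v < 100 for v in self.llmr_values):
            raise ParameterError("LLMR values must lie in (0, 100) percent")
        for sd in (self.rom_sd_deg, self.trial_rom_sd_deg):
            if not (np.isfinite(sd) and sd >= 0):
                raise ParameterError("ROM standard deviations must be >= 0")
        if not -1.0 <= self.rom_correlation <= 1.0:
            raise ParameterError("rom_correlation must lie in [-1, 1]")


@dataclass
class CohortMember:
    """One generated trial of a cohort: who, which group, which condition."""

    participant_id: str
    llmr_pct: float
    group: str
    condition: str
    trajectory: MarkerTrajectorySet


@dataclass
class AscentFixture:
    """A 1-D ascent vertical-velocity trace with known landmark samples."""

    velocity: np.ndarray
    sampling_rate_hz: float
    landmarks: dict[str, int]  # v0, vmax1, vmin, vmax2 sample indices
    snapped: bool  # True if any landmark time was snapped to the frame grid

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.velocity)) / self.sampling_rate_hz


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """0 -> 1 -> 0 over u in [0, 1]; one full cosine cycle."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _joint_profiles(params: TrialParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prescribed hip/knee interior angle time courses and the time grid."""
    fs = params.sampling_rate_hz
    T = params.rep_period_s
    total_s = 2 * params.lead_s + params.n_reps * T
    n = int(round(total_s * fs)) + 1
    t = np.arange(n) / fs

    hip = np.full(n, STANDING_HIP_DEG)
    knee = np.full(n, STANDING_KNEE_DEG)
    for r in range(params.n_reps):
        drift = 1.0 + params.fatigue_drift * (
            r / (params.n_reps - 1) if params.n_reps > 1 else 0.0
        )
        t0 = params.lead_s + r * T
        sel = (t >= t0) & (t <= t0 + T)
        u = (t[sel] - t0) / T
        hip[sel] = STANDING_HIP_DEG - params.rom_hip_deg * drift * _raised_cosine(u)
        knee[sel] = STANDING_KNEE_DEG - params.rom_knee_deg * drift * _raised_cosine(u)
    return t, hip, knee


def pose_markers(
    hip_deg: np.ndarray, knee_deg: np.ndarray, segments: SegmentLengths
) -> dict[str, np.ndarray]:
    """Planar forward kinematics: interior joint angles -> marker positions.

    The malleolus sits at the origin, the toe at ``(foot_m, 0)``. The
    shank lean from vertical ``phi`` solves the balance closure that
    keeps the trochanter at x = 0:

        tan(phi) = thigh * sin(beta) / (shank + thigh * cos(beta)),
        beta = 180 deg - knee angle.

    Segment absolute directions (angle from +y, positive forward): shank
    ``phi``; thigh (knee->hip) ``phi - beta``; trunk (hip->shoulder)
    ``phi - beta + (180 - hip angle)``. Standing (180/180) reproduces a
    vertical stack with ankle angle 90 deg.
    """
    hip_deg = np.asarray(hip_deg, dtype=float)
    knee_deg = np.asarray(knee_deg, dtype=float)
    beta = np.radians(180.0 - knee_deg)
    phi = np.arctan2(
        segments.thigh_m * np.sin(beta),
        segments.shank_m + segments.thigh_m * np.cos(beta),
    )
    a_thigh = phi - beta
    a_trunk = a_thigh + np.radians(180.0 - hip_deg)

    def step(origin, length, ang):
        return origin + length * np.column_stack([np.sin(ang), np.cos(ang)])

    n = len(hip_deg)
    malleolus = np.zeros((n, 2))
    toe = np.column_stack([np.full(n, segments.foot_m), np.zeros(n)])
    epicondyle = step(malleolus, segments.shank_m, phi)
    trochanter = step(epicondyle, segments.thigh_m, a_thigh)
    acromion = step(trochanter, segments.trunk_m, a_trunk)
    return {
        "acromion": acromion,
        "trochanter": trochanter,
        "epicondyle": epicondyle,
        "malleolus": malleolus,
        "toe": toe,
    }


def generate_trial(
    params: TrialParams, segments: SegmentLengths | None = None
) -> MarkerTrajectorySet:
    """Generate one squat trial as a marker trajectory set.

    Deterministic given ``params.seed``; Gaussian jitter of standard
    deviation ``noise_sd_m`` is added independently per frame and
    coordinate.
    """
    segments = segments or SegmentLengths()
    _, hip, knee = _joint_profiles(params)
    markers = pose_markers(hip, knee, segments)
    rng = np.random.default_rng(params.seed)
    if params.noise_sd_m > 0:
        for name in MARKER_NAMES:
            markers[name] = markers[name] + rng.normal(
                0.0, params.noise_sd_m, markers[name].shape
            )
    return MarkerTrajectorySet(
        sampling_rate_hz=params.sampling_rate_hz, markers=markers
    )


def _dip_profile(
    tau: np.ndarray, t_asc: float, dip: StickingDipParams, vmax2_ratio: float = 1.0
) -> np.ndarray:
    """Unit-Vmax1 ascent velocity with an interior dip; 0 at both ends."""
    t1 = dip.t_pre_s
    t2 = t1 + dip.t_dip_s
    t3 = t2 + dip.t_recover_s
    if t3 >= t_asc:
        raise ValueError(
            f"dip timing ({t3:.3f} s) must fit inside the ascent ({t_asc:.3f} s)"
        )
    vmin = 1.0 - dip.dip_depth_frac
    v = np.empty_like(tau)
    seg0 = tau <= t1
    v[seg0] = 0.5 * (1.0 - np.cos(np.pi * tau[seg0] / t1))
    seg1 = (tau > t1) & (tau <= t2)
    v[seg1] = 1.0 - dip.dip_depth_frac * 0.5 * (
        1.0 - np.cos(np.pi * (tau[seg1] - t1) / dip.t_dip_s)
    )
    seg2 = (tau > t2) & (tau <= t3)
    v[seg2] = vmin + (vmax2_ratio - vmin) * 0.5 * (
        1.0 - np.cos(np.pi * (tau[seg2] - t2) / dip.t_recover_s)
    )
    seg3 = tau > t3
    v[seg3] = vmax2_ratio * 0.5 * (1.0 + np.cos(np.pi * (tau[seg3] - t3) / (t_asc - t3)))
    return v


def inject_sticking(
    trial: MarkerTrajectorySet, rep_index: int, dip: StickingDipParams
) -> MarkerTrajectorySet:
    """Reshape one repetition's ascent to carry a sticking-style dip.

    The selected repetition's ascent vertical hip-velocity profile is
    replaced by a piecewise raised-cosine curve rising to Vmax1 at
    ``t_pre_s``, dipping by ``dip_depth_frac`` over ``t_dip_s``,
    recovering to Vmax2 over ``t_recover_s`` and decaying to zero at the
    ascent end. The profile is scaled so its integral equals the original
    net vertical displacement, the new hip height trace is integrated
    from it, and all markers are re-sampled by time-warping the original
    ascent (the pose as a function of hip height is preserved), so chain
    geometry, position continuity and net displacement are intact. All
    other repetitions are untouched.

    ``rep_index`` is 0-based into the repetitions detected on the trial.
    """
    from .segmentation import detect_repetitions  # local: avoid import cycle

    kin = compute_kinematics(trial, cutoff_hz=None)
    cycles = detect_repetitions(kin)
    if not 0 <= rep_index < len(cycles):
        raise IndexError(f"rep_index {rep_index} outside 0..{len(cycles) - 1}")
    cyc = cycles[rep_index]
    fs = trial.sampling_rate_hz
    lo, hi = cyc.bottom_idx, cyc.end_idx  # ascent, inclusive
    t_asc = (hi - lo) / fs
    tau = (np.arange(hi - lo + 1)) / fs

    y0 = kin.y_hip[lo : hi + 1]
    net = y0[-1] - y0[0]
    shape = _dip_profile(tau, t_asc, dip)
    area = np.trapezoid(shape, dx=1.0 / fs)
    v_new = shape * (net / area)
    y_new = y0[0] + cumulative_trapezoid(v_new, dx=1.0 / fs, initial=0.0)
    y_new[-1] = y0[-1]  # guard the endpoint against roundoff

    # Time-warp: the ascent pose is a monotone function of hip height, so
    # map each new height back to the original time axis and resample.
    t_orig = tau
    y_mono = np.maximum.accumulate(y0)  # strictly monotone up to roundoff
    warped_t = np.interp(y_new, y_mono, t_orig)

    out = trial.copy()
    for name in MARKER_NAMES:
        for col in (0, 1):
            series = trial.markers[name][lo : hi + 1, col]
            out.markers[name][lo : hi + 1, col] = np.interp(warped_t, t_orig, series)
    return out


def _apply_effects(params: TrialParams, effects: dict) -> TrialParams:
    """Additive (float) or (add, mul) offsets on TrialParams fields."""
    changes = {}
    for name, eff in effects.items():
        base = getattr(params, name)
        if isinstance(eff, (tuple, list)):
            add, mul = eff
        else:
            add, mul = eff, 1.0
        changes[name] = base * mul + add
    return replace(params, **changes) if changes else params


def generate_cohort(
    config: CohortConfig,
    params: TrialParams,
    segments: SegmentLengths | None = None,
) -> list[CohortMember]:
    """Generate a two-condition cohort (non-fatigue and fatigue trials).

    Group labels come from the median split of ``llmr_values`` (lower
    half "low"). For each participant, the base ``params`` receive the
    participant's group effects and a Gaussian between-participant ROM
    offset; the fatigue trial additionally receives
    ``config.condition_effects``. Deterministic given ``config.seed``.
    """
    from .stats import assign_groups  # local: stats does not import synthetic

    groups = assign_groups(dict(enumerate(config.llmr_values)))
    rng = np.random.default_rng(config.seed)
    rho = config.rom_correlation

    def correlated_pair(sd: float) -> np.ndarray:
        z = rng.normal(size=2)
        return sd * np.array([z[0], rho * z[0] + np.sqrt(1.0 - rho**2) * z[1]])

    members: list[CohortMember] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        group = groups[i]
        subj_rom = correlated_pair(config.rom_sd_deg)
        p_subj = _apply_effects(params, config.group_effects.get(group, {}))
        p_subj = replace(
            p_subj,
            rom_hip_deg=max(p_subj.rom_hip_deg + subj_rom[0], 5.0),
            rom_knee_deg=max(p_subj.rom_knee_deg + subj_rom[1], 5.0),
        )
        for condition in ("nonfatigue", "fatigue"):
            p_trial = p_subj
            if condition == "fatigue":
                p_trial = _apply_effects(p_trial, config.condition_effects)
            trial_rom = correlated_pair(config.trial_rom_sd_deg)
            seed = int(rng.integers(0, 2**31 - 1))
            p_trial = replace(
                p_trial,
                rom_hip_deg=max(p_trial.rom_hip_deg + trial_rom[0], 5.0),
                rom_knee_deg=max(p_trial.rom_knee_deg + trial_rom[1], 5.0),
                seed=seed,
            )
            traj = generate_trial(p_trial, segments)
            traj.participant_id = pid
            traj.condition = condition
            members.append(
                CohortMember(
                    participant_id=pid,
                    llmr_pct=config.llmr_values[i],
                    group=group,
                    condition=condition,
                    trajectory=traj,
                )
            )
    return members


def make_ascent_fixture(
    dip: StickingDipParams,
    sampling_rate_hz: float = 100.0,
    ascent_s: float = 0.8,
    vmax1_m_s: float = 1.0,
) -> AscentFixture:
    """Build a 1-D ascent vertical-velocity trace with known landmarks.

    The trace starts at 0 (V0 at sample 0) and carries Vmax1, Vmin and
    Vmax2 exactly at the requested sample times; landmark times that are
    not multiples of the sample interval are snapped to the nearest frame
    and reported via ``snapped``.
    """
    fs = sampling_rate_hz
    if not (np.isfinite(fs) and fs > 0):
        raise ParameterError("sampling_rate_hz must be positive")

    def snap(t: float) -> int:
        return int(round(t * fs))

    i1 = snap(dip.t_pre_s)
    i2 = i1 + snap(dip.t_dip_s)
    i3 = i2 + snap(dip.t_recover_s)
    n = snap(ascent_s)
    snapped = any(
        abs(t * fs - round(t * fs)) > 1e-9
        for t in (dip.t_pre_s, dip.t_dip_s, dip.t_recover_s, ascent_s)
    )
    if snapped:
        warnings.warn("landmark times snapped to the nearest frame", stacklevel=2)
    if not (0 < i1 < i2 < i3 < n):
        raise ValueError("landmark times must be ordered and fit inside the ascent")

    snapped_dip = StickingDipParams(
        t_pre_s=i1 / fs,
        t_dip_s=(i2 - i1) / fs,
        dip_depth_frac=dip.dip_depth_frac,
        t_recover_s=(i3 - i2) / fs,
    )
    tau = np.arange(n + 1) / fs
    v = vmax1_m_s * _dip_profile(tau, n / fs, snapped_dip)
    v[0] = 0.0
    return AscentFixture(
        velocity=v,
        sampling_rate_hz=fs,
        landmarks={"v0": 0, "vmax1": i1, "vmin": i2, "vmax2": i3},
        snapped=snapped,
    )
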