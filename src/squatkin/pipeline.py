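"""End-to-end orchestration: trajectories -> metrics -> statistics.

These functions tie the stages together the way the command-line
interface (and most scripted use) needs them: analyse one trial into the
per-repetition metric rows plus its ascent trace, sweep a cohort, and
run the statistical battery on the resulting long-format table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import JointKinematics, MarkerTrajectorySet, compute_kinematics
from .segmentation import (
    RegionMetrics,
    detect_repetitions,
    find_regions,
    region_metrics,
    select_analysis_reps,
)
from .sticking import batch_sticking_report
from . import stats as _stats

logger = logging.getLogger(__name__)


@dataclass
class TrialAnalysis:
    """One analysed trial: selected repetition, metrics and ascent trace."""

    participant_id: str
    condition: str
    metrics: RegionMetrics
    ascent_velocity: np.ndarray
    ascent_angles: dict[str, np.ndarray]
    sampling_rate_hz: float


def analyze_trial(
    traj: MarkerTrajectorySet,
    cutoff_hz: float | None = 6.0,
    reference_joint: str = "hip",
    rom_ext_mode: str = "bottom",
) -> TrialAnalysis:
    """Analyse one trial using its condition label to pick the repetition.

    Repetitions are detected on the hip vertical velocity; a trial
    labelled "fatigue" contributes its next-to-last repetition,
    anything else the third. The ascent velocity trace of the selected
    repetition (for sticking detection) is returned alongside the region
    metrics.
    """
    kin = compute_kinematics(traj, cutoff_hz=cutoff_hz)
    cycles = detect_repetitions(kin)
    nonfat, fat = select_analysis_reps(cycles)
    cycle = fat if traj.condition == "fatigue" else nonfat
    bounds = find_regions(cycle, kin, reference_joint=reference_joint)
    metrics = region_metrics(cycle, bounds, kin, rom_ext_mode=rom_ext_mode)
    lo, hi = cycle.bottom_idx, cycle.end_idx
    ascent_v = np.abs(kin.vy(reference_joint)[lo : hi + 1])
    angles = {j: kin.angle(j)[lo : hi + 1] for j in ("hip", "knee", "ankle")}
    return TrialAnalysis(
        participant_id=traj.participant_id,
        condition=traj.condition,
        metrics=metrics,
        ascent_velocity=ascent_v,
        ascent_angles=angles,
        sampling_rate_hz=traj.sampling_rate_hz,
    )


def analyze_cohort(
    trials: list[MarkerTrajectorySet],
    llmr: dict[str, float],
    cutoff_hz: float | None = 6.0,
    reference_joint: str = "hip",
    rom_ext_mode: str = "bottom",
    sticking_depth: float = 0.05,
    sticking_min_s: float = 0.03,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Analyse a cohort of labelled trials.

    Returns the long-format metrics table (with group labels from the
    LLMR median split), the sticking report and the sticking prevalence.
    Trials whose repetition detection fails are excluded and logged; the
    run continues.
    """
    groups = _stats.assign_groups(llmr)
    tables = []
    traces = []
    for traj in trials:
        try:
            ana = analyze_trial(
                traj, cutoff_hz=cutoff_hz, reference_joint=reference_joint,
                rom_ext_mode=rom_ext_mode,
            )
        except ValueError as exc:
            logger.warning(
                "participant %s (%s) excluded: %s",
                traj.participant_id, traj.condition, exc,
            )
            continue
        rows = ana.metrics.to_rows(traj.participant_id, traj.condition)
        rows["group"] = groups[traj.participant_id]
        rows["llmr_pct"] = llmr[traj.participant_id]
        tables.append(rows)
        traces.append(
            (traj.participant_id, traj.condition, ana.ascent_velocity,
             traj.sampling_rate_hz)
        )
    if not tables:
        raise ValueError("no trial could be analysed")
    table = pd.concat(tables, ignore_index=True)
    report, prevalence = batch_sticking_report(
        traces, min_depth_frac=sticking_depth, min_dip_s=sticking_min_s
    )
    return table, report, prevalence


def run_stats(
    table: pd.DataFrame,
    degree: int = 2,
    regression_direction: str = "shoulder_to_hip",
    screen_outliers: bool = True,
) -> dict:
    """The statistical battery on a long-format metrics table.

    Runs the per-variable mixed ANOVA / ICC battery, the homogeneity
    checks on a representative variable, and the shoulder-hip
    phase-mean velocity regressions per condition and phase.
    """
    battery = _stats.anova_battery(table, screen_outliers=screen_outliers)

    regressions = {}
    for condition, sub in table.groupby("condition"):
        for phase in ("Vflex", "Vext"):
            wide = sub[sub["variable"] == phase].pivot_table(
                index="participant_id", columns="joint", values="value"
            )
            if {"shoulder", "hip"} - set(wide.columns):
                continue
            x, y = wide["shoulder"].to_numpy(), wide["hip"].to_numpy()
            if regression_direction == "hip_to_shoulder":
                x, y = y, x
            try:
                regressions[(condition, phase)] = _stats.velocity_regression(
                    x, y, degree=degree
                )
            except ValueError as exc:
                logger.warning("regression %s/%s skipped: %s", condition, phase, exc)

    homogeneity = {}
    for var in ("Vflex", "Vext"):
        sub = table[(table["variable"] == var) & (table["joint"] == "hip")]
        if not sub.empty:
            homogeneity[var] = _stats.homogeneity_checks(sub)

    return {"anova": battery, "regressions": regressions, "homogeneity": homogeneity}
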