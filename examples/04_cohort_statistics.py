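"""Cohort-level statistics: mixed ANOVA, effect sizes, ICC, regressions.

Simulates a 21-participant cohort (non-fatigue and fatigue trials, low
vs high lower-limb muscle ratio groups) with a +5.8 deg fatigue effect
on knee flexion ROM, runs the full pipeline, and prints the condition
effect for that variable plus the shoulder-hip velocity regression.
"""

import numpy as np

from squatkin import CohortConfig, TrialParams, generate_cohort
from squatkin.pipeline import analyze_cohort, run_stats

rng = np.random.default_rng(1)
cfg = CohortConfig(
    n_participants=21,
    llmr_values=tuple(np.round(rng.uniform(32.0, 36.6, 21), 2)),
    condition_effects={"rom_knee_deg": 5.8},
    seed=77,
)
members = generate_cohort(cfg, TrialParams(n_reps=5, noise_sd_m=0.001))
llmr = {m.participant_id: m.llmr_pct for m in members}
# cohort screening uses a stricter dip depth than the single-trace default:
# differentiated marker jitter leaves shallow spurious dips on every trial
table, sticking, prevalence = analyze_cohort(
    [m.trajectory for m in members], llmr, sticking_depth=0.15
)
print(f"analysed {table['participant_id'].nunique()} participants x 2 conditions; "
      f"sticking prevalence {prevalence:.1%} (none injected)")

out = run_stats(table, screen_outliers=False)
row = out["anova"]
row = row[(row["variable"] == "ROM_Flex_knee") & (row["effect"] == "condition")].iloc[0]
print(f"knee ROM_Flex condition effect: F(1,19) = {row['F']:.2f}, p = {row['p']:.3g}, "
      f"eta_p2 = {row['eta_p2']:.2f} "
      f"[{row['eta_p2_ci90_lo']:.2f}, {row['eta_p2_ci90_hi']:.2f}] ({row['size_label']})")
print(f"knee ROM_Flex test-retest ICC = {row['icc']:.2f} ({row['icc_category']})")

reg = out["regressions"][("nonfatigue", "Vflex")]
print(f"flexion shoulder->hip velocities: r = {reg.pearson_r:.3f}, "
      f"linear R2 = {reg.r2_linear:.3f}, quadratic R2 = {reg.r2_poly:.3f}")
print("-> the injected fatigue effect surfaces as a large condition main "
      "effect; shoulder and hip phase-mean velocities correlate because "
      "hip and knee excursions co-vary across participants.")
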