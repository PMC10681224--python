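"""Segment repetitions into the four velocity regions and extract metrics.

Each repetition splits into flexion (descent) and extension (ascent) at
the deepest frame, and each phase splits again at its peak hip vertical
velocity, giving V1down / V2down / V1up / V2up. Printed below: the mean
and peak speeds, the ROMs and the region durations of the third
repetition — the rep that characterises the non-fatigued pattern.
"""

from squatkin import (
    TrialParams,
    compute_kinematics,
    detect_repetitions,
    find_regions,
    generate_trial,
    region_metrics,
    select_analysis_reps,
)

params = TrialParams(tempo_bpm=45.0, n_reps=8, noise_sd_m=0.002, seed=3)
kin = compute_kinematics(generate_trial(params), cutoff_hz=6.0)
cycles = detect_repetitions(kin)
print(f"detected {len(cycles)} repetitions "
      f"(~{(cycles[0].end_idx - cycles[0].start_idx) / 100:.2f} s each)")

nonfatigue_rep, _ = select_analysis_reps(cycles)
bounds = find_regions(nonfatigue_rep, kin, reference_joint="hip")
m = region_metrics(nonfatigue_rep, bounds, kin)

print(f"hip mean speeds  Vflex {m['Vflex_hip']:.2f}  Vext {m['Vext_hip']:.2f} m/s")
print(f"hip peak speeds  Vdownpeak {m['Vdownpeak_hip']:.2f}  "
      f"Vuppeak {m['Vuppeak_hip']:.2f} m/s")
print(f"ROM_Flex hip {m['ROM_Flex_hip']:.1f} deg, knee {m['ROM_Flex_knee']:.1f} deg")
print(f"durations  t_V1down {m['t_V1down']:.2f}  t_V2down {m['t_V2down']:.2f}  "
      f"t_V1up {m['t_V1up']:.2f}  t_V2up {m['t_V2up']:.2f}  "
      f"total {m['t_total']:.2f} s")
print("-> region durations always add up to the repetition duration exactly.")
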