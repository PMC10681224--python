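# Methods

## Scope

`squatkin` analyses sagittal-plane (2-D) marker trajectories of the
body-weight squat: five retroreflective markers — acromion (shoulder),
trochanter major (hip), epicondylus lateralis (knee), malleolus
lateralis (ankle), caput metatarsalis (toe) — filmed from the right
side at a fixed rate (100 Hz by default). From these it derives joint
kinematics, segments repetitions into four velocity-defined regions,
extracts the per-region metric set, detects sticking regions on the
ascent, and runs a cohort-level statistical battery. A forward-kinematic
generator provides synthetic cohorts so every stage is testable without
motion-capture data.

## Kinematic model and conventions

Coordinates are x anterior, y vertical up, meters. Joint angles are
interior three-point angles: hip at the trochanter between acromion and
epicondyle; knee at the epicondyle between trochanter and malleolus;
ankle at the malleolus between epicondyle and toe. Neutral standing
therefore reads hip 180°, knee 180°, ankle 90°, and the flexion range of
motion is `ROM = 180° − angle at the deepest frame`. These vertex
choices are the unique assignment consistent with those standing values.

Angular velocities are reported as magnitudes in rad·s⁻¹ (the whole
metric set follows an absolute-value convention); vertical linear
velocities (m·s⁻¹) and accelerations (m·s⁻²) come from the y
coordinates of the shoulder, hip and knee markers. Differentiation uses
central differences with one-sided stencils at the ends, which is exact
for linear trends. Positions are smoothed with a zero-lag low-pass
filter (2nd-order Butterworth run forward and backward, i.e. effective
4th order) at a default cutoff of 6 Hz — the conventional choice for
human movement captured at 100 Hz; pass `cutoff_hz=None` to disable it
(noise-free synthetic data, unit tests).

## Repetition segmentation and regions

Repetitions are found on the hip vertical velocity: frames outside a
hysteresis band of ±0.05 m·s⁻¹ form descent and ascent runs; a descent
run paired with the next ascent run is a candidate repetition, kept if
the hip drops at least 0.10 m. Both thresholds sit far below typical
peak velocities and squat depths and are configurable. Candidate
boundaries are then extended outward along the hip height to the
nearest turnaround or standing plateau, so back-to-back repetitions at
a no-rest tempo span their full metronome period and adjacent cycles
share at most the single turnaround frame.

Two repetitions per trial are analysed: the third after initiation
(movement pattern settled, pre-fatigue) and the next-to-last
accomplished one (fatigued). At least five repetitions are therefore
required for the two picks to be distinct.

Each repetition splits at the deepest (minimum hip height) frame into
flexion and extension, and each phase splits again at its peak vertical
speed frame of a reference joint (hip by default; configurable), giving
V1down / V2down / V1up / V2up. Ties go to the earliest frame. Durations
use the shared-boundary half-open convention, so the four region
durations sum to the repetition duration exactly. Mean region speeds
and angular velocities average magnitudes over the region frames
(endpoints inclusive); region accelerations are the endpoint slope
|Δv/Δt|, identical to the mean instantaneous acceleration up to the
end stencils. `ROM_Ext` defaults to mirroring `ROM_Flex` from the
bottom-frame angle (the two conventions coincide for a motion that
returns to standing); `rom_ext_mode="end"` instead uses the excursion
recovered by the extension end. The ankle angle is computed but not
propagated into the metric table; it appears only in sticking reports.

Note that even for a time-symmetric joint-angle profile the
vertical-velocity peaks do not fall at the phase midpoints: hip height
is a nonlinear function of the joint angles, so the speed peak shifts
toward the deeper part of each phase. The symmetry that does hold, and
that the tests check, is mirror symmetry of the two peaks about the
bottom frame.

## Sticking-region detection

A sticking region is a transient deceleration and re-acceleration
during the ascent, described by four landmarks: V0 (ascent start),
Vmax1 (first velocity peak), Vmin (local minimum) and Vmax2 (second
peak). The detector scans interior peak/trough pairs in temporal order
and declares a sticking region for the first pair satisfying all of:

* fractional depth `(Vmax1 − Vmin)/Vmax1 ≥ min_depth_frac` (default 0.05);
* dip duration `≥ min_dip_s` (default 0.03 s);
* `Vmin > 0` and `Vmin ≥ min_floor_frac ×` trace maximum (default 0.10);
* `Vmax2 ≥ min_vmax2_frac × Vmax1` (default 0.50).

No numeric criteria for "sticking" exist in the literature for the
body-weight squat; these are detection choices. The depth and duration
floors are set so a 0.10 s dip of worked-example scale is always found
while single-frame wiggles are not; the velocity floor and the
re-acceleration requirement distinguish a genuine mid-ascent dip from
the low-velocity fluctuation around the terminal deceleration into
standing, where fractional depths are meaninglessly large. Detection is
invariant to uniform velocity scaling, and a strictly unimodal ascent
never fires. On smooth traces the recovered pre-sticking and sticking
durations match injected values within one frame.

Cohort screening reports one verdict per participant and condition plus
the prevalence (fraction of participants detected in at least one
condition). The same detector can be pointed at the descent speed trace
to flag the analogous flexion-phase slowdown.

## Synthetic motion generator

The generator is a planar four-segment chain (foot, shank, thigh,
trunk; defaults 0.15 / 0.43 / 0.45 / 0.52 m — plausible adult
anthropometry, configurable) with the malleolus fixed at the origin and
the foot flat. Per repetition the hip and knee interior angles follow a
raised-cosine profile from standing down to `180° − ROM` and back (one
cosine cycle per repetition): smooth, bounded derivatives, and a single
velocity peak per phase. The shank lean solves a closed-form balance
closure keeping the hip vertically above the ankle; the ankle angle
follows from it and the acromion rides rigidly on the trunk. Defaults
follow the study conditions: 45 bpm 1:0:1:0 tempo (rep period
2·60/45 ≈ 2.667 s), 100 Hz sampling, hip/knee excursions near
90–105°, Gaussian marker jitter of 0.002 m (sub-pixel-scale tracking
error at ~2 m camera distance), and a 0.5 s standing plateau before and
after the repetitions.

Within a trial, fatigue is a per-repetition multiplicative drift on the
excursions applied linearly from first to last repetition; at fixed
tempo this also scales velocities. Across a cohort, each participant
receives correlated Gaussian hip/knee excursion offsets
(SD 8°, correlation 0.8 — people who squat deeper flex both joints
more, which is what couples shoulder and hip velocities across
participants), each trial an additional correlated offset (SD 2°), and
the fatigue trial the configured condition effects (additive or
multiplicative offsets on any trial parameter). Group effects key off
the low/high muscle-ratio labels from the median split. Everything is
deterministic given the seed.

Sticking injection reshapes one repetition's ascent: the prescribed
piecewise raised-cosine velocity profile (rise to Vmax1 at `t_pre_s`,
dip by `dip_depth_frac` over `t_dip_s`, recover over `t_recover_s`,
decay to zero) is scaled so its integral equals the original net
vertical hip displacement, integrated into a new hip-height trace, and
all markers are re-sampled by time-warping the original ascent. Because
the ascent pose is a monotone function of hip height, this preserves
chain geometry, position continuity and net displacement (to < 10⁻⁶ m)
while giving the hip the requested velocity profile.

`make_ascent_fixture` builds the bare 1-D ascent velocity trace with the
same piecewise shape and landmarks exactly on the requested sample
times (off-grid times are snapped to the nearest frame and flagged).

### What the generator does and does not emulate

It reproduces the study's tempo, sampling, marker set, angle
conventions, depth scale, two-condition paired structure, group
structure, fatigue drift, and injectable sticking dips. It does not
reproduce: participants moving faster than the metronome (the study's
measured repetitions lasted ~1.57 s inside the 2.667 s beat, giving
peak hip velocities near 1 m·s⁻¹; the generator fills the full period
and peaks near 0.45 m·s⁻¹ at default depth — tempo fidelity was
preferred because repetition duration is the pinned quantity),
trunk-lean strategies, arm motion, or temporally correlated tracking
error. The white per-frame jitter is harsher on differentiated signals
than real, smooth tracking error: at the default 0.002 m jitter,
velocity traces retain shallow spurious dips after 6 Hz filtering, so
cohort-level sticking screening on jittered synthetic data should use
a stricter depth threshold (0.15 works well) than the single-trace
default. Passing tests on this generator therefore validate the
pipeline's arithmetic, segmentation logic and statistical machinery,
not the detector's operating characteristics on real video-tracked
data.

## Statistics

The battery mirrors a 2 (condition: non-fatigue, fatigue) × 2 (group:
low/high lower-limb muscle ratio) mixed design:

* **Grouping** — median split of LLMR percentages; the sorted lower
  half (⌊n/2⌋) is "low", so an odd cohort splits ⌊n/2⌋/⌈n/2⌉ with the
  median participant in the high group. Ties at the cut resolve by
  participant order with a warning.
* **Outlier screening** — Tukey boxplot rule (1.5·IQR) per
  group × condition cell; a flagged value removes that participant
  pairwise for that variable, keeping the within-subject design
  complete.
* **Mixed ANOVA** — classical sum-of-squares decomposition, computed
  in-package. Because every subject contributes both conditions, group
  and condition are orthogonal even with unequal group sizes, so the
  cell-mean formulas are exact (Type I/II/III coincide); the
  implementation is verified to machine precision against an
  independent least-squares projection oracle and against
  `pingouin.mixed_anova`. The Greenhouse–Geisser ε is computed
  generally but equals 1 for a two-level within factor (a single
  difference score cannot violate sphericity); a note is logged when
  the correction is a no-op. Zero residual variance (degenerate
  noise-free input) yields F = 0 with a warning rather than an error.
* **Effect sizes** — partial eta squared `ηp² = F·df1/(F·df1 + df2)`,
  labelled small/medium/large at 0.01/0.06/0.14; its confidence
  interval inverts the noncentral F distribution for the noncentrality
  parameter at each tail and maps through `λ/(λ + df1 + df2 + 1)`,
  lower bound clipped at 0.
* **Reliability** — test–retest ICC across conditions, form ICC(3,1):
  two-way mixed effects, single measurement, consistency (the form is
  stated in every result since category thresholds 0.5/0.75/0.9 are
  form-agnostic but the coefficient is not).
* **Regressions** — ordinary least squares of hip on shoulder
  phase-mean velocity (direction flippable), degree 1 and degree 2; the
  quadratic was chosen as the polynomial degree because the
  relationship shows a single bend. The fits are nested, so
  R²poly ≥ R²linear always, and Pearson's r satisfies r² = R²linear.
* **Assumption checks** — Levene (center = mean) per condition and
  Box's M across condition covariance matrices; reported, never used to
  gate the ANOVA. No multiple-testing correction is applied (α = 0.05
  per test), matching the design this battery mirrors.

## Numerical choices and degenerate inputs

Angle computation clips cosines into [−1, 1]; coincident markers raise
an error naming the frame. Trajectory readers convert units per the
file header, accept case-insensitive marker aliases, interpolate
isolated gaps ≤ 0.1 s with a logged warning and reject a marker missing
more than 5% of frames. Regions shorter than 2 frames flag the metric
set as degenerate. Repetition detection on an empty or flat record
returns an empty list with a warning; trials failing the five-repetition
requirement are excluded from cohort analysis with a log entry while
the run continues.

## Problem sizes used in the validation suite

Property tests run on 5–8-repetition trials (≈1 400–2 200 frames at
100 Hz), cohorts of 21 participants × 2 conditions, 100 random small
ANOVA designs (2–6 subjects per group) for the oracle equivalence,
1 000 simulated null cohorts for the type-I error check, and 500
replicates for the Levene null-uniformity check. These sizes give
stable Monte-Carlo estimates (±1.5 percentage points on the rejection
rate) while keeping the full suite under half a minute.

## Known limitations

2-D projection error, camera perspective and marker-placement error are
upstream of this package and not modelled. The generator's balance
closure (hip over ankle) is one of several plausible squat strategies;
real lifters shift the hip rearward. Sticking detection thresholds are
conventions, not estimated operating points — no labelled real data
exists here to calibrate them. The ICC form used in the study is not
recoverable from its text; ICC(3,1) is a defensible default and is
always labelled. The unweighted-marginal convention is used for group
mean differences; weighted marginals differ slightly in unbalanced
designs.
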