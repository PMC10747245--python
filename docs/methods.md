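# Methods

## Problem setting

A single video camera placed laterally records a walking subject; a pose
estimator (e.g. OpenPose) returns per-frame 2D keypoints with
confidences. The question the package addresses is methodological: how
closely do sagittal hip, knee and ankle angle waveforms and their
discrete per-cycle parameters, derived from those keypoints, agree with
the same quantities derived from reference joint-centre trajectories
(the kind a marker-based optical system exports) — and how does the
agreement differ between the near (camera-side) and far limb, the far
limb being intermittently hidden behind the near one during limb
crossing.

Because raw recordings of this kind are rarely shareable, the package
carries a synthetic planar-gait generator whose output has exact ground
truth. All tests and the acceptance script run against it.

## Coordinate and angle conventions

Internal frame: x along the direction of progression, y up, origin at
the walkway start; pixels = metres × `pixel_scale`. OpenPose JSON uses
image coordinates (y down), so the reader/writer flip y against the
image height.

Axes are defined proximal→distal: trunk Neck→MidHip, thigh Hip→Knee,
shank Knee→Ankle, foot Heel→BigToe. Angles (degrees, flexion and
dorsiflexion positive):

- hip = signed angle from trunk axis to thigh axis;
- knee = signed angle from shank axis to thigh axis;
- ankle = signed angle from shank axis to foot axis − 90°.

The 90° ankle offset is required because the foot axis is perpendicular
to the shank in neutral standing while dorsiflexion is conventionally
reported near 10–15°. Signs are resolved via an orientation factor
inferred from the mean trunk-up vector and the net pelvis displacement,
which makes all angles invariant under rotation, translation, scaling
and mirroring of the scene (verified by property tests). The hip angle
is measured against the trunk axis, not the vertical; no static-trial
offset calibration is applied to the pose stream (an optional per-study
offset could be subtracted upstream, but none is applied by default).

Peak-extension and peak-plantarflexion parameters are reported as
positive magnitudes of the most extended (minimum signed) value, the
clinical convention; signed waveforms are kept internally.

## Synthetic gait model

**Angle templates.** Hip: a single-harmonic cosine peaking at 92% of the
cycle (terminal swing) with max = `hip_peak_flex` and min =
−`hip_peak_ext`. Knee and ankle: sums of periodic windowed
raised-cosine lobes, `cos⁴(π d/w)` on a compact support of width `w`
(C³ at the edges): knee lobes at 18% (stance, width 0.36) and 75%
(swing, width 0.30) of the cycle; ankle a positive dorsiflexion lobe at
35% (width 0.44) and a negative plantarflexion lobe at 68% (width
0.22). The lobe supports are disjoint, so each phase-restricted
extremum equals its profile amplitude *exactly* — a truncated Fourier
fit was considered first but cannot pin local extrema without iteration,
and exact extrema are what the round-trip contracts need. The left limb
is the right limb phase-shifted by exactly half a cycle.
`parameter_targets()` evaluates the implied 12 parameter truths on a
dense grid (10⁵ points) using the same stance/swing split the pipeline
recovers.

**Forward kinematics.** The pelvis translates at constant speed
(default 1.3 m/s) with the trunk vertical; absolute segment angles are
thigh = hip, shank = thigh − knee, foot = shank + dorsiflexion, and the
12 feature points follow from the segment lengths (defaults: trunk
0.50 m, thigh 0.41 m, shank 0.42 m, foot 0.25 m — anthropometric
plumbing, not claims). The heel sits 20% of foot length behind and 16%
below the ankle centre along the foot axis, so re-deriving the foot
axis recovers the input dorsiflexion identically. Re-deriving all
angles from the landmarks reproduces the inputs to ~1e-13°.

**Ground reaction force.** Stance occupies `stance_fraction` (default
0.6) of each cycle. Over normalized stance time the force is two
raised-cosine bumps (centres 0.25/0.75 of stance, width 0.7 of stance,
peaks 1.05 and 1.00 × body weight, mid-stance valley ≈ 0.39 BW) and is
identically 0 N in swing. The shape is intentionally discontinuous at
contact (~0.2 BW at the first loaded sample), standing in for the steep
loading transient of heel strike: it guarantees the trace crosses the
20 N threshold at the declared initial-contact sample, so detected and
declared events can be compared exactly. Each trial opens with a
20%-of-cycle unloaded lead-in on the right side (the left starts
mid-stance; that partial contact is deliberately not a declared event).

**Measurement model.** The pose stream adds i.i.d. Gaussian noise (SD
in pixels, default 0) to every coordinate, and during frames where the
left and right knees or ankles are within `crossing_threshold_px`
(default 20 px ≈ 5 cm at the default 400 px/m scale) the left-limb
keypoints (knee, ankle, big toe, heel) are dropped — confidence set to
0, coordinates kept, matching pose-estimator output semantics — with
probability `dropout_prob_crossing`. The right limb is never dropped
(camera-side convention). With noise and dropout at 0 the pose stream
equals the reference stream bit for bit.

**Cohort simulation.** Per-participant profiles are drawn around the
base profile: amplitude SDs of 4.2–8.6° (typical between-subject spread
of healthy adult sagittal peaks), cycle duration 1.1 ± 0.07 s, stance
fraction 0.60 ± 0.015 (clipped to 0.55–0.65), body weight 585 ± 100 N;
each trial adds 1° amplitude jitter (within-session stride
variability). These defaults produce ICC(1,3) values in the 0.9–0.99
range on clean data, as seen in healthy-cohort reliability studies.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real recordings: out-of-sagittal-plane motion
and projection error, soft-tissue artifact, pose-estimator bias (noise
here is zero-mean and i.i.d., real keypoint error is structured),
lens distortion, pelvis vertical oscillation, double support with
asymmetric timing, and multi-person scenes.

## Signal processing

"Fourth-order zero-lag Butterworth, 6 Hz" is implemented as a 2nd-order
low-pass design applied forward and backward (`scipy.signal.filtfilt`),
the dominant biomechanics convention: effective 4th order, −6.02 dB at
the cutoff, exactly zero phase, DC gain 1. The alternative reading (a
4th-order design applied twice, effective 8th order) is available via
`convention="cascade"`. Filtering is applied to landmark coordinates
before any angle computation, never to angles. Frames that remain
invalid after gap filling are bridged by linear interpolation before
filtering (so they cannot contaminate neighbours) but stay flagged
invalid downstream. Series shorter than 3× the filter length plus one
sample are rejected with the minimum named.

Interior confidence-zero gaps of at most `max_gap_frames` (default 10
frames ≈ 83 ms, comfortably above the few-frame crossing occlusions)
are linearly interpolated and flagged imputed; longer interior gaps
mark the side unusable; leading/trailing gaps are never extrapolated.

## Event detection and normalization

Contact = vertical GRF strictly above 20 N. Debouncing: unloaded gaps
shorter than 50 ms within a contact are merged; contacts shorter than
100 ms are discarded as artifacts; a contact already loaded at the
first sample of the trace is not an initial contact. All three windows
are configurable; the 20 N threshold is the field's standard. Toe-off
is the first unloaded sample after a contact. Force-sample indices map
to video frames by floor division of the rate ratio (1200/120 = 10 by
default; the force rate must be an integer multiple of the video rate).

Cycles are normalized to 101 points (0–100% inclusive, the universal
grid) by linear interpolation in frame time; cycles shorter than 20
frames, with no unique toe-off, or with more than 20% flagged frames in
any joint are excluded with a logged reason. Knee parameters are
restricted to the stance/swing slices from the force-derived toe-off;
ankle and hip parameters use the whole cycle.

## Statistics

- **MAE**: mean |difference| over the 101 points, computed per cycle,
  averaged over a participant's trials, then mean and parametric
  t-based 95% CI across participants. An alternative granularity
  (mean absolute difference over the 12 discrete parameters per joint)
  is available via `mae_granularity="parameters"`.
- **CMC**: the between-protocol formulation with F = 2 protocols over
  one cycle, T = 101; ratios above 1 yield an undefined value that is
  excluded from means with a reported count, never clamped or imputed.
- **ICC(1,3)**: one-way random effects, average of k = 3 trials,
  (BMS − WMS)/BMS, with the F-bound confidence interval
  (1 − 1/F_L, 1 − 1/F_U). Note ICC(1,k) has a small negative bias under
  the null hypothesis of no subject effect, E[ICC] = 1 − (n−1)/(n−3)
  (≈ −0.042 at n = 50); the Monte-Carlo null check accounts for this.
  Degenerate inputs are reported as computed (1 for zero within-subject
  variance, −∞ for zero between-subject variance), flagged, never
  floored.
- **Pearson r / paired t**: standard definitions via scipy, with the
  conventions r = NaN for zero-variance input and (t, p) = (0, 1) for
  identical paired samples. No multiple-testing correction is applied.
- Interpretation bands as listed in the README; absolute-error bands
  are closed on the right, CMC bands half-open except the top band.

Every estimator is tested against an independent double-loop
transcription of its defining formula (≤1e-10), and ICC additionally
against pingouin's ICC(1,k).

## Problem sizes

Defaults were chosen to make the full suite and the acceptance script
fast while keeping each check statistically meaningful: 5-cycle trials
for round trips, 5 × 3 noiseless cohorts for the perfect-agreement
limit, 50 random profiles for event detection, 10,000 replicates for
the ICC null mean (Monte-Carlo SE ≈ 0.003 against the 0.05 band),
2,000 replicates for CI coverage, and 10 seeds × 21 participants × 3
trials for the occlusion-asymmetry direction.

## Known limitations

- All angles are planar projections; 3D effects are out of scope by
  design.
- The OpenPose/reference streams are assumed pre-synchronized at frame
  0 and sampled at the same nominal rate; only a constant frame offset
  could be corrected upstream, and none is applied.
- The hip definition uses the trunk axis; studies measuring hip
  extension against the vertical will differ systematically.
- The GRF onset step is a modelling convenience; real loading rates are
  finite, so on real force data the detected IC lags the true contact
  by the time to reach 20 N.
- With `mae_granularity="waveform"` the MAE is a whole-curve error;
  discrete-parameter error can behave differently (hence the flag).
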