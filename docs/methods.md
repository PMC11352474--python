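# Methods

This note documents the models, parameter choices, and numerical
conventions behind `reachgap`. It covers what each stage assumes, what the
synthetic generators do and do not emulate, and where the design was
genuinely open.

## Task protocol

A session is 10 unrotated practice trials followed by 108 task trials.
Rotated trials carry an integer cursor rotation drawn uniformly from
{−25…−1} ∪ {1…24} degrees about the vertical axis (positive = clockwise
viewed from above). The schedule is built as repeated blocks
`[rotated, k washouts]` with k uniform on {1, 2}, truncated to exactly 108
task trials; this satisfies the constraint that rotated trials are
separated by one or two unrotated trials while leaving block construction —
which the protocol description does not pin down — as simple as possible.
Practice trials are unrotated (the protocol is silent; an unrotated
warm-up is the conservative reading).

Geometry uses a right-handed y-up frame (x right, z straight ahead), origin
at the chin. Targets sit on a frontal arc at 0.9 × arm length; the default
arc half-width is 45° (the true arc extent is unspecified and
configurable). The cursor-occlusion boundary is *closed*: horizontal
extension exactly 50% of |OT| counts as hidden — "approximately 50%" needs
a fixed convention to be testable. The speed-feedback window defaults to
0.8–1.2 s movement duration (no published values; configurable).

## Gap angle

Per trial, P90 is the first point whose *horizontal* distance from the
origin reaches 0.9 |OT|, linearly interpolated (on the distance) between
the bracketing 72 Hz samples. Horizontal extension — not 3D radial distance
or arc length — defines the criterion, matching the horizontal-plane
construction of the angle itself. Trials that never attain 90% extension
are scored at their point of maximal extension, flagged `attained=False`,
and kept in the mean: retaining early-stoppers is the point of using the
90% position. The angle is computed on horizontally projected vectors (the
score measures horizontal aiming accuracy, not depth accuracy), with the
arccos argument clamped to [−1, 1]; angles are reported in degrees. The
participant score is the arithmetic mean over the session's task trials.

## Behavioural generator

No motor-control model is published for this task; the package uses an
AR(1)-heading aiming model chosen because a single noise parameter spans
straight to meandering reaches:

* the hand's horizontal heading is updated each 72 Hz step toward the
  direction from the *perceived* hand position to the target with gain
  `reaim_gain`;
* the perceived position is the rotated cursor while visible (extension
  < 50%), the true hand afterwards — so rotated trials produce a curved
  pursuit path and a residual endpoint error that shrinks as the gain
  grows;
* heading noise is AR(1) with stationary SD `heading_noise_sd` (degrees per
  step) and persistence `heading_noise_persistence`;
* speed follows a minimum-jerk bell profile over a nominal 1 s movement
  (held at its τ = 0.9 value until termination, capped at six nominal
  durations); the reach ends at 100% extension, or — with probability
  `early_stop_prob` — at a point drawn uniformly in [90%, 100%);
* a small vertical bow (4% of reach) makes trajectories genuinely 3D; it is
  invisible to the horizontally projected score.

Cohorts draw a per-subject lognormal multiplier on `heading_noise_sd`
(log-SD `noise_spread_log_sd`) to create between-subject heterogeneity.
Defaults were calibrated once, by simulation, so cohort statistics
reproduce the group statistics the analysis is designed around:

| profile | noise SD (°/step) | persistence | gain | early stop | log-spread |
|---|---|---|---|---|---|
| young_default | 7.3 | 0.85 | 0.40 | 0.02 | 0.34 |
| older_default | 9.1 | 0.90 | 0.12 | 0.15 | 0.75 |

yielding expected cohort mean ± SD of the mean gap angle ≈ 2.5 ± 0.8°
(n = 41 young) and ≈ 18.5 ± 12.6° (n = 35 older). With n = 35 and a
coefficient of variation near 0.7, a single simulated older cohort's mean
has an SE of ≈ 2°; calibration statements refer to the generator's
expectation, estimated over several seeded cohorts. The default older
cohort is unimodal; `OLDER_BIMODAL` provides a two-component mixture
(a low-error and a high-error subgroup) but is not the default. Covariates:
young ages uniform 25–60, older 70–85; sex Bernoulli(0.5) (0 = male);
activity level multinomial (6, 24, 7, 3)/40. Post-trial rotation judgements
are simulated with a Gaussian psychometric curve on |rotation| plus a 10%
false-alarm rate — plumbing for the exclusion rules, not a fitted model.

The generator emulates endpoint accuracy, meander, early stopping, and the
rotation/washout structure. It does **not** emulate reaction times, depth
(radial) errors, learning or fatigue across trials, or trial-to-trial
adaptation after-effects; passing tests therefore say nothing about those
aspects of real data.

## Exclusion and behavioural statistics

A participant is excluded when their correct-answer count deviates from the
cohort mean by more than three population SDs (two-sided, single pass, SD
over all pre-exclusion participants including any all-incorrect ones), or
when all answers were wrong. The battery wraps scipy: Shapiro–Wilk,
Spearman (two-sided), Mann–Whitney U (exact for tie-free samples with both
n ≤ 8, else tie-corrected normal approximation with continuity correction),
and Kruskal–Wallis (chi-square, tie-corrected). No multiplicity correction
is applied to the battery.

## BOLD generator

Per subject and run (default 2 runs × 450 volumes, TR 0.8 s, 140 ROIs),
unit-variance "neural" signals are white in time: each planted ROI pair is
drawn with population correlation `tanh(baseline_z + slope · s)` where `s`
is the subject's standardized mean gap angle; all other pairs share a weak
global factor giving a score-independent background correlation (default
0.1). On top are added: per-ROI sinusoidal drift at 0.002–0.006 Hz (below
the passband), a motion-coupled artifact (an exact linear image of the six
simulated realignment parameters), and white-matter/CSF leakage (linear in
the two latent factors underlying each tissue's source signals). Simulated
head motion is a sum of slow sinusoids (per-volume increments ≪ 0.5 mm)
plus optional injected step spikes. Defaults: 3 planted edges on ROI pairs
(1,2), (3,4), (5,6) with `baseline_z = 0.25` and `slope = −0.5` z per SD of
score — the slope chosen by power analysis so that, at n = 16 subjects and
df = 12, planted |T| (≈ 7–13) reliably exceeds the maximum null |T| over
all 9730 edges (≈ 5–8; t with 12 df is heavy-tailed). The white temporal
spectrum is a simplification: real BOLD is autocorrelated, so effective
degrees of freedom here are optimistic relative to real data.

`sample_subject_records` draws behavioural scores directly from a lognormal
matched to the calibrated cohort mean/SD; it is used where only the
participant-level score matters (repeated recovery simulations, the
pipeline's `behavioral: sample` mode), while `simulate_cohort` runs the
full schedule → trajectory → scoring chain.

## Denoising and connectivity

Runs are processed independently; the run-effect regressor of a
concatenated design is exactly the per-run constant. Per run:

1. Framewise displacement = Σ|Δtranslation| + 50 mm × Σ|Δrotation|
   (FD[0] = 0; 50 mm head radius is the convention of the tool family the
   outlier threshold comes from). Outliers: FD > 0.5 mm or |z| > 3 of the
   volume-to-volume change of the mean-across-ROIs signal (the global
   criterion's exact metric is not published; this declares one).
2. Confound matrix: constant, linear trend, 6 motion parameters + 6 first
   derivatives, one-hot outlier indicators (outliers are regressed, not
   deleted, preserving volume alignment), mean WM and CSF signals, and 5+5
   CompCor components (top principal components of the tissue source
   signals after projecting out their average and the base regressors).
   The tissue averages are included because the components are constructed
   orthogonal to them; omitting the averages leaves one direction of the
   noise span in the data and measurably attenuates planted
   edge–behaviour slopes.
3. OLS confound regression (pseudo-inverse with a warning if rank
   deficient — expected for short runs where slow motion drifts and their
   derivatives become collinear), **then** bandpass 0.008–0.09 Hz by
   frequency-domain masking (bins outside the band, including DC, zeroed).
   The order matters and is guarded by a frequency-probe test.
4. Scan weights: unit step convolved with the canonical double-gamma HRF
   (peak 6 s, undershoot 16 s, ratio 1:6, unit sum), rectified. The
   steady-state plateau is 1, so early pre-steady-state volumes are
   down-weighted and the weight briefly overshoots (~1.17) before settling
   — normalizing to the plateau rather than the maximum keeps the bulk of
   the run at full weight.
5. Connectivity: weighted Pearson correlation over the pooled volumes of
   all runs (per-volume weights from step 4; uniform mode available for
   oracle tests), then z = atanh(r) clipped away from ±1; diagonal NaN;
   zero-variance ROIs yield NaN entries with a warning.

## Group GLM and FDR

Edge-wise OLS of Fisher z on [age, sex, activity_level, mean_gap_angle]
with **no intercept**: four regressors with 16 subjects give the residual
df of 12 that the reported T(12) statistics imply. An intercept mode
exists but changes df and is not the default. The contrast tests the mean
gap angle; p-values are two-sided from the t distribution. Covariates are
not centred by default (irrelevant to the contrast t without an intercept;
an option exists because it changes betas).

FDR uses Benjamini–Hochberg. The default family is per-seed (139 edges per
seed ROI, the tool-family convention): each unordered edge belongs to two
seed families and receives the smaller of its two adjusted values, since a
seed-level report would surface it under either seed. A global family over
all C(140, 2) = 9730 edges is available. Significant edges are sorted by
|t| descending, ties broken by seed then target label for deterministic
reports.

## Determinism and problem sizes

Every stochastic operation takes a seed or Generator; the pipeline driver
derives stage seeds from one master seed, and re-runs are byte-identical.
The test suite and acceptance script use the study-scale dimensions where
they are the point (108 trials, 450 volumes × TR 0.8 s, 140 ROIs, n = 16
group analyses, 41/35-subject cohorts) and smaller grids (6–20 ROIs,
60–300 volumes) for oracle and property checks where dimensionality is
irrelevant.

## Known limitations

* The aiming model has no feedforward adaptation, so washout dynamics are
  trivial; the rotation/washout structure affects only within-trial
  perception.
* BOLD is temporally white before filtering; no physiological (cardiac or
  respiratory) noise, no voxel level, no spatial structure beyond the
  planted pairs and one global factor.
* Effective-degrees-of-freedom estimation after denoising is out of scope;
  inference at the edge level uses the across-subject df only.
* The exclusion rule's SD is computed over all pre-exclusion participants
  (including all-incorrect ones) in a single pass; iterative re-computation
  would change borderline cases.
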