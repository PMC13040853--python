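# Methods

This note documents the models, rules and numerical choices behind
`exengage`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Skeleton model and angle conventions

Streams are 19 named joints (head, neck, shoulder/mid/base spine, and
shoulder–elbow–wrist–hand, hip–knee–foot per side) sampled at a nominal
30 frames/s, coordinates in meters with x horizontal, y vertical, z
depth/forward. Tracking hardware vocabularies differ, so readers map input
joint names onto this canonical list and reject unknown names.

Angles are defined from marker vectors, zero at anatomical neutral:

* **hip flexion** = 180° − angle(trunk vector spine_base→spine_shoulder,
  thigh vector hip→knee); standing straight reads 0°, thigh horizontal 90°;
* **knee flexion** = 180° − interior angle at the knee (hip–knee–foot);
* **hip ab/adduction** = frontal-plane (x–y) angle between the thigh and
  the downward trunk axis, signed positive away from the midline
  (abduction) and negative toward it; adduction is its negation;
* **lateral trunk lean** = frontal-plane tilt of the spine vector from
  vertical; a pure sagittal (forward) bend projects to 0.

These definitions are the package's own operationalization: published
movement-acceptability criteria state thresholds (e.g. "at least 20
degrees of hip flexion") without fixing vector conventions.

## Repetition detection

Each exercise is a set of per-frame scalar metrics with thresholds
(angles in degrees, displacements in meters). The normalized driver
s(t) = min over rules of metric/threshold reaches 1 exactly when all rules
hold simultaneously. Events are segmented with hysteresis: open at
s ≥ 1, close at s < 0.5 (50 % of threshold), minimum 0.25 s between the
close of one event and the opening of the next; drivers are smoothed with
a 5-frame boxcar before detection. This prevents sensor chatter from
double-counting one movement. Bilateral exercises (leg lifts, steps,
kicks) are detected per side and merged so alternating left/right
excursions count separately; whole-body symmetric movements (squat,
sit-to-stand, hamstring stretch) are detected once.

Displacement thresholds operationalize qualitative criteria and are
configurable: staggered stance 0.15 m of relative foot lead (0.20 m for
tandem, where the heel must pass the toes; 0.20 m — about one foot length
— for the backward step), foot beyond shoulder 0.05 m, foot lift 0.05 m,
foot anterior to the pelvis 0.15 m, chest drop/reach 0.10 m, arm/foot
lateral excursion 0.10 m. Baselines for displacement metrics are the
median over the first 0.5 s of the stream, which is assumed to start in
the exercise's start posture.

**Quality rules.** Full quality criteria are published only for the squat
and tandem stance; the checker registry is pluggable for the rest.
Squat: peak hip and knee flexion within [70°, 110°] (90° ± 20°; a total
20° band [80°, 100°] is configurable, since "within a 20-degree range"
admits both readings), max lateral trunk lean < 10°, mean foot separation
within ±25 % of shoulder separation, feet displaced < 0.05 m during the
event, knees > 0.08 m apart and within 0.10 m of the feet in x.
Tandem stance: front-leg hip flexion ≥ 15° and hip adduction ≥ 5° (the
published proxy for heel-past-toes; the true foot-overlap geometry is not
modelled), held contiguously for the prescribed time.

**Timed exercises** score up to 3 hold attempts inside a 120 s window
(hold criteria = quality rules when configured, else attempt rules);
fidelity uses the best hold, adherence the summed attempt durations capped
at the prescription. **Missing markers** are linearly interpolated across
gaps ≤ 5 frames; longer gaps exclude their frames from event formation.
**Speed warnings** flag intervals where any joint's central-difference
speed exceeds 2.0 m/s for ≥ 0.2 s (both configurable).

## Engagement scoring

Adherence = attempted/prescribed, fidelity = quality/prescribed; both may
exceed 1.0. Stars: quality fraction < 0.50 → 1, in [0.50, 0.75] → 2,
> 0.75 → 3 — the boundary handling follows the literal "less than
50 %" / "more than 75 %" wording, so both edges land in the 2-star band,
and 1 star is the floor. In the feedback condition attempts are capped at
prescribed + 3 per exercise (the in-game limit); self-counted no-feedback
sessions are never capped. Session-level adherence/fidelity default to the
unweighted mean of per-exercise proportions; a pooled
total-attempts/total-prescribed mode is available because the aggregation
order is not uniquely determined by session-level reporting conventions.

## Design and statistics

**Schedules.** Admissible schedules have runs ≤ max_run (default 2) and,
with balance on (default), condition counts differing by ≤ 1. Enumeration
is exhaustive up to 24 sessions (the n = 16 balanced max-run-2 space has
1296 members) with a deterministic lexicographic order; draws are uniform
under a stated seed.

**PND.** Comparisons pair adjacent condition transitions in session
order, each session used at most once; ties count as overlap (strict
inequality defines non-overlap). This deterministic pairing reproduces the
magnitude of published comparison counts but is a documented choice — the
original procedure is not specified.

**Best-alone rule.** PND ≥ 90 % on the adherence path picks the superior
condition; otherwise the higher mean adherence. Exact mean ties are
surfaced as `undetermined` rather than silently broken.

**SCRT.** Statistic = difference in condition means under the observed
schedule; the null recomputes it under every admissible schedule
(exhaustive when the space is within the resampling budget, default
10 000; otherwise Monte-Carlo including the observed schedule, so p > 0).
One-tailed with ties extreme, default direction "feedback greater" per the
stated hypothesis. Because the null re-randomizes only over the restricted
space, the test is exact under exchangeability regardless of serial trend.

**Fisher–Pitman / Wilcoxon–Pratt.** Mean-difference statistic over all
C(n, n_a) label assignments (unpaired) and signed-rank statistic over all
2^m sign flips of non-zero differences (paired), with Pratt's treatment:
zeros are ranked with all |d|, then discarded. Exhaustive whenever the
assignment count fits the budget; Monte-Carlo samples always include the
observed assignment. All-zero differences give the degenerate p = 1.

**Bayes factor.** Two-sample JZS BF10 with a Cauchy(0, √2⁄2) prior on the
standardized effect (inverse-gamma(1/2, r²/2) on g), integrated with
adaptive quadrature; two-sided. The prior scale and sidedness are the
field-standard defaults — the original analyses name neither.

**Visual summaries.** Level = mean vs tertiles of the outcome scale
(adherence/fidelity on [0, 1.25] since both may exceed 1; ratings on
[1, 5]); trend = least-squares slope, |slope| < 0.01/session
zero-celerating, < 0.05 gradual, else steep; variability = coefficient of
variation, < 10 % stable, < 25 % somewhat, else highly variable. The
conventional labels are qualitative; these bands are the package's own
quantification and all are configurable.

## Agreement

WMRE = 100 × Σ|system − manual| / Σ manual (ratio of sums). This matches
"weighted mean of relative errors with manual as ground truth", reproduces
the 100 % boundary when the system records nothing, and is invariant to
count scaling; a per-video unweighted mean is available. Under the
ratio-of-sums form, videos with manual = 0 contribute their |system| to
the numerator only. Acceptability is strict: WMRE < 25 %.

ICC(2,1) comes from the two-way mean squares
(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n) with the exact F-based
confidence bounds (Satterthwaite degrees of freedom for the rater term).
With k = 2 raters the CI is mildly approximate; simulation with known
variance components (in the test suite) shows coverage a little below the
nominal 95 %, which is a known property of these bounds, not an
implementation artifact. Bland–Altman: bias = mean(system − manual),
limits = bias ± 1.96 × sample SD of differences.

## Synthetic data

The skeleton generator drives one or two anatomical angles (or segment
displacements) per exercise with a raised-cosine pulse per repetition
(trapezoidal plateau for timed holds), solved through a stick figure with
fixed child-scaled segment lengths (trunk 0.40 m, thigh 0.40 m, shank
0.40 m, shoulder half-width 0.16 m — all configurable). This is the
simplest model whose noiseless angle traces are exactly controllable, so
detector recovery (detected = constructed counts) is provable. Camera
jitter is additive isotropic Gaussian noise on joint positions (exercising
the angle-computation path, as real depth-camera jitter does), and
dropouts blank whole frames. It deliberately does **not** model
biomechanically realistic balance strategies, partial/ambiguous movements,
occlusion-correlated dropouts, multi-person scenes, or clothing/lighting
artifacts — so passing recovery tests demonstrates the detector logic, not
field robustness of any particular camera.

The session generator draws per-session adherence as
baseline + trend·i + N(0, sd), adding the feedback effect in feedback
sessions and optional self-miscount noise in no-feedback sessions
(children count their own repetitions without feedback). Defaults —
baseline 0.8, effect 0.2, sd 0.15 — are in the range reported for
supervised home programs in this population; the true distributions of
adherence and miscount noise are unpublished, so these are stated
placeholders, not estimates. With effect = 0 and miscount sd = 0 the two
conditions are exchangeable, which is what the type-I calibration tests
rely on.

## Problem sizes and determinism

The calibration suite uses 2000 null replicates of 16-session trials
(exhaustive 1296-schedule nulls, vectorized), 200 enumeration-checked
permutation instances at n ≤ 10, 50 noisy detection videos, and 500
ICC-coverage replicates — sizes chosen so the whole battery runs in a few
minutes on one core while keeping Monte-Carlo error well inside the
asserted bands. Every stochastic component takes an explicit integer seed
and one `numpy` Generator per call; identical inputs give bit-identical
outputs, and `run_trial` reports echo the seed and a configuration hash.

## Known limitations

Quality rule sets beyond squat and tandem stance must be supplied by the
user. The PND pairing rule and the visual-summary bands are documented
choices where the field's practice is qualitative. Angle conventions
assume an upright-ish trunk for the frontal-plane decomposition; seated
exercises are driven by displacement metrics instead. No multi-arm
(> 2 condition) designs, and no pose estimation — the package starts from
tracked joints.
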