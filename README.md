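# exengage

Engagement analytics for camera-tracked home exercise programs.

Children prescribed home physiotherapy — for example, children with
cerebral palsy working on lower-limb goals — often struggle to stick with
their exercises. Gamified programs track the child with a depth camera
(19 body joints at 30 frames/s) and can count exercise repetitions, grade
movement quality, and feed both back to the child as repetition counters
and star ratings. Evaluating whether that feedback actually changes
engagement calls for single-case experimental methods: each child serves
as their own control, alternating sessions with and without feedback.

`exengage` implements that full analysis chain as a tested, reusable
library:

* **kinematics** — joint angles (hip/knee flexion, hip ab/adduction,
  lateral trunk lean) from 19-joint skeleton streams; rule-based detection
  of attempted repetitions for 13 exercises (hysteresis segmentation, one
  threshold per named metric); quality grading (e.g. squat: hip/knee
  flexion 90° ± 20° at the lowest position, lateral trunk lean < 10°, feet
  shoulder-width and unmoving, knees apart and over the feet); timed holds
  (best of 3 attempts in a 120 s window); speed warnings.
* **engagement** — exercise *adherence* (attempted/prescribed, may exceed
  1.0), *fidelity* (high-quality/prescribed), the three-star rule
  (< 50 % of repetitions with appropriate form → 1 star, 50–75 % → 2,
  > 75 % → 3), and session summaries with the feedback-condition cap of
  prescribed + 3 attempts per exercise.
* **sced_design** — restricted randomization for alternating-treatments
  designs (no more than 2 consecutive sessions of the same condition),
  exhaustive schedule enumeration, uniform draws, and the best-alone rule
  (PND ≥ 90 % picks the superior condition, otherwise the higher mean
  adherence).
* **sced_stats** — percentage of non-overlapping data (PND), quantified
  visual summaries (level / trend / variability), the single-case
  randomization test whose null re-assigns outcomes over the *restricted*
  schedule space, Fisher–Pitman and Wilcoxon–Pratt permutation tests
  (one-tailed, ties extreme, exhaustive when feasible), and the two-sample
  JZS Bayes factor (Cauchy prior, r = √2⁄2, numerical integration).
* **agreement** — weighted mean relative error of system vs manual counts
  (WMRE, ratio of sums; < 25 % acceptable), ICC(2,1) with exact F-based
  95 % CI and the poor/moderate/good/excellent grading at 0.5/0.75/0.9,
  and Bland–Altman bias with 95 % limits of agreement.
* **synthetic_data** — a stick-figure pose generator whose noiseless angle
  traces are exactly controllable (so detector recovery is provable), an
  alternating-treatments series generator with a dial-in feedback effect
  (delta = 0 gives the exchangeable null for calibration), and correlated
  rater-count tables.
* **pipeline_io** — delimited-text formats for skeletons, session logs and
  agreement tables; YAML trial configuration; `run_trial` chaining
  detection → scoring → design → statistics → agreement into one
  deterministic report; a thin `exengage` CLI.

## Worked example

```python
from exengage import *

# 1. simulate one squat bout with realistic sensor noise, then detect/grade
prof = MotionProfile("squat", n_reps=8, noise_sd=0.010, dropout_rate=0.02, seed=7)
seq = simulate_skeleton(prof)
ex = default_exercises()["squat"]
events = detect_attempts(seq, ex)
graded = [assess_quality(e, seq, ex) for e in events]
n_quality = sum(g.quality for g in graded)
print(len(events), n_quality, star_rating(n_quality / len(events)))
# -> 8 5 2

# 2. a full alternating-treatments trial on synthetic sessions
from exengage.sced_design import enumerate_schedules, draw_schedule
space = enumerate_schedules(16, max_run=2, balance=True)   # 1296 schedules
sched = draw_schedule(space, seed=7)                       # NNFNFFNNFNFFNNFF
recs = simulate_atd_sessions(
    EffectSpec(feedback_delta=0.2, session_sd=0.1, seed=7), list(sched))
report = run_trial(TrialConfig(seed=7), recs)
write_report(report, "out/")
```

The summary the last call writes:

```
adherence: level high, trend zero-celerating, somewhat variable, PND 100.0%
...
best-alone condition: feedback (rule: pnd) - PND 100.0% >= 90% favouring feedback
adherence: scrt stat=0.2427 p=0.0007716
fidelity: wilcoxon_pratt stat=0.0791 p=0.05469
```

Reading it: all 8 squat attempts were detected under 10 mm camera jitter
and 2 % frame dropouts, 5 met every quality rule (62.5 % → 2 stars). In
the simulated trial the feedback condition's adherence exceeded its
no-feedback neighbour in every between-session comparison (PND 100 %), so
the best-alone rule picks feedback by non-overlap; the randomization test
confirms the 0.24 mean adherence difference is larger than under almost
every admissible re-scheduling (p ≈ 0.0008, exhaustive over 1296
schedules).

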