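# reachadapt

A hardware-free simulator and analysis suite for **adaptive duration tuning
in robot-assisted upper-limb reach training**.

Assist-as-needed rehabilitation robots guide point-to-point reaching
movements along a reference trajectory and must decide how much time to
allow for each movement: too little and the user is dragged, too much and
the training is unchallenging. This package implements, end to end and
without the robot, an adaptation scheme in which the set duration of each
movement is tuned iteratively to the user's own pace from the lead/lag
relation between the achieved and the reference trajectory. It is aimed at
researchers in rehabilitation robotics and human motor control who want to
study, extend or re-parameterise such adaptive schemes in simulation.

## The model

**Reference trajectory.** The robot follows a straight-line minimum-jerk
trajectory (MJT) between source and target: position
`x(t) = x_s + (x_t - x_s) * sigma(t/D)` with the quintic blend
`sigma(s) = 10 s^3 - 15 s^4 + 6 s^5`, which starts and ends at rest and
mimics the smoothness of natural reaching.

**Lead/lag metrics.** At every sample, the *effort* of a trajectory is the
signed scalar projection of its displacement from the source onto the unit
source→target vector. With `Effort_MJT` from the reference and
`Effort_Actual` from the achieved path,

    dEffort = Effort_MJT - Effort_Actual

is positive when the user trails (lags) the reference and negative when the
user is ahead (leads); its sum over the segment, `sum(dEffort)`, indicates
the dominant role over the whole movement. `tau` maps the segment's time
span linearly onto [-1, 1] for cross-segment comparison.

**Adaptation rule.** After each execution of segment *k*:

    if sum(dEffort) > 0:  duration_k <- duration_k + delta   # lagging
    else:                 duration_k <- duration_k - delta   # leading

with `delta` proportional to `|sum(dEffort)|` and bounded in [0, 1] s. The
updated duration is snapped to a 0.2 s grid and floored at 0.5 s. A
segment's duration has *converged* (reached its constant optimum) once the
trailing run of equal values across iterations is at least two long.

**Condition regression.** Executed durations are regressed on 0/1 dummies
for the movement conditions — embedded vs. virtual target (EV1), reach
vs. return (RR1), towards-gravity / ground-level vs. against-gravity
(G1, G2), small vs. large cross-body component (CB1) — plus participant
dummies and, in the interaction model, the products EV1G1, EV1G2, RR1G1,
RR1G2, RR1CB1, G1CB1, G2CB1:

    duration = b0 + b1 x1 + b2 x2 + ... + bi xi

Nested models are compared with the R² change and its F statistic, and
predictions for arbitrary condition profiles are obtained by substituting
the fitted (or published) `b_i` into the equation.

Synthetic participants close the loop: each follows their own minimum-jerk
clock with an intrinsic preferred duration per segment (plus optional
Gaussian position noise or, for passive users, a pure response delay), so
the adaptive loop's behaviour can be studied against a known ground truth.

## Worked example

```python
import reachadapt as ra

segments = ra.load_segments()               # the 13 task segments
seg = segments[1]                           # 0.32 m, embedded return movement

# an eager user who prefers 1.6 s for this segment, robot starts at 4 s
user = ra.UserModel(behavior="leading", preferred_duration=1.6)
seq = ra.run_adaptation(seg, user, ra.AdaptationConfig(), iterations=5, seed=0)
print(seq.durations, seq.converged, seq.optimum)
# (4.0, 3.0, 2.0, 1.6, 1.6) True 1.6
```

The set duration shrinks by the capped 1 s step while the user leads by a
lot, then lands on the user's preferred 1.6 s and stays — a trailing run of
two equal values, so the segment is flagged converged with optimum 1.6 s.

Substituting published interaction-model coefficients predicts durations
for condition combinations without refitting:

```python
from reachadapt import ConditionCoding, predict_duration, model2_coefficients

coeffs = model2_coefficients()
print(round(predict_duration(coeffs, ConditionCoding(ev1=1, g1=1)), 3))  # 7.191
print(round(predict_duration(coeffs, ConditionCoding(ev1=1)), 3))        # 2.881
print(round(predict_duration(coeffs, ConditionCoding(g1=1)), 3))         # 6.475
```

7.191 s is the predicted duration for an embedded target approached towards
gravity (constant − embedded effect + towards-gravity effect + their
interaction); 2.881 s for an embedded target against gravity; 6.475 s for a
virtual target towards gravity.

A whole cohort, and the regression on its logs:

```python
from reachadapt import Protocol, AdaptationConfig, default_user_factory, simulate_cohort
from reachadapt.analysis import SegmentDurationModel, records_from_logs

protocol = Protocol.default(segments)
logs = simulate_cohort(6, protocol, default_user_factory(segments),
                       AdaptationConfig(), seed=42)
fit = SegmentDurationModel.from_records(
    records_from_logs(logs, segments), include_interactions=False).fit()
print(round(fit.params["Embedded"], 3), round(fit.params["Reach"], 3))
# -0.265 0.257  — embedded targets faster, reaching slower, as planted
```

## Command line

```bash
reachadapt simulate --participants 10 --seed 1 --out-dir out   # cohort logs
reachadapt adapt --samples out/samples.csv --out-dir out       # replay logs
reachadapt analyze --records out/analysis_records.csv --out-dir out
reachadapt fixtures --out-dir fixtures                          # packaged tables
```

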