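# Methods

This note documents the models, parameter choices and numerical decisions
behind `reachadapt`, and what its simulations do and do not show.

## Reference trajectories

Point-to-point reference motion is the straight-line minimum-jerk
trajectory: `x(t) = x_s + (x_t - x_s) * sigma(t/D)` with
`sigma(s) = 10 s^3 - 15 s^4 + 6 s^5`. The blend has zero velocity and
acceleration at both endpoints; peak speed is `1.875 * length / D` at
mid-movement. Sampling places points at `t = 0, dt, 2dt, ...` and forces
the final sample to land exactly at `t = D`, so endpoint invariants hold
bit-exactly whether or not `D` is a multiple of `dt`. The default sampling
interval is `dt = 0.01 s` (configurable); every decision quantity in the
package is either rate-invariant or has a rate-invariant variant (see
below). Multi-via or curved paths are out of scope: each segment is an
independent straight-line movement.

## Task segments

The 13 task segments carry published lengths (0.276–0.415 m) and four
condition labels each: embedded vs. virtual target, reach vs. return,
direction relative to gravity (against / towards / ground level), and
small vs. large cross-body component. Segment *endpoints* are not
published, so `load_segments` synthesises a chained sequence of 3-D points
whose pairwise distances equal the published lengths and whose vertical
displacement sign matches the gravity label (up for against-gravity, down
for towards-gravity, zero for ground level), with the azimuth rotating
0.8 rad per segment so the path spreads through the workspace. The lengths
and labels are authoritative; the coordinates are illustrative. This is
sufficient because every metric in the package (projections, lead/lag
sums, normalised durations) depends only on source, target and length and
is invariant under rigid transformation — a property the test suite
asserts.

## Lead/lag metrics

`tau = 2 (t - t_start)/(t_end - t_start) - 1` maps a segment's time span
linearly onto [-1, 1]; linear is the minimal mapping consistent with that
purpose. The effort of a position is its signed scalar projection from the
source onto the unit source→target vector (metres; overshoot and
behind-source values are preserved). `dEffort = Effort_MJT -
Effort_Actual`, so a positive segment sum means the participant lagged for
the dominant part of the movement; this sign convention is what makes the
`> 0` branch of the adaptation rule the "lagging" branch.

When reference and achieved logs have different time bases, the achieved
positions are linearly interpolated onto the reference times with clamped
extrapolation at the ends (robot and log clocks need not align).

The raw per-sample sum `sum(dEffort)` scales with 1/dt for a fixed pair of
continuous trajectories. Decisions in this package depend only on its sign
(which is dt-invariant) or pass through the dt-compensating gain below; a
`time_weighted=True` option returns the trapezoidal time integral
(metre-seconds) instead, which is dt-invariant outright.

## Adaptation rule

After each execution of segment *k* the set duration is updated by
`delta = clip(gain * |sum(dEffort)|, delta_min, delta_max)` seconds, added
when the sum is positive (lagging) and subtracted otherwise. Defaults:

| parameter        | default | meaning                                              |
|------------------|---------|------------------------------------------------------|
| `delta_min/max`  | 0.0 / 1.0 s | bounds of the per-iteration adjustment            |
| `quantum`        | 0.2 s   | grid to which updated durations are snapped (0 = off)|
| `duration_floor` | 0.5 s   | smallest admissible set duration                     |
| `initial_duration` | 4.0 s | set duration of the first iteration                  |
| `gain`           | auto    | seconds of change per metre of accumulated lead/lag  |

The 0.2 s quantum reflects the granularity at which adapted set durations
are recorded in practice; the floor merely prevents non-physical values.

**Gain.** With `gain=None` the per-run gain is `2 * dt / length`. Two
properties motivate this choice. (a) A participant who never leaves the
source accumulates `sum(dEffort) ≈ n * length / 2` (the reference effort
integrated over n samples), which this gain maps to `delta ≈ D` — i.e. a
full-segment lag saturates the step at `delta_max`. (b) For an
intrinsic-duration user (below) the accumulated sum is
`≈ length * (D - P) / (2 dt)`, so `delta ≈ |D - P|`: the step equals the
actual duration mismatch and the loop lands on the preferred duration P in
a handful of iterations, e.g. 4.0 → 3.0 → 2.0 → 1.6 → 1.6 for P = 1.6 s.
Because the sum scales as 1/dt, the auto gain also makes the update
independent of the sampling rate. A fixed `gain` (seconds per metre) can be
set instead for studies of the update law itself.

**Convergence.** A duration sequence has reached its constant optimum when
the trailing run of values equal to the final one (within `tol`, default
1e-6 s on already-quantised values) has length ≥ `min_run` (default 2).
"Trailing" is deliberate: a plateau reached mid-sequence and left again —
users re-accelerating to outperform the robot produce exactly this
pattern — does not count, only a run that persists to the last iteration.

## Session protocol

A session executes the 13 segments, always in the same order, under the
schedule passive, AA1, 5×AA2, passive, AA1 (13 × 9 = 117 segment
executions), optionally preceded by warm-up passes excluded from analysis.
Only AA2 passes adapt durations; all other passes run at the per-segment
default (4 s). The first AA2 pass starts from one update applied to the
final preceding AA1 pass (configurable off), so adaptive durations have
already scaled below the default when the adaptive block begins — the
pattern seen in recorded sessions. Whether the closing passive/AA1 passes
should use adapted or default durations is not knowable from the record;
default is used, configurable. Inter-segment rest is not modelled.

## Synthetic participants

No biomechanics are modelled. A participant is an intrinsic-duration
follower: they run their own minimum-jerk clock along the segment axis at a
per-segment preferred duration P (clamping at the target once they arrive),
or — in passive mode — are dragged by the robot and trail it by a pure
response delay. Isotropic Gaussian position noise (default 2 mm in the
cohort generator) is added per sample, with the axial component clamped to
the segment. This model was chosen because it gives the loop's observable,
`sum(dEffort)`, a controlled and sign-correct dependence on `D - P`, which
turns preferred-duration recovery into a meaningful end-to-end test.

The cohort generator draws a per-participant base pace uniformly from
3.5–6.5 s per metre of segment length (bracketing the ~5 s/m that recorded
final durations normalise to) and multiplies in condition factors
(embedded ×0.80, reach ×1.25, towards-gravity ×1.05, ground ×1.10, small
cross-body ×0.95), planting effect directions — embedded faster, reaching
slower — that the regression must recover.

What the simulations do **not** emulate: within-session drift of intent
(users pushing harder in later iterations), force interaction dynamics,
fatigue, muscle-group asymmetries between movement types, or any cognitive
difference between embedded and virtual targets beyond the planted
multiplicative factor. Passing tests therefore show that the algorithms
behave as specified under the stated generative model, not that real
cohorts would reproduce particular published regression coefficients or
convergence counts.

## Regression analysis

The condition regression is ordinary least squares on 0/1 dummies with
reference categories Virtual (EV0), Return (RR0), Against Gravity (G0),
Large cross-body (CB0) and a reference participant (default participant 1);
the interaction model adds the seven products EV1G1, EV1G2, RR1G1, RR1G2,
RR1CB1, G1CB1, G2CB1. Fitting, standard errors, t and p values (two-sided
t on residual df) come from statsmodels OLS; standardized betas are
`b_i * sd(x_i) / sd(y)`; Durbin-Watson is computed on residuals in record
order (participant, mode, iteration, segment), as the original ordering
convention is unstated. Nested models are compared via
`F = ((R2_full - R2_restricted)/df1) / ((1 - R2_full)/df2)` with p from the
F distribution. Rank-deficient designs are rejected with the offending
columns named. Which executions enter the regression is the caller's
choice; `records_from_logs` defaults to all actual-performance AA2 records.

**Substitution predictions.** `predict_duration` evaluates
`b0 + sum(b_i x_i)` for a condition profile against any coefficient
mapping, including the packaged published coefficient table, and
`condition_duration_table` tabulates the target-type/movement × gravity
grid. Published grids round coefficients to 3 decimals before summing, so
four cells of the published table differ from the coefficient-sum value by
0.001 s (Virtual/Ground 8.190 vs 8.189, Reach/Against 10.792 vs 10.791,
Reach/Towards 8.227 vs 8.226, Reach/Ground 8.864 vs 8.863); exact
assertions target only the cells that reproduce from the printed
coefficients (7.191, 2.881, 6.475, 6.358, 7.543). Likewise the published
nested-model F (104.518) cannot be recovered exactly from the published
R² pair rounded to 3 decimals; it is checked to lie in the interval the
rounded inputs imply.

## Fixtures and demographics

Five table transcriptions ship with the package (demographics; one
participant's per-iteration durations; segment definitions; the coding
scheme; the interaction-model coefficients), each pinned by SHA-256
checksum. Cohort age statistics describe all recruited participants; the
population SD (divisor n) is the reporting default because it reproduces
the published 9.4 from the recruited ages (sample SD gives 9.5), with
`sample_sd=True` exposed. The per-participant adaptation table for the full
cohort is not publicly available; cohort-level convergence counts are
emulated qualitatively by the synthetic generator and frozen-seed
regression tests, not asserted against published counts.

## Problem sizes and determinism

Defaults keep everything fast: dt = 0.01 s, 13 segments, 5 adaptive
iterations, cohorts of 6–10 in examples and tests; a full simulated session
takes ~0.5 s and the whole test suite ~20 s. All randomness flows from
numpy `SeedSequence` spawns of a single master seed; identical seeds give
bit-identical logs. Hypothesis property tests run derandomised.
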