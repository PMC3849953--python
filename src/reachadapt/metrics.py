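"""Lead/lag performance measures and duration-convergence detection.

The human's contribution during a guided movement is measured by comparing
the achieved end-effector path with the time-matched reference:

* ``tau`` maps the time axis of one segment onto [-1, 1].
* ``effort_projection`` is the signed scalar projection of the displacement
  from the segment source onto the unit source-to-target vector, metres.
* ``delta_effort`` = reference effort - achieved effort at a sample; a
  positive value means the participant is behind the reference (lagging),
  a negative value that they are ahead (leading).
* ``summarize_efforts`` collects the per-sample series and the segment
  aggregate sum(delta_effort), whose sign indicates whether the participant
  led or lagged for the major part of the segment.

Duration convergence across adaptation iterations uses the constant-optimum
rule: a segment's duration has settled once the trailing run of equal
values (within tolerance) is at least ``min_run`` long. A mid-sequence
plateau that is later left again does not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trajectory import Point3, Segment, TrajectorySample, samples_to_arrays

__all__ = [
    "DegenerateSegmentError",
    "EffortSeries",
    "DurationSequence",
    "ConvergenceResult",
    "tau",
    "effort_projection",
    "delta_effort",
    "summarize_efforts",
    "segment_magnitude",
    "normalized_duration",
    "is_constant_optimum",
    "count_converged_segments",
    "duration_sequences_from_table",
    "write_effort_series_csv",
]


class DegenerateSegmentError(ValueError):
    """Raised when a segment's source and target coincide (zero length)."""


def tau(t_start: float, t_end: float, t: float) -> float:
    """Map time ``t`` within [t_start, t_end] linearly onto [-1, 1]."""
    if not t_end > t_start:
        raise ValueError(f"t_end = {t_end} must exceed t_start = {t_start}")
    if t < t_start or t > t_end:
        raise ValueError(f"t = {t} outside segment window [{t_start}, {t_end}]")
    return 2.0 * (t - t_start) / (t_end - t_start) - 1.0


def segment_magnitude(a: Point3, b: Point3) -> float:
    """Euclidean distance between two points, metres."""
    return a.distance_to(b)


def _axis(source: Point3, target: Point3) -> tuple[np.ndarray, np.ndarray, float]:
    a = source.as_array()
    d = target.as_array() - a
    length = float(np.linalg.norm(d))
    if length == 0.0:
        raise DegenerateSegmentError("source and target coincide")
    return a, d / length, length


def effort_projection(position: Point3, source: Point3, target: Point3) -> float:
    """Signed projection of (position - source) on the source->target axis.

    May exceed the segment length (overshoot) or be negative (behind the
    source); both are meaningful and preserved.
    """
    a, u, _ = _axis(source, target)
    return float(np.dot(position.as_array() - a, u))


def delta_effort(
    reference_position: Point3,
    actual_position: Point3,
    source: Point3,
    target: Point3,
) -> float:
    """Reference effort minus achieved effort; positive means lagging."""
    return effort_projection(reference_position, source, target) - effort_projection(
        actual_position, source, target
    )


@dataclass(frozen=True)
class EffortSeries:
    """Per-sample lead/lag series for one segment execution."""

    segment_id: int
    t: np.ndarray
    tau: np.ndarray
    effort_mjt: np.ndarray
    effort_actual: np.ndarray
    delta_effort: np.ndarray
    sum_delta_effort: float
    n_samples: int

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("tau", "effort_mjt", "effort_actual", "delta_effort"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from t")
        if self.n_samples != n:
            raise ValueError("n_samples inconsistent with series length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": self.segment_id,
                "t": self.t,
                "tau": self.tau,
                "effort_mjt": self.effort_mjt,
                "effort_actual": self.effort_actual,
                "delta_effort": self.delta_effort,
            }
        )


def _resample(
    ref_t: np.ndarray, act_t: np.ndarray, act_pos: np.ndarray
) -> np.ndarray:
    """Linearly interpolate achieved positions onto the reference times.

    Extrapolation is clamped to the first/last achieved sample, matching a
    log whose clock starts late or stops early.
    """
    if act_t[-1] < ref_t[0] or act_t[0] > ref_t[-1]:
        raise ValueError("reference and achieved trajectories do not overlap in time")
    return np.column_stack(
        [np.interp(ref_t, act_t, act_pos[:, k]) for k in range(act_pos.shape[1])]
    )


def summarize_efforts(
    reference: Sequence[TrajectorySample],
    actual: Sequence[TrajectorySample],
    segment: Segment,
    *,
    time_weighted: bool = False,
) -> EffortSeries:
    """Build the per-sample effort series and its segment aggregate.

    The achieved trajectory is resampled onto the reference time base by
    clamped linear interpolation when the two time bases differ. With
    ``time_weighted=True`` the aggregate is the trapezoidal time integral of
    delta_effort (metre-seconds), which is invariant to the sampling rate;
    the default is the raw per-sample sum (metres), whose sign carries the
    lead/lag decision either way.
    """
    source, target = segment.require_endpoints()
    ref_t, ref_pos = samples_to_arrays(reference)
    act_t, act_pos = samples_to_arrays(actual)
    if len(ref_t) != len(act_t) or not np.allclose(ref_t, act_t):
        act_pos = _resample(ref_t, act_t, act_pos)
    a, u, _ = _axis(source, target)
    e_ref = (ref_pos - a) @ u
    e_act = (act_pos - a) @ u
    delta = e_ref - e_act
    if time_weighted:
        total = float(np.trapezoid(delta, ref_t))
    else:
        total = float(delta.sum())
    taus = 2.0 * (ref_t - ref_t[0]) / (ref_t[-1] - ref_t[0]) - 1.0
    return EffortSeries(
        segment_id=segment.id,
        t=ref_t,
        tau=taus,
        effort_mjt=e_ref,
        effort_actual=e_act,
        delta_effort=delta,
        sum_delta_effort=total,
        n_samples=len(ref_t),
    )


def write_effort_series_csv(series: Iterable[EffortSeries], path) -> None:
    """Write one or more effort series as a tidy CSV."""
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


def normalized_duration(recorded: float, magnitude: float) -> float:
    """Recorded segment duration per unit segment length, seconds/metre."""
    if not magnitude > 0:
        raise DegenerateSegmentError(f"segment magnitude must be positive, got {magnitude}")
    return recorded / magnitude


class ConvergenceResult(NamedTuple):
    converged: bool
    optimum: float | None


def is_constant_optimum(
    durations: Sequence[float], min_run: int = 2, tol: float = 1e-6
) -> ConvergenceResult:
    """Constant-optimum rule: has the trailing run of equal values settled?

    Returns ``(True, value)`` iff the run of values equal (within ``tol``)
    to the final duration, counted backwards from the end, has length of at
    least ``min_run``. Earlier plateaus that were left again do not qualify.
    """
    durations = list(durations)
    if not durations:
        raise ValueError("duration sequence is empty")
    if min_run < 2:
        raise ValueError(f"min_run must be at least 2, got {min_run}")
    last = durations[-1]
    run = 1
    for d in reversed(durations[:-1]):
        if abs(d - last) <= tol:
            run += 1
        else:
            break
    if run >= min_run:
        return ConvergenceResult(True, float(last))
    return ConvergenceResult(False, None)


@dataclass(frozen=True)
class DurationSequence:
    """Duration of one segment across adaptation iterations."""

    segment_id: int
    durations: tuple[float, ...]
    converged: bool
    optimum: float | None

    def __post_init__(self) -> None:
        if not self.durations:
            raise ValueError("duration sequence is empty")
        if any(d <= 0 for d in self.durations):
            raise ValueError("all durations must be positive")
        if self.converged != (self.optimum is not None):
            raise ValueError("optimum must be present iff converged")

    @classmethod
    def from_durations(
        cls,
        segment_id: int,
        durations: Sequence[float],
        min_run: int = 2,
        tol: float = 1e-6,
    ) -> "DurationSequence":
        converged, optimum = is_constant_optimum(durations, min_run=min_run, tol=tol)
        return cls(segment_id, tuple(float(d) for d in durations), converged, optimum)


def count_converged_segments(sequences: Iterable[DurationSequence]) -> int:
    """Number of segments whose duration reached a constant optimum."""
    sequences = list(sequences)
    if sequences:
        n_iter = {len(s.durations) for s in sequences}
        if len(n_iter) > 1:
            raise ValueError(f"sequences have unequal iteration counts: {sorted(n_iter)}")
    return sum(1 for s in sequences if s.converged)


def duration_sequences_from_table(
    table: pd.DataFrame,
    participant: int,
    mode: str = "AA2",
    min_run: int = 2,
    tol: float = 1e-6,
) -> dict[int, DurationSequence]:
    """Build per-segment duration sequences from a tidy duration table.

    ``table`` needs columns ``participant, mode, iteration, seg, duration_s``
    (the layout of the packaged adaptation-table fixture).
    """
    sub = table[(table["participant"] == participant) & (table["mode"] == mode)]
    out: dict[int, DurationSequence] = {}
    for seg, grp in sub.groupby("seg"):
        durations = grp.sort_values("iteration")["duration_s"].to_numpy(dtype=float)
        out[int(seg)] = DurationSequence.from_durations(
            int(seg), durations, min_run=min_run, tol=tol
        )
    return out
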