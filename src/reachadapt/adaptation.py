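"""The duration-adaptation rule and its iteration across repetitions.

After each execution of a segment the aggregate lead/lag measure
sum(delta_effort) decides the update of that segment's set duration:

    if sum(delta_effort) > 0:   # participant lagging
        duration <- duration + delta
    else:                       # participant leading
        duration <- duration - delta

with delta proportional to |sum(delta_effort)| and clipped to
[delta_min, delta_max] (0.0 to 1.0 s by default). The updated duration is
optionally snapped to a quantum grid (0.2 s by default, the granularity at
which set durations are observed in practice) and never drops below a
physical floor.

The proportionality gain maps metres of accumulated lead/lag to seconds.
When left unset it is derived per run as ``2 * dt / length``: a participant
stuck at the source for the whole segment accumulates roughly
n * length / 2 metres of lag, which this gain maps to the set duration
itself, saturating delta at its cap; conversely, for an intrinsic-duration
user the accumulated measure is about length * (D - P) / (2 * dt), so delta
approximates the actual duration mismatch D - P and the loop homes in on
the preferred duration within a few iterations. Because sum(delta_effort)
scales as 1/dt, this auto gain also makes the update independent of the
sampling rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .metrics import DurationSequence, summarize_efforts
from .trajectory import Segment, sample_trajectory
from .user_sim import UserModel, simulate_segment

__all__ = [
    "AdaptationConfig",
    "AdaptationState",
    "DurationUpdate",
    "update_duration",
    "run_adaptation",
]


@dataclass(frozen=True)
class AdaptationConfig:
    """Tunable parameters of the duration-update rule.

    gain
        seconds of duration change per metre of accumulated lead/lag;
        ``None`` selects the auto gain ``2 * dt / segment length`` at run
        time (see module docstring).
    delta_min, delta_max
        bounds of the per-iteration adjustment delta, seconds.
    duration_floor
        smallest admissible set duration, seconds.
    quantum
        rounding step for updated durations, seconds; 0 disables rounding.
    initial_duration
        set duration of the first adaptive iteration, seconds.
    """

    gain: float | None = None
    delta_min: float = 0.0
    delta_max: float = 1.0
    duration_floor: float = 0.5
    quantum: float = 0.2
    initial_duration: float = 4.0

    def __post_init__(self) -> None:
        if self.gain is not None and not self.gain > 0:
            raise ValueError("gain must be positive (or None for auto)")
        if not (0 <= self.delta_min < self.delta_max):
            raise ValueError("need 0 <= delta_min < delta_max")
        if not self.duration_floor > 0:
            raise ValueError("duration_floor must be positive")
        if self.quantum < 0:
            raise ValueError("quantum must be non-negative")
        if not self.initial_duration > 0:
            raise ValueError("initial_duration must be positive")

    @classmethod
    def from_mapping(cls, mapping) -> "AdaptationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "AdaptationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def effective_gain(self, segment: Segment, dt: float) -> float:
        return self.gain if self.gain is not None else 2.0 * dt / segment.length


class DurationUpdate(NamedTuple):
    duration: float
    delta: float


def _snap(value: float, quantum: float) -> float:
    if quantum <= 0:
        return value
    return quantum * math.floor(value / quantum + 0.5)


def update_duration(
    current: float,
    sum_delta_effort: float,
    config: AdaptationConfig,
    gain: float | None = None,
) -> DurationUpdate:
    """Apply the duration-update rule once.

    Returns the new duration together with the applied delta for logging.
    ``gain`` overrides the config gain (used for the per-segment auto gain).
    """
    if current < config.duration_floor:
        raise ValueError(
            f"current duration {current} is below the floor {config.duration_floor}"
        )
    g = gain if gain is not None else config.gain
    if g is None:
        raise ValueError("no gain given; set config.gain or pass the per-segment gain")
    delta = float(np.clip(g * abs(sum_delta_effort), config.delta_min, config.delta_max))
    new = current + delta if sum_delta_effort > 0 else current - delta
    new = _snap(new, config.quantum)
    new = max(new, config.duration_floor)
    return DurationUpdate(float(new), delta)


@dataclass
class AdaptationState:
    """Per-segment set durations and their history across iterations."""

    durations: dict[int, float]
    iteration: int = 0
    history: dict[int, list[float]] = field(default_factory=dict)

    def record(self, segment_id: int, duration: float) -> None:
        self.history.setdefault(segment_id, []).append(float(duration))

    def sequences(self, min_run: int = 2, tol: float = 1e-6) -> dict[int, DurationSequence]:
        return {
            seg: DurationSequence.from_durations(seg, hist, min_run=min_run, tol=tol)
            for seg, hist in self.history.items()
        }


def run_adaptation(
    segment: Segment,
    user: UserModel,
    config: AdaptationConfig,
    iterations: int,
    seed: int = 0,
    dt: float = 0.01,
    *,
    min_run: int = 2,
    tol: float = 1e-6,
    return_log: bool = False,
):
    """Iterate the adaptive loop for one segment against a simulated user.

    Iteration 1 executes at ``config.initial_duration``; each later
    iteration executes at the duration updated from the previous
    iteration's sum(delta_effort). Returns the :class:`DurationSequence`
    (with the constant-optimum convergence flag), and with
    ``return_log=True`` also a tidy DataFrame of per-iteration records.
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(iterations)
    gain = config.effective_gain(segment, dt)
    duration = config.initial_duration
    durations: list[float] = []
    rows: list[dict] = []
    for i in range(iterations):
        reference = sample_trajectory(segment, duration, dt)
        achieved = simulate_segment(segment, duration, user, dt=dt, seed=int(child_seeds[i]))
        series = summarize_efforts(reference, achieved, segment)
        durations.append(duration)
        delta_applied = 0.0
        if i < iterations - 1:
            updated = update_duration(duration, series.sum_delta_effort, config, gain=gain)
            delta_applied = updated.delta
            duration = updated.duration
        rows.append(
            {
                "seg": segment.id,
                "iteration": i + 1,
                "duration_s": durations[-1],
                "sum_delta_effort": series.sum_delta_effort,
                "delta_applied": delta_applied,
            }
        )
    sequence = DurationSequence.from_durations(segment.id, durations, min_run=min_run, tol=tol)
    if return_log:
        log = pd.DataFrame(rows)
        log["converged"] = sequence.converged
        return sequence, log
    return sequence
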