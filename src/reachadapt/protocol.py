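"""The session schedule and its orchestration.

One experimental session executes the 13 segments, in the same fixed order,
under a schedule of modes:

    passive, AA1, AA2 x 5, passive, AA1      (actual-performance phase)

optionally preceded by a warm-up (training) phase that is excluded from
analysis. The passive mode drags a passive participant along the reference;
the two active-assisted modes require the participant to initiate and work
with the robot, and only the second one (AA2) has duration adaptation
enabled. Durations never change outside AA2 passes; the final passive/AA1
passes run at the default durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .adaptation import AdaptationConfig, update_duration
from .metrics import DurationSequence, EffortSeries, summarize_efforts
from .trajectory import Segment, sample_trajectory
from .user_sim import UserModel, simulate_segment

__all__ = ["Mode", "PASSIVE", "AA1", "AA2", "Protocol", "SessionLog", "run_session"]

_MODE_NAMES = frozenset({"passive", "AA1", "AA2"})


@dataclass(frozen=True)
class Mode:
    """One mode of robot operation."""

    name: str
    robot_active: bool
    user_initiates: bool
    adaptation_enabled: bool

    def __post_init__(self) -> None:
        if self.name not in _MODE_NAMES:
            raise ValueError(f"mode name must be one of {sorted(_MODE_NAMES)}, got {self.name!r}")
        if self.name == "passive" and self.user_initiates:
            raise ValueError("passive mode cannot be user-initiated")
        if self.name in ("AA1", "AA2") and not self.user_initiates:
            raise ValueError(f"{self.name} must be user-initiated")
        if self.adaptation_enabled and self.name != "AA2":
            raise ValueError(f"adaptation can only be enabled for AA2, not {self.name}")


PASSIVE = Mode("passive", robot_active=True, user_initiates=False, adaptation_enabled=False)
AA1 = Mode("AA1", robot_active=True, user_initiates=True, adaptation_enabled=False)
AA2 = Mode("AA2", robot_active=True, user_initiates=True, adaptation_enabled=True)

DEFAULT_SCHEDULE: tuple[tuple[Mode, int], ...] = (
    (PASSIVE, 1),
    (AA1, 1),
    (AA2, 5),
    (PASSIVE, 1),
    (AA1, 1),
)


@dataclass(frozen=True)
class Protocol:
    """Segment order and mode schedule of one session."""

    segments: tuple[Segment, ...]
    schedule: tuple[tuple[Mode, int], ...] = DEFAULT_SCHEDULE
    training_repetitions: int = 0  # warm-up passes per mode, excluded from analysis
    seed_adaptation_from_previous: bool = True

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for mode, reps in self.schedule:
            if reps < 0:
                raise ValueError(f"repetitions must be non-negative, got {reps} for {mode.name}")
        if self.training_repetitions < 0:
            raise ValueError("training_repetitions must be non-negative")

    @classmethod
    def default(cls, segments: Sequence[Segment] | None = None, aa2_repetitions: int = 5) -> "Protocol":
        if segments is None:
            from .fixtures_io import load_segments

            segments = load_segments()
        schedule = (
            (PASSIVE, 1),
            (AA1, 1),
            (AA2, aa2_repetitions),
            (PASSIVE, 1),
            (AA1, 1),
        )
        return cls(segments=tuple(segments), schedule=schedule)


@dataclass
class SessionLog:
    """Everything recorded during one simulated session."""

    participant_id: int
    records: pd.DataFrame  # one row per segment execution
    duration_sequences: dict[int, DurationSequence]  # per-segment AA2 history
    effort_series: list[EffortSeries] = field(default_factory=list)

    @property
    def actual_performance(self) -> pd.DataFrame:
        return self.records[self.records["phase"] == "actual"].reset_index(drop=True)

    def adaptation_frame(self) -> pd.DataFrame:
        """AA2 records in the adaptation-log CSV layout."""
        aa2 = self.records[
            (self.records["mode"] == "AA2") & (self.records["phase"] == "actual")
        ]
        out = aa2[
            ["participant", "seg", "iteration", "duration_s", "sum_delta_effort", "delta_applied"]
        ].copy()
        out["converged"] = out["seg"].map(
            {seg: s.converged for seg, s in self.duration_sequences.items()}
        )
        return out.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _effective_user(user: UserModel, mode: Mode) -> UserModel:
    """Mode determines the interaction dynamics.

    In the passive mode every participant is dragged by the robot
    (passive-lag dynamics with their response delay); in the active-assisted
    modes the participant's own behaviour applies.
    """
    if mode.name == "passive":
        return user.with_behavior("passive_lag")
    if user.behavior == "passive_lag":
        return user.with_behavior("cooperative")
    return user


def run_session(
    protocol: Protocol,
    user: UserModel,
    config: AdaptationConfig,
    seed: int = 0,
    dt: float = 0.01,
    participant_id: int = 1,
    store_traces: bool = False,
) -> SessionLog:
    """Execute the full schedule and return the session log.

    Duration adaptation is active only during AA2 passes. The first AA2
    pass starts from one update applied to the final preceding AA1 pass
    (``protocol.seed_adaptation_from_previous``), so set durations have
    already scaled down from the default when adaptation proper begins;
    with the flag off it starts at ``config.initial_duration`` unchanged.
    """
    n_passes = protocol.training_repetitions * 3 + sum(r for _, r in protocol.schedule)
    child = np.random.SeedSequence(seed).generate_state(
        max(n_passes * len(protocol.segments), 1)
    )
    seed_iter = iter(int(s) for s in child)

    rows: list[dict] = []
    stored: list[EffortSeries] = []
    pass_counter = 0
    aa2_durations: dict[int, float] = {}
    aa2_started = False
    last_aa1_sums: dict[int, float] = {}
    history: dict[int, list[float]] = {seg.id: [] for seg in protocol.segments}

    def execute_pass(mode: Mode, phase: str, iteration: int, adapt: bool) -> None:
        nonlocal aa2_started, pass_counter
        pass_counter += 1
        eff_user = _effective_user(user, mode)
        for segment in protocol.segments:
            if adapt:
                if not aa2_started:
                    start = config.initial_duration
                    if protocol.seed_adaptation_from_previous and segment.id in last_aa1_sums:
                        gain = config.effective_gain(segment, dt)
                        start = update_duration(
                            config.initial_duration,
                            last_aa1_sums[segment.id],
                            config,
                            gain=gain,
                        ).duration
                    aa2_durations[segment.id] = start
                duration = aa2_durations[segment.id]
            else:
                duration = segment.default_duration
            reference = sample_trajectory(segment, duration, dt)
            achieved = simulate_segment(segment, duration, eff_user, dt=dt, seed=next(seed_iter))
            series = summarize_efforts(reference, achieved, segment)
            delta_applied = 0.0
            if adapt:
                history[segment.id].append(duration)
                gain = config.effective_gain(segment, dt)
                updated = update_duration(duration, series.sum_delta_effort, config, gain=gain)
                aa2_durations[segment.id] = updated.duration
                delta_applied = updated.delta
            if mode.name == "AA1" and phase == "actual":
                last_aa1_sums[segment.id] = series.sum_delta_effort
            rows.append(
                {
                    "participant": participant_id,
                    "phase": phase,
                    "mode": mode.name,
                    "pass_index": pass_counter,
                    "iteration": iteration,
                    "seg": segment.id,
                    "duration_s": duration,
                    "sum_delta_effort": series.sum_delta_effort,
                    "delta_applied": delta_applied,
                }
            )
            if store_traces:
                stored.append(series)
        if adapt:
            aa2_started = True

    for _ in range(protocol.training_repetitions):
        for mode in (PASSIVE, AA1, AA2):
            execute_pass(mode, phase="training", iteration=0, adapt=False)

    for mode, reps in protocol.schedule:
        for rep in range(1, reps + 1):
            execute_pass(
                mode,
                phase="actual",
                iteration=rep,
                adapt=mode.adaptation_enabled,
            )

    sequences = {
        seg_id: DurationSequence.from_durations(seg_id, hist)
        for seg_id, hist in history.items()
        if hist
    }
    return SessionLog(
        participant_id=participant_id,
        records=pd.DataFrame(rows),
        duration_sequences=sequences,
        effort_series=stored,
    )
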