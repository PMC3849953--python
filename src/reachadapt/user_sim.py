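"""Synthetic participants that close the human-robot interaction loop.

No biomechanics are modelled. Each simulated participant follows their own
minimum-jerk clock along the segment axis:

* ``leading`` / ``cooperative`` users execute the segment at their intrinsic
  preferred duration regardless of the robot's set duration, clamping at the
  target once they arrive. A cooperative user is simply one whose preferred
  duration matches the robot's.
* ``passive_lag`` users are dragged by the robot and trail it by a pure
  response delay, clamped at the source before they start moving.

Isotropic Gaussian position noise can be added per sample; the axial
component is clamped to [source, target] afterwards, so achieved progress
never leaves the segment. Given a seed the traces are bit-reproducible.

The intrinsic-duration model makes the adaptation loop's observable —
sum(delta_effort) — depend on the gap between the robot's set duration and
the participant's preferred one with the correct sign, so the loop's
recovery of a planted preferred duration is a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np

from .trajectory import Point3, Segment, TrajectorySample, _blend, _sample_times

__all__ = ["UserModel", "BEHAVIORS", "simulate_segment", "simulate_cohort", "default_user_factory"]

BEHAVIORS = frozenset({"passive_lag", "cooperative", "leading"})


@dataclass(frozen=True)
class UserModel:
    """A synthetic participant.

    ``preferred_duration`` is either one value for every segment or a
    mapping from segment id to seconds. ``response_lag`` only matters for
    ``passive_lag`` behaviour.
    """

    behavior: str = "leading"
    preferred_duration: float | Mapping[int, float] = 2.0
    noise_sd: float = 0.0  # metres
    response_lag: float = 0.0  # seconds
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"behavior must be one of {sorted(BEHAVIORS)}, got {self.behavior!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.response_lag < 0:
            raise ValueError("response_lag must be non-negative")
        if isinstance(self.preferred_duration, (int, float)):
            if not self.preferred_duration > 0:
                raise ValueError("preferred_duration must be positive")
        else:
            if any(v <= 0 for v in self.preferred_duration.values()):
                raise ValueError("all preferred durations must be positive")

    def preferred_for(self, segment_id: int) -> float:
        if isinstance(self.preferred_duration, (int, float)):
            return float(self.preferred_duration)
        try:
            return float(self.preferred_duration[segment_id])
        except KeyError:
            raise KeyError(f"no preferred duration for segment {segment_id}") from None

    def with_behavior(self, behavior: str) -> "UserModel":
        return replace(self, behavior=behavior)


def simulate_segment(
    segment: Segment,
    robot_duration: float,
    user: UserModel,
    dt: float = 0.01,
    seed: int | None = None,
) -> list[TrajectorySample]:
    """Generate the achieved trajectory of ``user`` against the reference.

    Samples share the reference time base (t = 0 .. robot_duration at
    interval ``dt``, final sample exactly at the set duration).
    """
    if not robot_duration > 0:
        raise ValueError(f"robot_duration must be positive, got {robot_duration}")
    source, target = segment.require_endpoints()
    a = source.as_array()
    u = segment.direction()
    length = segment.length
    t = _sample_times(robot_duration, dt)

    if user.behavior in ("leading", "cooperative"):
        preferred = user.preferred_for(segment.id)
        s = np.clip(t / preferred, 0.0, 1.0)
        axial = length * np.array([_blend(si) for si in s])
    else:  # passive_lag: dragged by the robot, pure delay
        shifted = np.clip(t - user.response_lag, 0.0, robot_duration)
        axial = length * np.array([_blend(si / robot_duration) for si in shifted])

    pos = a + np.outer(axial, u)
    if user.noise_sd > 0:
        rng = np.random.default_rng(seed if seed is not None else user.seed)
        pos = pos + rng.normal(0.0, user.noise_sd, size=pos.shape)
        # clamp only the along-axis component; transverse noise is physical
        rel = pos - a
        ax = rel @ u
        transverse = rel - np.outer(ax, u)
        pos = a + np.outer(np.clip(ax, 0.0, length), u) + transverse

    return [
        TrajectorySample(t=float(ti), position=Point3.from_array(pi))
        for ti, pi in zip(t, pos)
    ]


#: default multiplicative effects of the segment conditions on a simulated
#: participant's preferred duration (embedded targets are faster to acquire,
#: reaching away takes longer than returning)
DEFAULT_CONDITION_FACTORS = {
    "embedded": 0.80,
    "reach": 1.25,
    "towards": 1.05,
    "ground": 1.10,
    "small": 0.95,
}


def default_user_factory(
    segments,
    *,
    base_rate_range: tuple[float, float] = (3.5, 6.5),
    condition_factors: Mapping[str, float] | None = None,
    noise_sd: float = 0.002,
) -> Callable[[int, int], UserModel]:
    """Factory of heterogeneous leading users with planted condition effects.

    Each participant draws a base speed (seconds per metre of segment
    length); the preferred duration for a segment is base_rate * length,
    scaled by multiplicative factors for the segment's condition labels.
    Planted directions (embedded faster, reach slower) let the regression
    analysis be exercised against a known ground truth.
    """
    factors = dict(DEFAULT_CONDITION_FACTORS)
    if condition_factors:
        factors.update(condition_factors)
    segments = list(segments)

    def make(participant_id: int, seed: int) -> UserModel:
        rng = np.random.default_rng(seed)
        rate = rng.uniform(*base_rate_range)
        preferred = {}
        for seg in segments:
            d = rate * seg.length
            if seg.embedded:
                d *= factors["embedded"]
            if seg.reach:
                d *= factors["reach"]
            if seg.gravity == "towards":
                d *= factors["towards"]
            elif seg.gravity == "ground":
                d *= factors["ground"]
            if seg.cross_body == "small":
                d *= factors["small"]
            preferred[seg.id] = d
        return UserModel(
            behavior="leading",
            preferred_duration=preferred,
            noise_sd=noise_sd,
            seed=seed,
        )

    return make


def simulate_cohort(
    n_participants: int,
    protocol,
    user_factory: Callable[[int, int], UserModel],
    config,
    seed: int = 0,
    dt: float = 0.01,
):
    """Run a full session per simulated participant; reproducible from seed.

    Returns a list of :class:`reachadapt.protocol.SessionLog`, one per
    participant (ids 1..n).
    """
    from .protocol import run_session  # local import to avoid a cycle

    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(max(2 * n_participants, 1))
    logs = []
    for pid in range(1, n_participants + 1):
        user = user_factory(pid, int(states[2 * (pid - 1)]))
        logs.append(
            run_session(
                protocol,
                user,
                config,
                seed=int(states[2 * (pid - 1) + 1]),
                dt=dt,
                participant_id=pid,
            )
        )
    return logs
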