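"""Minimum-jerk reference trajectories for point-to-point reaching.

The robot guides the hand along the straight line between a source and a
target point using the classic minimum-jerk time profile: the normalised
path coordinate follows the quintic blend

    sigma(s) = 10 s^3 - 15 s^4 + 6 s^5,    s = t / duration,

which starts and ends at rest (zero velocity and acceleration at both
endpoints) and minimises the integrated squared jerk of the movement.
Reaching movements of healthy adults are well described by this profile,
which is why it serves as the robot's reference motion.

A :class:`Segment` is one of the point-to-point movements of the task: a
source, a target, the Euclidean length between them, and the four condition
labels under which the movement is executed (embedded vs. virtual target,
reach vs. return, direction relative to gravity, and the size of the
cross-body component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Point3",
    "Segment",
    "TrajectorySample",
    "mjt_position",
    "mjt_velocity",
    "sample_trajectory",
    "samples_to_arrays",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "GRAVITY_LABELS",
    "CROSS_BODY_LABELS",
]

GRAVITY_LABELS = frozenset({"against", "towards", "ground"})
CROSS_BODY_LABELS = frozenset({"small", "large"})

#: tolerance for the |target - source| == length consistency check
LENGTH_TOL = 1e-9


def _blend(s: float) -> float:
    """Quintic minimum-jerk blend sigma(s) = 10 s^3 - 15 s^4 + 6 s^5."""
    return s * s * s * (10.0 + s * (-15.0 + 6.0 * s))


def _blend_rate(s: float) -> float:
    """d sigma / d s = 30 s^2 (1 - s)^2."""
    return 30.0 * s * s * (1.0 - s) * (1.0 - s)


@dataclass(frozen=True)
class Point3:
    """A position in 3-D Cartesian space, metres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"Point3 coordinates must be finite, got {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Point3":
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.as_array() - other.as_array()))


@dataclass(frozen=True)
class Segment:
    """One point-to-point movement with its condition labels.

    ``source`` and ``target`` may be omitted when only the length and the
    condition labels are known (as in the published segment table); every
    geometric operation then requires endpoints to be attached first.
    """

    id: int
    length: float
    embedded: bool
    reach: bool
    gravity: str  # one of GRAVITY_LABELS
    cross_body: str  # one of CROSS_BODY_LABELS
    default_duration: float = 4.0
    source: Point3 | None = None
    target: Point3 | None = None

    def __post_init__(self) -> None:
        if int(self.id) != self.id or self.id < 1:
            raise ValueError(f"segment id must be a positive integer, got {self.id}")
        if not self.length > 0:
            raise ValueError(f"segment length must be positive, got {self.length}")
        if self.gravity not in GRAVITY_LABELS:
            raise ValueError(f"gravity must be one of {sorted(GRAVITY_LABELS)}, got {self.gravity!r}")
        if self.cross_body not in CROSS_BODY_LABELS:
            raise ValueError(f"cross_body must be one of {sorted(CROSS_BODY_LABELS)}, got {self.cross_body!r}")
        if not self.default_duration > 0:
            raise ValueError("default_duration must be positive")
        if (self.source is None) != (self.target is None):
            raise ValueError("source and target must be given together")
        if self.source is not None and self.target is not None:
            d = self.source.distance_to(self.target)
            if abs(d - self.length) > LENGTH_TOL:
                raise ValueError(
                    f"segment {self.id}: |target - source| = {d!r} does not match "
                    f"length = {self.length!r} within {LENGTH_TOL}"
                )

    @property
    def has_endpoints(self) -> bool:
        return self.source is not None

    def require_endpoints(self) -> tuple[Point3, Point3]:
        if self.source is None or self.target is None:
            raise ValueError(f"segment {self.id} has no endpoints attached")
        return self.source, self.target

    def direction(self) -> np.ndarray:
        """Unit vector from source to target."""
        a, b = self.require_endpoints()
        d = b.as_array() - a.as_array()
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class TrajectorySample:
    """One time-stamped position (and optionally velocity) on a path."""

    t: float
    position: Point3
    velocity: Point3 | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be non-negative, got {self.t}")


def mjt_position(source: Point3, target: Point3, duration: float, t: float) -> Point3:
    """Reference position at time ``t`` of a minimum-jerk movement.

    The path is the straight line from ``source`` to ``target``; progress
    along it follows the quintic blend. Endpoints are returned exactly so
    the interpolation invariants hold to the last bit.
    """
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if t < 0 or t > duration:
        raise ValueError(f"t = {t} outside [0, {duration}]")
    if t == 0:
        return source
    if t == duration:
        return target
    a = source.as_array()
    b = target.as_array()
    return Point3.from_array(a + (b - a) * _blend(t / duration))


def mjt_velocity(source: Point3, target: Point3, duration: float, t: float) -> Point3:
    """Analytic velocity of the minimum-jerk movement at time ``t``.

    The speed profile is ``30 s^2 (1-s)^2 * length / duration``; it is zero
    at both endpoints and peaks at 1.875 * length / duration at mid-movement.
    """
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if t < 0 or t > duration:
        raise ValueError(f"t = {t} outside [0, {duration}]")
    a = source.as_array()
    b = target.as_array()
    return Point3.from_array((b - a) * (_blend_rate(t / duration) / duration))


def _sample_times(duration: float, dt: float) -> np.ndarray:
    """Times 0, dt, 2dt, ... with the final sample forced exactly to duration."""
    n = int(math.floor(duration / dt + 1e-12))
    times = np.arange(n + 1, dtype=float) * dt
    if abs(times[-1] - duration) <= 1e-12 * max(1.0, duration):
        times[-1] = duration
    else:
        times = np.append(times, duration)
    return times


def sample_trajectory(segment: Segment, duration: float, dt: float) -> list[TrajectorySample]:
    """Sample the minimum-jerk reference for ``segment`` at interval ``dt``.

    Samples are taken at t = 0, dt, 2dt, ...; the final sample always lands
    exactly at ``duration`` so the endpoint invariants hold regardless of
    whether ``duration`` is a multiple of ``dt``.
    """
    source, target = segment.require_endpoints()
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt >= duration:
        raise ValueError(f"dt = {dt} must be smaller than duration = {duration}")
    return [
        TrajectorySample(
            t=float(t),
            position=mjt_position(source, target, duration, float(t)),
            velocity=mjt_velocity(source, target, duration, float(t)),
        )
        for t in _sample_times(duration, dt)
    ]


def samples_to_arrays(samples: Iterable[TrajectorySample]) -> tuple[np.ndarray, np.ndarray]:
    """Return (times, positions[N, 3]) arrays for a list of samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty trajectory")
    t = np.array([s.t for s in samples], dtype=float)
    pos = np.array([[s.position.x, s.position.y, s.position.z] for s in samples], dtype=float)
    return t, pos


def trajectory_to_frame(samples: Iterable[TrajectorySample]) -> pd.DataFrame:
    samples = list(samples)
    t, pos = samples_to_arrays(samples)
    frame = pd.DataFrame({"t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})
    if samples[0].velocity is not None:
        vel = np.array(
            [[s.velocity.x, s.velocity.y, s.velocity.z] for s in samples], dtype=float
        )
        frame["vx"], frame["vy"], frame["vz"] = vel[:, 0], vel[:, 1], vel[:, 2]
    return frame


def write_trajectory_csv(samples: Iterable[TrajectorySample], path) -> None:
    """Write samples as CSV with header ``t,x,y,z[,vx,vy,vz]`` (SI units)."""
    trajectory_to_frame(samples).to_csv(path, index=False)


def read_trajectory_csv(path) -> list[TrajectorySample]:
    frame = pd.read_csv(path)
    required = {"t", "x", "y", "z"}
    if not required.issubset(frame.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    has_vel = {"vx", "vy", "vz"}.issubset(frame.columns)
    out = []
    for row in frame.itertuples(index=False):
        vel = Point3(row.vx, row.vy, row.vz) if has_vel else None
        out.append(TrajectorySample(t=float(row.t), position=Point3(row.x, row.y, row.z), velocity=vel))
    return out
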