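"""Packaged table transcriptions and the CSV/config interfaces.

Five fixtures ship with the package, transcribed from the published study
tables: the cohort demographics, the per-iteration adaptation of segment
durations for one participant, the 13 segment definitions, the
dummy-coding reference scheme, and the interaction-model regression
coefficients. Content is pinned by SHA-256 checksum so a silently edited
fixture fails loudly.

Segment endpoints are not published; :func:`load_segments` synthesises a
chained set of 3-D endpoints whose Euclidean distances equal the published
lengths exactly and whose vertical direction matches each segment's gravity
label (up for against-gravity, down for towards-gravity, horizontal for
ground level). The lengths and condition labels are authoritative; the
coordinates are illustrative, which is sufficient because every metric in
the package depends only on source, target and length, never on absolute
placement.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trajectory import Point3, Segment

__all__ = [
    "FIXTURE_NAMES",
    "FixtureChecksumError",
    "ParticipantRecord",
    "CohortSummary",
    "load_fixture",
    "load_participants",
    "load_segments",
    "model2_coefficients",
    "cohort_summary",
]

_FILES = {
    "participants": "participants.csv",
    "table3_durations": "table3_durations.csv",
    "segments": "segments.csv",
    "coding_reference": "coding_reference.csv",
    "model2_coefficients": "model2_coefficients.csv",
}
FIXTURE_NAMES = tuple(_FILES)

_CHECKSUMS = {
    "participants": "4864429908965ce91762e22df5988385a504633677d788e350fd08be7f3f8604",
    "table3_durations": "0339a5e8b7cd188d05e0db57e97044443ec59fcca82a3e5cf9003ce8cc844543",
    "segments": "b08ee414f9e855f943f37b9ffbe2bf3befc9eab6d602d9746bfca11ae55aeb9b",
    "coding_reference": "fee3d6d2f7f4aa969011f9066de286689b0a08ff90b8c3f3fa5cb7f155f0dbd4",
    "model2_coefficients": "70ef44bf41fa754fcd827d9f816d9a524bb44fbbec799d28d2eb99f190a117e3",
}


class FixtureChecksumError(RuntimeError):
    """A packaged fixture does not match its pinned checksum."""


def _fixture_bytes(name: str) -> bytes:
    return (resources.files("reachadapt") / "data" / _FILES[name]).read_bytes()


def load_fixture(name: str, verify: bool = True) -> pd.DataFrame:
    """Load one packaged fixture as a DataFrame, verifying its checksum."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}")
    raw = _fixture_bytes(name)
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _CHECKSUMS[name]:
            raise FixtureChecksumError(
                f"fixture {name!r} checksum {digest} != pinned {_CHECKSUMS[name]}"
            )
    import io

    return pd.read_csv(io.BytesIO(raw))


@dataclass(frozen=True)
class ParticipantRecord:
    id: int
    age: float
    gender: str  # F or M
    dominant_hand: str  # R or L
    vision_correction: str  # Y or N
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be F or M, got {self.gender!r}")
        if self.dominant_hand not in ("R", "L"):
            raise ValueError(f"dominant_hand must be R or L, got {self.dominant_hand!r}")
        if self.vision_correction not in ("Y", "N"):
            raise ValueError(f"vision_correction must be Y or N, got {self.vision_correction!r}")


def load_participants(exclusions: Sequence[int] = ()) -> list[ParticipantRecord]:
    frame = load_fixture("participants")
    records = [
        ParticipantRecord(
            id=int(r.participant),
            age=float(r.age),
            gender=r.gender,
            dominant_hand=r.dominant_hand,
            vision_correction=r.vision_correction,
            excluded=int(r.participant) in set(exclusions),
        )
        for r in frame.itertuples(index=False)
    ]
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("participant ids are not unique")
    return records


class CohortSummary(NamedTuple):
    n_included: int
    mean_age: float
    sd_age: float


def cohort_summary(
    records: Iterable[ParticipantRecord],
    exclusions: Sequence[int] = (),
    sample_sd: bool = False,
) -> CohortSummary:
    """Included count after exclusions plus age mean and SD of ALL recruited.

    The age statistics describe the recruited cohort (the convention of the
    published demographics); the default SD uses divisor n (population
    form), ``sample_sd=True`` selects divisor n-1. Mean and SD are rounded
    to one decimal for reporting.
    """
    records = list(records)
    ids = {r.id for r in records}
    unknown = set(exclusions) - ids
    if unknown:
        raise ValueError(f"unknown exclusion ids: {sorted(unknown)}")
    ages = np.array([r.age for r in records], dtype=float)
    n_included = len(ids - set(exclusions))
    ddof = 1 if sample_sd else 0
    return CohortSummary(
        n_included=n_included,
        mean_age=round(float(ages.mean()), 1),
        sd_age=round(float(ages.std(ddof=ddof)), 1),
    )


_GRAVITY_FROM_LABEL = {
    "against gravity": "against",
    "towards gravity": "towards",
    "ground-level": "ground",
    "ground level": "ground",
}

#: elevation of the synthesised direction per gravity class, radians
_ELEVATION = {"ground": 0.0, "against": math.pi / 4, "towards": -math.pi / 4}


def _synthesize_endpoints(
    lengths: Sequence[float], gravities: Sequence[str]
) -> list[tuple[Point3, Point3]]:
    """Chain illustrative endpoints matching lengths and gravity classes."""
    p = np.zeros(3)
    pairs = []
    for i, (length, gravity) in enumerate(zip(lengths, gravities)):
        theta = 0.8 * i  # azimuth varies so the path spreads through space
        phi = _ELEVATION[gravity]
        u = np.array(
            [math.cos(phi) * math.cos(theta), math.cos(phi) * math.sin(theta), math.sin(phi)]
        )
        q = p + length * u
        pairs.append((Point3.from_array(p), Point3.from_array(q)))
        p = q
    return pairs


def load_segments(
    default_duration: float = 4.0, with_endpoints: bool = True
) -> list[Segment]:
    """The 13 segments with published lengths/labels and synthesised endpoints."""
    frame = load_fixture("segments")
    gravities = [_GRAVITY_FROM_LABEL[g.strip().lower()] for g in frame["gravity"]]
    lengths = frame["length_m"].astype(float).tolist()
    if with_endpoints:
        endpoints = _synthesize_endpoints(lengths, gravities)
    else:
        endpoints = [(None, None)] * len(frame)
    segments = []
    for row, gravity, (source, target) in zip(
        frame.itertuples(index=False), gravities, endpoints
    ):
        # lengths are authoritative: take |target - source| where endpoints
        # exist so the consistency invariant holds bit-exactly
        length = source.distance_to(target) if source is not None else float(row.length_m)
        segments.append(
            Segment(
                id=int(row.id),
                length=length,
                embedded=row.embedded.strip().lower() == "embedded",
                reach=row.reach.strip().lower() == "reach",
                gravity=gravity,
                cross_body=row.cross_body.strip().lower(),
                default_duration=default_duration,
                source=source,
                target=target,
            )
        )
    return segments


def model2_coefficients() -> dict[str, float]:
    """Published interaction-model coefficients as a term -> b mapping."""
    frame = load_fixture("model2_coefficients")
    return {str(r.term): float(r.b) for r in frame.itertuples(index=False)}
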