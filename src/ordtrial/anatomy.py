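"""Cervical segment bookkeeping for the ten upper-extremity key muscles.

Each body side carries five key muscles, one per spinal segment C5-T1,
ordered rostral to caudal.  A side's motor level (ML) partitions its
muscles into above-level (intact), at-level, and below-level (impaired)
groups; only below-level muscles enter the transitional model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

SEGMENTS: tuple[str, ...] = ("C5", "C6", "C7", "C8", "T1")
SEGMENT_RANK: dict[str, int] = {s: i for i, s in enumerate(SEGMENTS)}
SIDES: tuple[str, str] = ("left", "right")
N_MUSCLES = 10
MAX_SCORE = 5
N_CATEGORIES = 6


def segment_rank(label: str) -> int:
    """Rostral->caudal rank of a segment label (C5=0 ... T1=4)."""
    try:
        return SEGMENT_RANK[label]
    except KeyError:
        raise ValueError(f"unknown segment label: {label!r}") from None


@dataclass(frozen=True, order=True)
class Constellation:
    """Left/right motor-level pair.  (T1, T1) is invalid: such participants
    have no below-level key muscles and are excluded everywhere."""

    left_ml: str
    right_ml: str

    def __post_init__(self) -> None:
        segment_rank(self.left_ml)
        segment_rank(self.right_ml)
        if self.left_ml == "T1" and self.right_ml == "T1":
            raise ValueError("(T1, T1) is not a valid constellation")

    @property
    def label(self) -> str:
        return f"{self.left_ml}/{self.right_ml}"

    @classmethod
    def from_label(cls, label: str) -> "Constellation":
        left, _, right = label.partition("/")
        return cls(left, right)

    def ml(self, side: str) -> str:
        if side == "left":
            return self.left_ml
        if side == "right":
            return self.right_ml
        raise ValueError(f"unknown side: {side!r}")


def valid_constellations() -> list[Constellation]:
    """All 24 admissible left/right ML pairs (5x5 minus (T1,T1))."""
    out = []
    for left in SEGMENTS:
        for right in SEGMENTS:
            if left == "T1" and right == "T1":
                continue
            out.append(Constellation(left, right))
    return out


@dataclass(frozen=True, order=True)
class LevCode:
    """Motor level x distance code for a below-level muscle.

    ``distance`` counts key muscles below the motor level, so it is
    negative: -1 is the first muscle below the level.  Valid codes number
    exactly ten (C5 x {-1..-4}, C6 x {-1..-3}, C7 x {-1,-2}, C8 x {-1});
    T1 has no muscles below it.  The reference code is (C5, -1).
    """

    motor_level: str
    distance: int

    def __post_init__(self) -> None:
        rank = segment_rank(self.motor_level)
        if self.motor_level == "T1":
            raise ValueError("no muscles below level: motor level T1")
        max_below = len(SEGMENTS) - 1 - rank
        if not -max_below <= self.distance <= -1:
            raise ValueError(
                f"invalid distance {self.distance} for motor level {self.motor_level}"
            )

    @property
    def label(self) -> str:
        return f"{self.motor_level}.{self.distance}"

    @classmethod
    def from_label(cls, label: str) -> "LevCode":
        ml, _, dist = label.partition(".")
        return cls(ml, int(dist))


REFERENCE_LEV = LevCode("C5", -1)


def lev_code(motor_level: str, segment: str) -> LevCode:
    """Code the position of ``segment`` relative to ``motor_level``.

    Raises for segments at or above the level and for motor level T1.
    """
    if motor_level == "T1":
        raise ValueError("no muscles below level: motor level T1")
    gap = segment_rank(segment) - segment_rank(motor_level)
    if gap <= 0:
        raise ValueError(
            f"not below level: segment {segment} is not caudal to motor level {motor_level}"
        )
    return LevCode(motor_level, -gap)


def all_lev_codes() -> list[LevCode]:
    """The ten valid codes in canonical order (by level, then distance)."""
    out = []
    for ml in SEGMENTS[:-1]:
        for seg in SEGMENTS[segment_rank(ml) + 1 :]:
            out.append(lev_code(ml, seg))
    return sorted(out, key=lambda c: (segment_rank(c.motor_level), -c.distance))


def below_level_segments(motor_level: str) -> Iterator[str]:
    """Segments strictly caudal to ``motor_level``, rostral->caudal."""
    yield from SEGMENTS[segment_rank(motor_level) + 1 :]


def muscle_index(side: str, segment: str) -> int:
    """Flat index into a 10-score vector ordered left C5..T1, right C5..T1."""
    if side not in SIDES:
        raise ValueError(f"unknown side: {side!r}")
    return SIDES.index(side) * 5 + segment_rank(segment)
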