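"""Two-arm randomized-trial simulator.

Participants are generated in five steps: draw a left/right motor-level
constellation, resample a baseline score vector from the matching pool,
allocate arms 1:1 (exact balance via a random permutation), draw the
at-level follow-up score from the per-segment frequency table, then walk
each side rostral-to-caudal sampling below-level follow-up scores from the
transitional model — each draw conditions on the muscle's own baseline
score and on the follow-up score just simulated for the muscle above.  The
treatment coefficient enters only for below-level muscles of treated
participants; above-level follow-up scores are always maximal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .anatomy import (
    MAX_SCORE,
    SEGMENTS,
    SIDES,
    Constellation,
    below_level_segments,
    lev_code,
    muscle_index,
    segment_rank,
)
from .ordinal import CoefficientSet, cumulative_probabilities
from .population import PopulationModel

__all__ = [
    "ParticipantRecord",
    "ScenarioSpec",
    "sample_motor_levels",
    "sample_baseline",
    "allocate_arms",
    "simulate_followup",
    "simulate_trial",
]

#: treatment-effect grid used in the power study: log odds ratios for
#: OR = 1.0, 1.1, ..., 1.5
DEFAULT_EFFECTS: tuple[float, ...] = tuple(math.log(1 + i / 10) for i in range(6))
DEFAULT_SIZES: tuple[int, ...] = (50, 75, 100, 125, 150, 175, 200)


@dataclass
class ParticipantRecord:
    id: str
    arm: int
    constellation: Constellation
    baseline: np.ndarray
    followup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=int)
        if self.followup is not None:
            self.followup = np.asarray(self.followup, dtype=int)


@dataclass
class ScenarioSpec:
    n_total: int
    beta_trt: float = 0.0
    n_replications: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")


def sample_motor_levels(
    pop: PopulationModel, n: int, rng: np.random.Generator
) -> list[Constellation]:
    """n i.i.d. constellation draws from the population frequency table."""
    cons = pop.constellations
    probs = np.array([pop.constellation_freq[c] for c in cons])
    idx = rng.choice(len(cons), size=n, p=probs)
    return [cons[i] for i in idx]


def sample_baseline(
    pop: PopulationModel, constellation: Constellation, rng: np.random.Generator
) -> np.ndarray:
    """Resample one baseline vector, with replacement, from the pool."""
    pool = pop.baseline_pool.get(constellation)
    if pool is None or len(pool) == 0:
        raise ValueError(f"empty baseline pool for constellation {constellation.label}")
    return pool[rng.integers(len(pool))].copy()


def allocate_arms(n: int, rng: np.random.Generator) -> np.ndarray:
    """1:1 allocation with exact balance: floor(n/2) treated, rest control,
    in random order."""
    if n < 2:
        raise ValueError("need at least 2 participants")
    arms = np.zeros(n, dtype=int)
    arms[: n // 2] = 1
    rng.shuffle(arms)
    return arms


class _TransitionTable:
    """Cached cumulative probabilities P(Y<=k) indexed by
    (lev, y_base, y_auto, arm); avoids per-draw dict lookups."""

    def __init__(self, coeffs: CoefficientSet, beta_trt: float):
        self._cum: dict[tuple, np.ndarray] = {}
        self._coeffs = coeffs
        self._beta_trt = beta_trt

    def cumulative(self, lev, y_base: int, y_auto: int, arm: int) -> np.ndarray:
        key = (lev, y_base, y_auto, arm)
        cum = self._cum.get(key)
        if cum is None:
            eta_trt = self._beta_trt * arm
            base = cumulative_probabilities(self._coeffs, lev, y_base, y_auto, 0)
            if eta_trt:
                cum = np.append(expit(logit(base[:-1]) - eta_trt), 1.0)
            else:
                cum = base
            self._cum[key] = cum
        return cum


def simulate_followup(
    pop: PopulationModel,
    record: ParticipantRecord,
    beta_trt: float,
    rng: np.random.Generator,
    _table: _TransitionTable | None = None,
) -> ParticipantRecord:
    """Fill in the 10 follow-up scores of ``record`` (returns it mutated)."""
    table = _table if _table is not None else _TransitionTable(pop.coefficients, beta_trt)
    fu = np.empty(10, dtype=int)
    at_cum = {seg: np.cumsum(pop.at_ml_freq[seg]) for seg in SEGMENTS}
    for side in SIDES:
        ml = record.constellation.ml(side)
        rank = segment_rank(ml)
        for seg in SEGMENTS[:rank]:
            fu[muscle_index(side, seg)] = MAX_SCORE
        at_idx = muscle_index(side, ml)
        fu[at_idx] = int(np.searchsorted(at_cum[ml], rng.random(), side="right"))
        prev = fu[at_idx]
        for seg in below_level_segments(ml):
            idx = muscle_index(side, seg)
            cum = table.cumulative(
                lev_code(ml, seg), int(record.baseline[idx]), int(prev), record.arm
            )
            fu[idx] = int(np.searchsorted(cum, rng.random(), side="right"))
            prev = fu[idx]
    record.followup = fu
    return record


def simulate_trial(
    pop: PopulationModel,
    n_total: int,
    beta_trt: float,
    rng: np.random.Generator,
) -> list[ParticipantRecord]:
    """One complete two-arm trial of ``n_total`` participants."""
    constellations = sample_motor_levels(pop, n_total, rng)
    arms = allocate_arms(n_total, rng)
    table = _TransitionTable(pop.coefficients, beta_trt)
    records = []
    for i, (c, arm) in enumerate(zip(constellations, arms)):
        rec = ParticipantRecord(
            id=f"p{i + 1:04d}",
            arm=int(arm),
            constellation=c,
            baseline=sample_baseline(pop, c, rng),
        )
        records.append(simulate_followup(pop, rec, beta_trt, rng, _table=table))
    return records
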