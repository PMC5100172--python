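"""Reference-population summaries that drive the trial simulator.

A :class:`PopulationModel` carries everything needed to simulate a cohort:
the left/right motor-level constellation frequencies, per-constellation
pools of observed baseline score vectors (resampled with replacement), the
follow-up score distribution of the muscle *at* the motor level for each
segment, and the coefficients of the spontaneous-recovery model (no
treatment term).

Because the observational cohort that parameterized the original study is
not distributable, :func:`make_synthetic_population` builds a qualitatively
faithful stand-in: follow-up scores decrease stochastically with distance
below the motor level, and on average exceed baseline (spontaneous
recovery).  :func:`estimate_population_from_cohort` recovers a
PopulationModel from any wide-format cohort, e.g. one simulated from a
known model (round-trip testing) or supplied by a user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import (
    MAX_SCORE,
    N_CATEGORIES,
    SEGMENTS,
    SIDES,
    Constellation,
    LevCode,
    below_level_segments,
    muscle_index,
    segment_rank,
    valid_constellations,
)
from .ordinal import CoefficientSet, build_transitional_rows, fit_proportional_odds

_PROB_TOL = 1e-12


@dataclass
class PopulationModel:
    """Everything the simulator needs, with validated probability tables."""

    constellation_freq: dict[Constellation, float]
    baseline_pool: dict[Constellation, np.ndarray]  # (pool_size, 10) int arrays
    at_ml_freq: dict[str, np.ndarray]  # segment -> 6 follow-up probabilities
    coefficients: CoefficientSet

    def __post_init__(self) -> None:
        total = sum(self.constellation_freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"constellation_freq sums to {total}, not 1")
        if any(p < 0 for p in self.constellation_freq.values()):
            raise ValueError("constellation_freq contains negative probability")
        # renormalize exactly; Constellation itself forbids (T1,T1)
        self.constellation_freq = {c: p / total for c, p in self.constellation_freq.items()}
        for seg in SEGMENTS:
            if seg not in self.at_ml_freq:
                raise ValueError(f"at_ml_freq missing segment {seg}")
            v = np.asarray(self.at_ml_freq[seg], dtype=float)
            if v.shape != (N_CATEGORIES,) or np.any(v < 0) or v.sum() <= 0:
                raise ValueError(f"at_ml_freq[{seg}] is not a valid probability vector")
            self.at_ml_freq[seg] = v / v.sum()
        for c, pool in self.baseline_pool.items():
            pool = np.asarray(pool, dtype=int)
            if pool.ndim != 2 or pool.shape[1] != 10 or pool.shape[0] == 0:
                raise ValueError(f"baseline_pool[{c.label}] must be a non-empty (m,10) array")
            if pool.min() < 0 or pool.max() > MAX_SCORE:
                raise ValueError(f"baseline_pool[{c.label}] has scores outside 0..{MAX_SCORE}")
            self.baseline_pool[c] = pool

    @property
    def constellations(self) -> list[Constellation]:
        return sorted(self.constellation_freq)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

#: Marginal per-side motor-level weights; the joint constellation weight is
#: the product, with (T1,T1) removed and the rest renormalized.
DEFAULT_CONFIG: dict = {
    "segment_weights": {"C5": 0.30, "C6": 0.25, "C7": 0.20, "C8": 0.15, "T1": 0.10},
    "constellation_weights": None,  # explicit map "C5/C6" -> weight overrides the marginals
    "at_ml_weights": {
        "C5": [0.06, 0.12, 0.18, 0.26, 0.22, 0.16],
        "C6": [0.07, 0.13, 0.19, 0.25, 0.21, 0.15],
        "C7": [0.08, 0.14, 0.20, 0.24, 0.20, 0.14],
        "C8": [0.09, 0.15, 0.21, 0.23, 0.19, 0.13],
        "T1": [0.10, 0.16, 0.22, 0.22, 0.18, 0.12],
    },
    # baseline severity below the level: score s at distance d gets weight
    # exp(-s * (decay_base + decay_slope * (|d| - 1)))
    "baseline_decay_base": 0.20,
    "baseline_decay_slope": 0.15,
    "at_ml_baseline_weights": [0.10, 0.20, 0.25, 0.20, 0.15, 0.10],
    "baseline_pool_size": 60,
    "coefficients": {
        "cutpoints": [-1.5, -0.4, 0.6, 1.6, 2.7],
        # per extra muscle of distance below the level (distance -1 = 0)
        "lev_distance_step": -0.5,
        # per rank of the motor level itself (C5 = 0)
        "lev_level_step": -0.1,
        "base": [0.4, 0.8, 1.2, 1.5, 1.8],  # levels 1..5
        "auto": [0.5, 0.9, 1.3, 1.7, 2.1],  # levels 1..5
    },
}


def _merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if config:
        for k, v in config.items():
            if k not in merged:
                raise ValueError(f"unknown population config key: {k!r}")
            if isinstance(merged.get(k), dict) and isinstance(v, dict) and k != "constellation_weights":
                merged[k].update(v)
            else:
                merged[k] = v
    return merged


def _constellation_table(cfg: dict) -> dict[Constellation, float]:
    if cfg.get("constellation_weights"):
        weights = {
            Constellation.from_label(lbl): float(w)
            for lbl, w in cfg["constellation_weights"].items()
        }
    else:
        seg_w = cfg["segment_weights"]
        for seg, w in seg_w.items():
            if w < 0:
                raise ValueError(f"segment_weights[{seg}] is negative")
        weights = {
            c: seg_w[c.left_ml] * seg_w[c.right_ml] for c in valid_constellations()
        }
    bad = [c.label for c, w in weights.items() if w < 0]
    if bad:
        raise ValueError(f"negative constellation weight for {bad}")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("constellation_weights sum to zero")
    return {c: w / total for c, w in weights.items() if w > 0}


def default_coefficients(coeff_config: dict | None = None) -> CoefficientSet:
    """Spontaneous-recovery coefficients implied by a coefficient config."""
    c = dict(DEFAULT_CONFIG["coefficients"])
    if coeff_config:
        c.update(coeff_config)
    beta_lev: dict[LevCode, float] = {}
    for ml in SEGMENTS[:-1]:
        for seg in below_level_segments(ml):
            dist = -(segment_rank(seg) - segment_rank(ml))
            code = LevCode(ml, dist)
            val = c["lev_distance_step"] * (-dist - 1) + c["lev_level_step"] * segment_rank(ml)
            beta_lev[code] = 0.0 if code == LevCode("C5", -1) else val
    return CoefficientSet(
        cutpoints=np.asarray(c["cutpoints"], dtype=float),
        beta_lev=beta_lev,
        beta_base={i + 1: float(v) for i, v in enumerate(c["base"])},
        beta_auto={i + 1: float(v) for i, v in enumerate(c["auto"])},
        beta_trt=0.0,
    )


def _baseline_score_probs(distance: int, cfg: dict) -> np.ndarray:
    lam = cfg["baseline_decay_base"] + cfg["baseline_decay_slope"] * (-distance - 1)
    w = np.exp(-lam * np.arange(N_CATEGORIES))
    return w / w.sum()


def _sample_baseline_vector(c: Constellation, cfg: dict, rng: np.random.Generator) -> np.ndarray:
    """One synthetic 10-score baseline: 5 above level, config-driven at level,
    decaying with distance below."""
    vec = np.zeros(10, dtype=int)
    at_w = np.asarray(cfg["at_ml_baseline_weights"], dtype=float)
    at_w = at_w / at_w.sum()
    for side in SIDES:
        ml = c.ml(side)
        rank = segment_rank(ml)
        for seg in SEGMENTS:
            idx = muscle_index(side, seg)
            gap = segment_rank(seg) - rank
            if gap < 0:
                vec[idx] = MAX_SCORE
            elif gap == 0:
                vec[idx] = rng.choice(N_CATEGORIES, p=at_w)
            else:
                vec[idx] = rng.choice(N_CATEGORIES, p=_baseline_score_probs(-gap, cfg))
    return vec


def make_synthetic_population(config: dict | None = None, seed: int = 0) -> PopulationModel:
    """Build a fully specified synthetic PopulationModel.

    Deterministic given (config, seed).  Constellation frequencies and
    at-level follow-up frequencies come straight from the config (no noise);
    baseline pools are drawn stochastically from the configured severity
    profile.
    """
    cfg = _merge_config(config)
    rng = np.random.default_rng(seed)
    freq = _constellation_table(cfg)

    at_ml_freq = {}
    for seg in SEGMENTS:
        v = np.asarray(cfg["at_ml_weights"][seg], dtype=float)
        if v.shape != (N_CATEGORIES,) or np.any(v < 0) or v.sum() <= 0:
            raise ValueError(f"at_ml_weights[{seg}] is not a valid weight vector")
        at_ml_freq[seg] = v / v.sum()

    pool_size = int(cfg["baseline_pool_size"])
    if pool_size < 1:
        raise ValueError("baseline_pool_size must be >= 1")
    baseline_pool = {
        c: np.stack([_sample_baseline_vector(c, cfg, rng) for _ in range(pool_size)])
        for c in sorted(freq)
    }
    return PopulationModel(
        constellation_freq=freq,
        baseline_pool=baseline_pool,
        at_ml_freq=at_ml_freq,
        coefficients=default_coefficients(cfg["coefficients"]),
    )


# ---------------------------------------------------------------------------
# estimation from a cohort
# ---------------------------------------------------------------------------


def estimate_population_from_cohort(records) -> PopulationModel:
    """Empirical PopulationModel from participant records with both timepoints.

    Participants with both motor levels at T1 carry no below-level muscles
    and are excluded before every frequency computation.  Coefficients are
    the treatment-free proportional-odds fit to the cohort's transitional
    rows.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    kept = [
        r
        for r in records
        if not (r.constellation.left_ml == "T1" and r.constellation.right_ml == "T1")
    ]
    if not kept:
        raise ValueError("all participants have (T1,T1) motor levels; none contribute")

    n = len(kept)
    freq: dict[Constellation, float] = {}
    pools: dict[Constellation, list[np.ndarray]] = {}
    for r in kept:
        freq[r.constellation] = freq.get(r.constellation, 0.0) + 1.0 / n
        pools.setdefault(r.constellation, []).append(np.asarray(r.baseline, dtype=int))

    at_counts = {seg: np.zeros(N_CATEGORIES) for seg in SEGMENTS}
    for r in kept:
        fu = np.asarray(r.followup, dtype=int)
        for side in SIDES:
            ml = r.constellation.ml(side)
            at_counts[ml][fu[muscle_index(side, ml)]] += 1
    at_ml_freq = {}
    for seg, counts in at_counts.items():
        if counts.sum() == 0:
            # segment never a motor level in this cohort: fall back to uniform
            at_ml_freq[seg] = np.full(N_CATEGORIES, 1.0 / N_CATEGORIES)
        else:
            at_ml_freq[seg] = counts / counts.sum()

    rows = build_transitional_rows(kept)
    if rows["y_out"].nunique() < 2:
        raise ValueError("cohort has fewer than 2 outcome categories among below-level scores")
    fit = fit_proportional_odds(rows, include_treatment=False)
    return PopulationModel(
        constellation_freq=freq,
        baseline_pool={c: np.stack(v) for c, v in pools.items()},
        at_ml_freq=at_ml_freq,
        coefficients=fit.coefficients,
    )
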