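"""Monte-Carlo power study over a grid of trial sizes and treatment effects.

Each scenario simulates replicate trials, runs the six-test battery, and
reports per-method rejection fractions with Wilson score intervals.
Replicate r of a scenario uses an independent child RNG stream spawned from
the scenario seed, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .battery import METHODS, run_battery
from .ordinal import CoefficientSet, LevCode, predict_category_probabilities
from .population import PopulationModel
from .simulate import DEFAULT_EFFECTS, DEFAULT_SIZES, ScenarioSpec, simulate_trial

__all__ = [
    "PowerEstimate",
    "wilson_interval",
    "run_scenario",
    "run_grid",
    "grid_to_frame",
    "plot_score_shift",
    "plot_power_curves",
]

#: replicates at which a method's flagged replicates are dropped from the
#: power denominator rather than counted as non-rejections
FLAG_EXCLUSION_FRACTION = 0.01


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    # the boundary cases are exactly 0/1 analytically; avoid rounding dust
    low = 0.0 if successes == 0 else max(center - half, 0.0)
    high = 1.0 if successes == n else min(center + half, 1.0)
    return low, high


@dataclass
class PowerEstimate:
    scenario: ScenarioSpec
    method: str
    rejections: int
    replicates_used: int
    flagged: int = 0
    confidence: float = 0.95
    power: float = field(init=False)
    wilson_low: float = field(init=False)
    wilson_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.power = self.rejections / self.replicates_used
        self.wilson_low, self.wilson_high = wilson_interval(
            self.rejections, self.replicates_used, self.confidence
        )


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


def run_scenario(
    spec: ScenarioSpec,
    pop: PopulationModel,
    methods: tuple[str, ...] = METHODS,
    B: int = 1000,
    strata: str = "constellation",
    progress: bool = False,
) -> list[PowerEstimate]:
    """Estimate power of each method for one (n_total, beta_trt) scenario.

    A method rejects when p <= alpha.  Flagged replicates (failed fits,
    degenerate tests) count as non-rejections unless they exceed
    ``FLAG_EXCLUSION_FRACTION`` of replicates, in which case they are
    excluded from that method's denominator.
    """
    rejections = {m: 0 for m in methods}
    flagged = {m: 0 for m in methods}
    for r in range(spec.n_replications):
        rng = _replicate_rng(spec.seed, r)
        records = simulate_trial(pop, spec.n_total, spec.beta_trt, rng)
        results = run_battery(records, B=B, strata=strata, rng=rng)
        for res in results:
            if res.method not in rejections:
                continue
            if res.flagged or np.isnan(res.p_value):
                flagged[res.method] += 1
            elif res.p_value <= spec.alpha:
                rejections[res.method] += 1
        if progress and (r + 1) % 50 == 0:
            print(f"  replicate {r + 1}/{spec.n_replications}", flush=True)
    out = []
    for m in methods:
        n_used = spec.n_replications
        if flagged[m] > FLAG_EXCLUSION_FRACTION * spec.n_replications:
            n_used = spec.n_replications - flagged[m]
        n_used = max(n_used, 1)
        out.append(
            PowerEstimate(
                scenario=spec,
                method=m,
                rejections=rejections[m],
                replicates_used=n_used,
                flagged=flagged[m],
            )
        )
    return out


def default_grid() -> tuple[tuple[int, ...], tuple[float, ...]]:
    """The 7 trial sizes x 6 treatment effects of the reference design
    (42 scenarios)."""
    return DEFAULT_SIZES, DEFAULT_EFFECTS


def run_grid(
    sizes,
    effects,
    pop: PopulationModel,
    n_replications: int = 1000,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    strata: str = "constellation",
    progress: bool = False,
) -> list[PowerEstimate]:
    """Cartesian product of sizes x effects; each scenario gets its own
    child seed derived from the root seed."""
    sizes = list(sizes)
    effects = list(effects)
    if not sizes or not effects:
        raise ValueError("empty grid")
    estimates: list[PowerEstimate] = []
    for si, n in enumerate(sizes):
        for ei, eff in enumerate(effects):
            scen_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(si, ei)).generate_state(1)[0]
            )
            spec = ScenarioSpec(
                n_total=int(n),
                beta_trt=float(eff),
                n_replications=n_replications,
                alpha=alpha,
                seed=scen_seed,
            )
            if progress:
                print(f"scenario n={n} beta_trt={eff:.4f}", flush=True)
            estimates.extend(run_scenario(spec, pop, methods, B=B, strata=strata, progress=progress))
    return estimates


def grid_to_frame(estimates: list[PowerEstimate]) -> pd.DataFrame:
    """Long-format table: one row per scenario x method, mirroring the
    size / effect / OR / power / CI reporting layout."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "size": e.scenario.n_total,
                "effect": round(e.scenario.beta_trt, 4),
                "or": round(float(np.exp(e.scenario.beta_trt)), 4),
                "method": e.method,
                "power": e.power,
                "ci_lower": e.wilson_low,
                "ci_upper": e.wilson_high,
                "rejections": e.rejections,
                "replicates_used": e.replicates_used,
                "flagged": e.flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

#: covariate setting of the worked probability-shift example: a C8 key
#: muscle under motor level C5, baseline score 1, rostral follow-up score 3
DEFAULT_SHIFT_COVARIATES = {"lev": LevCode("C5", -3), "y_base": 1, "y_auto": 3}


def plot_score_shift(
    coeffs: CoefficientSet,
    beta_trt: float = float(np.log(1.3)),
    lev: LevCode | None = None,
    y_base: int = 1,
    y_auto: int = 3,
    out_path=None,
):
    """Two-panel bar chart of category probabilities, control vs treatment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lev = lev if lev is not None else DEFAULT_SHIFT_COVARIATES["lev"]
    shifted = CoefficientSet(
        cutpoints=coeffs.cutpoints.copy(),
        beta_lev=dict(coeffs.beta_lev),
        beta_base=dict(coeffs.beta_base),
        beta_auto=dict(coeffs.beta_auto),
        beta_trt=float(beta_trt),
    )
    p_ctrl = predict_category_probabilities(shifted, lev, y_base, y_auto, arm=0)
    p_trt = predict_category_probabilities(shifted, lev, y_base, y_auto, arm=1)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.6), sharey=True)
    for ax, probs, title in ((axes[0], p_ctrl, "control"), (axes[1], p_trt, "treatment")):
        ax.bar(range(6), probs, color="steelblue")
        ax.set_xlabel("motor score")
        ax.set_title(f"{title} (sum={probs.sum():.3f})")
    axes[0].set_ylabel("probability")
    fig.suptitle(
        f"lev={lev.label}, base={y_base}, auto={y_auto}, OR={np.exp(beta_trt):.2f}"
    )
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return p_ctrl, p_trt


def plot_power_curves(table: pd.DataFrame, out_path=None, effect: float | None = None):
    """Power vs trial size, one line per method, plus a method x (size,
    effect) heatmap when several effects are present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.copy()
    if effect is not None:
        df = df[np.isclose(df["effect"], round(effect, 4))]
    if df.empty:
        raise ValueError("no rows to plot after filtering")

    n_effects = df["effect"].nunique()
    fig, axes = plt.subplots(1, 2 if n_effects > 1 else 1, figsize=(10 if n_effects > 1 else 5, 4))
    ax0 = axes[0] if n_effects > 1 else axes
    line_eff = sorted(df["effect"].unique())[len(df["effect"].unique()) // 2]
    sub = df[np.isclose(df["effect"], line_eff)]
    for method, g in sub.groupby("method"):
        g = g.sort_values("size")
        ax0.plot(g["size"], g["power"], marker="o", label=method)
    ax0.set_xlabel("total trial size")
    ax0.set_ylabel("power")
    ax0.set_title(f"effect = {line_eff}")
    ax0.legend(fontsize=7)

    if n_effects > 1:
        piv = df[df["method"] == "transitional"].pivot_table(
            index="effect", columns="size", values="power"
        )
        im = axes[1].imshow(piv.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
        axes[1].set_xticks(range(len(piv.columns)), piv.columns)
        axes[1].set_yticks(range(len(piv.index)), piv.index)
        axes[1].set_xlabel("total trial size")
        axes[1].set_ylabel("effect")
        axes[1].set_title("transitional test power")
        fig.colorbar(im, ax=axes[1])
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
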