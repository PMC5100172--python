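"""Six treatment-effect tests for a two-arm trial on the 10-muscle endpoint.

Four summed-score approaches (Welch t-test on the follow-up total, Welch
t-test on the change from baseline, ANCOVA adjusting for the baseline
total, and their motor-level-stratified independence-test counterparts)
plus the transitional proportional-odds model with participant-level
permutation inference on its treatment coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ordinal import build_transitional_rows, encode_design, fit_proportional_odds

METHODS: tuple[str, ...] = (
    "t_test",
    "t_test_delta",
    "i_test",
    "i_test_delta",
    "ancova",
    "transitional",
)

__all__ = [
    "METHODS",
    "TestResult",
    "total_scores",
    "t_test_total",
    "ancova_total",
    "stratified_independence_test",
    "transitional_permutation_test",
    "run_battery",
]


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    estimate: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method label: {self.method!r}")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")

    @property
    def flagged(self) -> bool:
        return bool(self.detail.get("flags"))


def total_scores(records: Sequence) -> pd.DataFrame:
    """Per-participant totals: follow-up sum, baseline sum, and change."""
    out = []
    for rec in records:
        if rec.followup is None:
            continue
        y1 = int(np.sum(rec.baseline))
        y2 = int(np.sum(rec.followup))
        out.append((rec.id, rec.arm, rec.constellation.label, y1, y2, y2 - y1))
    return pd.DataFrame(
        out, columns=["participant_id", "arm", "constellation", "y_star_1", "y_star_2", "y_double_star"]
    )


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    df = getattr(res, "df", np.nan)
    return float(res.statistic), float(res.pvalue), float(df)


def t_test_total(records: Sequence, use_delta: bool = False) -> TestResult:
    """Two-sided Welch t-test on the total follow-up score (or its change
    from baseline)."""
    totals = total_scores(records)
    col = "y_double_star" if use_delta else "y_star_2"
    trt = totals.loc[totals.arm == 1, col].to_numpy(dtype=float)
    ctrl = totals.loc[totals.arm == 0, col].to_numpy(dtype=float)
    method = "t_test_delta" if use_delta else "t_test"
    detail: dict = {"n_trt": len(trt), "n_ctrl": len(ctrl)}
    if len(trt) < 2 or len(ctrl) < 2:
        detail["flags"] = ["insufficient_arm_size"]
        return TestResult(method, np.nan, np.nan, None, detail)
    if np.var(trt) == 0 and np.var(ctrl) == 0:
        if np.mean(trt) == np.mean(ctrl):
            return TestResult(method, 0.0, 1.0, 0.0, detail)
        detail["flags"] = ["zero_variance"]
        return TestResult(method, np.nan, np.nan, float(np.mean(trt) - np.mean(ctrl)), detail)
    t, p, df = _welch(trt, ctrl)
    detail["df"] = df
    return TestResult(method, t, p, float(np.mean(trt) - np.mean(ctrl)), detail)


def ancova_total(records: Sequence) -> TestResult:
    """OLS of the follow-up total on (intercept, arm, baseline total);
    two-sided t-test on the arm coefficient."""
    totals = total_scores(records)
    detail: dict = {"n_trt": int((totals.arm == 1).sum()), "n_ctrl": int((totals.arm == 0).sum())}
    if len(totals) < 4 or totals["y_star_1"].nunique() < 2:
        fallback = t_test_total(records, use_delta=False)
        fallback.detail["flags"] = fallback.detail.get("flags", []) + ["ancova_fallback_t_test"]
        fallback.method = "ancova"
        return fallback
    y = totals["y_star_2"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(totals)),
            totals["arm"].to_numpy(dtype=float),
            totals["y_star_1"].to_numpy(dtype=float),
        ]
    )
    XtX = X.T @ X
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    if dof <= 0:
        detail["flags"] = ["insufficient_dof"]
        return TestResult("ancova", np.nan, np.nan, None, detail)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0.0:
        stat, p = (0.0, 1.0) if coef[1] == 0 else (np.nan, np.nan)
        if np.isnan(p):
            detail["flags"] = ["degenerate_se"]
        return TestResult("ancova", stat, p, float(coef[1]), detail)
    t = float(coef[1]) / se
    p = float(2 * stats.t.sf(abs(t), dof))
    detail["df"] = dof
    return TestResult("ancova", t, p, float(coef[1]), detail)


def _stratum_moments(y: np.ndarray, n1: int) -> tuple[float, float]:
    """Conditional mean/variance of the treated-group sum under random
    reallocation of ``n1`` treated labels within the stratum."""
    n = len(y)
    ybar = float(np.mean(y))
    mean = n1 * ybar
    if n < 2:
        return mean, 0.0
    sigma2 = float(np.mean((y - ybar) ** 2))
    var = n1 * (n - n1) / (n - 1) * sigma2
    return mean, var


def stratified_independence_test(
    records: Sequence,
    use_delta: bool = False,
    strata: str = "constellation",
    mode: str = "asymptotic",
    rng: np.random.Generator | None = None,
    n_permutations: int = 10000,
) -> TestResult:
    """Conditional independence test of outcome vs arm, stratified by motor
    level.

    The linear statistic is the sum of outcomes in the treatment arm,
    accumulated within strata, standardized by its permutation mean and
    variance given stratum margins.  ``strata='constellation'`` blocks on
    the full left/right pair; ``'higher_level'`` on the more rostral side.
    Asymptotic mode refers Z to the standard normal; montecarlo mode
    permutes arms within strata.
    """
    totals = total_scores(records)
    col = "y_double_star" if use_delta else "y_star_2"
    method = "i_test_delta" if use_delta else "i_test"
    detail: dict = {"strata_rule": strata, "mode": mode}
    if strata == "constellation":
        labels = totals["constellation"]
    elif strata == "higher_level":
        labels = totals["constellation"].map(lambda s: min(s.split("/")))
    else:
        raise ValueError(f"unknown strata rule: {strata!r}")
    totals = totals.assign(stratum=labels.to_numpy())

    T = 0.0
    mean = 0.0
    var = 0.0
    inert = 0
    groups = []
    for _, g in totals.groupby("stratum"):
        y = g[col].to_numpy(dtype=float)
        arm = g["arm"].to_numpy(dtype=int)
        n1 = int(arm.sum())
        if n1 == 0 or n1 == len(g):
            inert += 1
            continue
        T += float(y[arm == 1].sum())
        m, v = _stratum_moments(y, n1)
        mean += m
        var += v
        groups.append((y, n1))
    detail["n_strata"] = int(totals["stratum"].nunique())
    detail["inert_strata"] = inert
    if var <= 0:
        detail["flags"] = ["degenerate_variance"]
        stat = 0.0 if T == mean else np.nan
        return TestResult(method, stat, 1.0 if T == mean else np.nan, None, detail)
    z = (T - mean) / np.sqrt(var)

    if mode == "asymptotic":
        p = float(2 * stats.norm.sf(abs(z)))
    elif mode == "montecarlo":
        if rng is None:
            rng = np.random.default_rng()
        obs = abs(T - mean)
        hits = 0
        for _ in range(n_permutations):
            t_perm = 0.0
            for y, n1 in groups:
                t_perm += float(y[rng.permutation(len(y))[:n1]].sum())
            if abs(t_perm - mean) >= obs - 1e-12:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
        detail["permutations"] = n_permutations
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return TestResult(method, float(z), p, float(T - mean), detail)


def transitional_permutation_test(
    records: Sequence,
    B: int = 1000,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Permutation test of the transitional model's treatment coefficient.

    The observed model is refit ``B`` times with arm labels permuted across
    participants (all rows of a participant move together, respecting the
    hierarchical structure); p = (1 + #{|beta*| >= |beta_hat|}) / (B + 1).
    Permutation refits start from the observed optimum, which does not
    change the optimum reached, only the time to reach it.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = build_transitional_rows(records)
    detail: dict = {"B": B, "n_rows": int(len(rows))}
    if len(rows) == 0 or rows.loc[rows.arm == 1].empty or rows.loc[rows.arm == 0].empty:
        detail["flags"] = ["no_rows_in_arm"]
        return TestResult("transitional", np.nan, np.nan, None, detail)
    try:
        design = encode_design(rows, include_treatment=True)
    except ValueError as exc:
        detail["flags"] = [str(exc)]
        return TestResult("transitional", np.nan, np.nan, None, detail)

    fit = fit_proportional_odds(rows, design=design)
    beta_hat = fit.coefficients.beta_trt
    detail["converged"] = fit.converged
    detail["log_likelihood"] = fit.log_likelihood
    if not fit.converged or fit.separation:
        detail["flags"] = ["observed_fit_failed" if not fit.converged else "separation"]
        return TestResult("transitional", np.nan, np.nan, float(beta_hat), detail)

    # participant -> row mapping so permuted labels move whole participants
    pid = rows["participant_id"].to_numpy()
    unique_ids, row_of = np.unique(pid, return_inverse=True)
    arm_by_id = rows.groupby("participant_id")["arm"].first()
    arms = arm_by_id.loc[unique_ids].to_numpy(dtype=float)
    tcol = design.treatment_column

    hits = 0
    failed = 0
    # permuted optima have treatment coefficient near zero; start there
    warm = fit.theta_.copy()
    if "trt" in fit.labels_:
        warm[5 + fit.labels_.index("trt")] = 0.0
    refit_opts = {"gtol": 1e-3, "ftol": 1e-10}
    for _ in range(B):
        design.X[:, tcol] = arms[rng.permutation(len(arms))][row_of]
        refit = fit_proportional_odds(rows, design=design, warm_start=warm, options=refit_opts)
        if not refit.converged:
            failed += 1
            continue
        if abs(refit.coefficients.beta_trt) >= abs(beta_hat) - 1e-12:
            hits += 1
    design.X[:, tcol] = rows["arm"].to_numpy(dtype=float)  # restore
    used = B - failed
    detail["permutations_used"] = used
    detail["failed_refits"] = failed
    if failed > 0.05 * B:
        detail["flags"] = ["excess_failed_refits"]
    if used == 0:
        detail["flags"] = detail.get("flags", []) + ["no_successful_refits"]
        return TestResult("transitional", np.nan, np.nan, float(beta_hat), detail)
    p = (1 + hits) / (used + 1)
    return TestResult("transitional", float(beta_hat), p, float(beta_hat), detail)


def run_battery(
    records: Sequence,
    B: int = 1000,
    strata: str = "constellation",
    i_test_mode: str = "asymptotic",
    rng: np.random.Generator | None = None,
) -> list[TestResult]:
    """All six tests, in the fixed order t_test, t_test_delta, i_test,
    i_test_delta, ancova, transitional.  Per-test failures are flagged in
    the result, never raised."""
    if rng is None:
        rng = np.random.default_rng()
    return [
        t_test_total(records, use_delta=False),
        t_test_total(records, use_delta=True),
        stratified_independence_test(records, use_delta=False, strata=strata, mode=i_test_mode, rng=rng),
        stratified_independence_test(records, use_delta=True, strata=strata, mode=i_test_mode, rng=rng),
        ancova_total(records),
        transitional_permutation_test(records, B=B, rng=rng),
    ]
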