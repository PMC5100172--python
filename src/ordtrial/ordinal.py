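"""Cumulative-logit proportional-odds engine with an autoregressive term.

The model for a below-level key muscle's follow-up score Y in {0..5} is

    logit P(Y <= k) = alpha_{k+1} - eta,      k = 0..4,
    eta = beta_lev[lev] + beta_base[y_base] + beta_auto[y_auto] + beta_trt * arm,

with five strictly increasing cutpoints alpha_1 < ... < alpha_5.  Under this
sign convention a positive slope shifts probability mass toward higher
outcome categories; in particular a positive treatment coefficient means
stochastically better recovery in the treatment arm, and exp(beta_trt) is the
conditional odds ratio of exceeding any given score.

Note: some descriptions write the linear predictor with a plus sign inside
logit P(Y <= k); taken literally that would make a positive treatment
coefficient favour *lower* scores.  We fix the minus convention throughout so
that reported odds ratios > 1 always mean benefit.

Factor coding: ``y_base`` and ``y_auto`` enter as dummy indicators against
reference level 0, and the 10-level motor-level/distance factor against
reference (C5, -1).  The maximized likelihood is invariant to any full-rank
recoding, so this choice is one of bookkeeping, not substance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .anatomy import (
    MAX_SCORE,
    N_CATEGORIES,
    REFERENCE_LEV,
    SIDES,
    LevCode,
    all_lev_codes,
    below_level_segments,
    lev_code,
    muscle_index,
)

N_CUTPOINTS = N_CATEGORIES - 1

__all__ = [
    "CoefficientSet",
    "FitResult",
    "build_transitional_rows",
    "encode_design",
    "neg_log_likelihood",
    "fit_proportional_odds",
    "predict_category_probabilities",
    "sample_score",
]


# ---------------------------------------------------------------------------
# coefficient container
# ---------------------------------------------------------------------------


@dataclass
class CoefficientSet:
    """Parameters of the transitional model.

    ``cutpoints`` are the five ordered intercepts; the slope maps omit their
    reference levels (lev (C5,-1), score level 0), which are fixed at zero.
    """

    cutpoints: np.ndarray
    beta_lev: dict[LevCode, float] = field(default_factory=dict)
    beta_base: dict[int, float] = field(default_factory=dict)
    beta_auto: dict[int, float] = field(default_factory=dict)
    beta_trt: float = 0.0

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.shape != (N_CUTPOINTS,):
            raise ValueError(f"expected {N_CUTPOINTS} cutpoints, got {self.cutpoints.shape}")
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if self.beta_lev.get(REFERENCE_LEV, 0.0) != 0.0:
            raise ValueError("reference lev code (C5,-1) must have coefficient 0")
        for name, m in (("beta_base", self.beta_base), ("beta_auto", self.beta_auto)):
            if m.get(0, 0.0) != 0.0:
                raise ValueError(f"{name} level 0 is the reference and must be 0")

    def linear_predictor(self, lev: LevCode, y_base: int, y_auto: int, arm: int) -> float:
        return (
            self.beta_lev.get(lev, 0.0)
            + self.beta_base.get(int(y_base), 0.0)
            + self.beta_auto.get(int(y_auto), 0.0)
            + self.beta_trt * int(arm)
        )

    def odds_ratio(self) -> float:
        """Conditional odds ratio between arms, exp(beta_trt)."""
        return float(np.exp(self.beta_trt))

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict[str, float | list[float]] = {
            "cutpoints": [float(a) for a in self.cutpoints],
            "trt": float(self.beta_trt),
        }
        for code, v in sorted(self.beta_lev.items()):
            out[f"lev:{code.label}"] = float(v)
        for lvl, v in sorted(self.beta_base.items()):
            out[f"base:{lvl}"] = float(v)
        for lvl, v in sorted(self.beta_auto.items()):
            out[f"auto:{lvl}"] = float(v)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        beta_lev, beta_base, beta_auto = {}, {}, {}
        for key, v in d.items():
            if key.startswith("lev:"):
                beta_lev[LevCode.from_label(key[4:])] = float(v)
            elif key.startswith("base:"):
                beta_base[int(key[5:])] = float(v)
            elif key.startswith("auto:"):
                beta_auto[int(key[5:])] = float(v)
        return cls(
            cutpoints=np.asarray(d["cutpoints"], dtype=float),
            beta_lev=beta_lev,
            beta_base=beta_base,
            beta_auto=beta_auto,
            beta_trt=float(d.get("trt", 0.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitResult:
    coefficients: CoefficientSet
    log_likelihood: float
    converged: bool
    n_rows: int
    dropped_levels: dict[str, list[str]] = field(default_factory=dict)
    separation: bool = False
    n_iter: int = 0


# ---------------------------------------------------------------------------
# long-format construction
# ---------------------------------------------------------------------------

ROW_COLUMNS = [
    "participant_id",
    "side",
    "segment",
    "motor_level",
    "lev",
    "y_base",
    "y_auto",
    "y_out",
    "arm",
]


def build_transitional_rows(records: Iterable) -> pd.DataFrame:
    """Expand participant records into one row per below-level key muscle.

    For the muscle at distance -1 the autoregressive covariate is the
    follow-up score of the at-level muscle; deeper muscles condition on the
    follow-up score of the muscle just rostral.  A side with motor level T1
    contributes no rows.
    """
    rows: list[tuple] = []
    for rec in records:
        base = np.asarray(rec.baseline, dtype=int)
        fu = np.asarray(rec.followup, dtype=int)
        if base.shape != (10,) or fu.shape != (10,):
            raise ValueError(f"participant {rec.id}: expected 10 baseline and follow-up scores")
        for arr in (base, fu):
            if arr.min() < 0 or arr.max() > MAX_SCORE:
                raise ValueError(f"participant {rec.id}: score outside 0..{MAX_SCORE}")
        for side in SIDES:
            ml = rec.constellation.ml(side)
            if ml == "T1":
                continue
            prev = fu[muscle_index(side, ml)]  # at-level follow-up
            for seg in below_level_segments(ml):
                idx = muscle_index(side, seg)
                code = lev_code(ml, seg)
                rows.append(
                    (rec.id, side, seg, ml, code, int(base[idx]), int(prev), int(fu[idx]), int(rec.arm))
                )
                prev = fu[idx]
    return pd.DataFrame(rows, columns=ROW_COLUMNS)


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Numeric design for the slope part of the model.

    ``X`` excludes the cutpoints; one column per non-reference observed
    factor level, plus a trailing treatment indicator when requested.
    """

    labels: list[str]
    X: np.ndarray
    y: np.ndarray
    dropped_levels: dict[str, list[str]]
    lev_reference: LevCode
    treatment_column: int | None


def encode_design(rows: pd.DataFrame, include_treatment: bool = False) -> DesignSpec:
    """Dummy-code the lev / baseline / autoregressive factors.

    Unobserved levels yield no column and are recorded in ``dropped_levels``.
    If the canonical reference (C5,-1) is absent, the first observed code in
    canonical order becomes the reference (recorded as a relabel).
    """
    if len(rows) == 0:
        raise ValueError("no rows to encode")
    y = rows["y_out"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("outcome degenerate: fewer than 2 observed categories")

    dropped: dict[str, list[str]] = {"lev": [], "y_base": [], "y_auto": []}
    labels: list[str] = []
    cols: list[np.ndarray] = []

    lev_values = rows["lev"].to_numpy()
    observed_lev = set(lev_values)
    canonical = all_lev_codes()
    dropped["lev"] = [c.label for c in canonical if c not in observed_lev]
    if REFERENCE_LEV in observed_lev:
        reference = REFERENCE_LEV
    else:
        reference = next(c for c in canonical if c in observed_lev)
        dropped["lev"].append(f"reference->{reference.label}")
    for code in canonical:
        if code == reference or code not in observed_lev:
            continue
        labels.append(f"lev:{code.label}")
        cols.append((lev_values == code).astype(float))

    for factor, key in (("y_base", "base"), ("y_auto", "auto")):
        vals = rows[factor].to_numpy(dtype=int)
        observed = set(np.unique(vals).tolist())
        dropped[factor] = [str(v) for v in range(1, MAX_SCORE + 1) if v not in observed]
        for lvl in range(1, MAX_SCORE + 1):
            if lvl in observed:
                labels.append(f"{key}:{lvl}")
                cols.append((vals == lvl).astype(float))

    treatment_column = None
    if include_treatment:
        treatment_column = len(labels)
        labels.append("trt")
        cols.append(rows["arm"].to_numpy(dtype=float))

    X = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    return DesignSpec(labels, X, y, dropped, reference, treatment_column)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _category_logprobs(alpha: np.ndarray, eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log P(Y = y_i | eta_i) for the cumulative-logit model."""
    # cumulative P(Y<=k) for k=0..4; P(Y<=5)=1, P(Y<=-1)=0
    z = alpha[None, :] - eta[:, None]  # (n, 5)
    cum = expit(z)
    upper = np.where(y < N_CUTPOINTS, cum[np.arange(len(y)), np.minimum(y, N_CUTPOINTS - 1)], 1.0)
    lower = np.where(y > 0, cum[np.arange(len(y)), np.maximum(y - 1, 0)], 0.0)
    p = upper - lower
    return np.log(np.clip(p, 1e-300, None))


def neg_log_likelihood(params: CoefficientSet, rows: pd.DataFrame) -> float:
    """-sum of row log-probabilities under ``params``.

    Works directly from the coefficient container (no design matrix), which
    makes it an independent check on the design-matrix likelihood used by
    the fitter.
    """
    eta = np.array(
        [
            params.linear_predictor(lev, yb, ya, arm)
            for lev, yb, ya, arm in zip(rows["lev"], rows["y_base"], rows["y_auto"], rows["arm"])
        ]
    )
    y = rows["y_out"].to_numpy(dtype=int)
    return float(-np.sum(_category_logprobs(params.cutpoints, eta, y)))


def _unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """theta = (alpha_1, log increments x4, slopes) -> (alpha, beta)."""
    alpha = np.empty(N_CUTPOINTS)
    alpha[0] = theta[0]
    alpha[1:] = theta[0] + np.cumsum(np.exp(theta[1:N_CUTPOINTS]))
    return alpha, theta[N_CUTPOINTS : N_CUTPOINTS + p]


def _pack(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    incr = np.diff(alpha)
    return np.concatenate(([alpha[0]], np.log(incr), beta))


class _Likelihood:
    """Negative log-likelihood and gradient in the working parameterization
    (free alpha_1, log-increments, slopes), with row-index arrays cached.

    Holds a *reference* to X, so callers may mutate columns in place (the
    permutation test swaps the treatment column) between calls.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y
        n = len(y)
        self._idx = np.arange(n)
        self._at_top = y == N_CUTPOINTS
        self._at_bottom = y == 0
        self._iu = np.minimum(y, N_CUTPOINTS - 1)
        self._il = np.maximum(y - 1, 0)

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        X, y = self.X, self.y
        n, p = X.shape
        alpha, beta = _unpack(theta, p)
        eta = X @ beta if p else np.zeros(n)
        z = alpha[None, :] - eta[:, None]
        cum = expit(z)  # (n, 5)
        f = cum * (1.0 - cum)  # logistic density at z

        upper = cum[self._idx, self._iu]
        upper[self._at_top] = 1.0
        lower = cum[self._idx, self._il]
        lower[self._at_bottom] = 0.0
        prob = np.clip(upper - lower, 1e-300, None)
        nll = -float(np.sum(np.log(prob)))

        inv_p = 1.0 / prob
        f_upper = f[self._idx, self._iu]
        f_upper[self._at_top] = 0.0
        f_lower = f[self._idx, self._il]
        f_lower[self._at_bottom] = 0.0

        # d nll / d alpha_j accumulated over rows
        g_alpha = np.bincount(self._iu, weights=-inv_p * f_upper, minlength=N_CUTPOINTS)
        g_alpha += np.bincount(self._il, weights=inv_p * f_lower, minlength=N_CUTPOINTS)

        # d nll / d eta_i, then chain to slopes
        d_eta = inv_p * (f_upper - f_lower)
        g_beta = X.T @ d_eta if p else np.empty(0)

        # chain alpha -> working parameters: alpha_j depends on increment m
        # for all j >= m
        g_theta = np.empty_like(theta)
        g_theta[0] = g_alpha.sum()
        tail = np.cumsum(g_alpha[::-1])[::-1]
        g_theta[1:N_CUTPOINTS] = tail[1:] * np.exp(theta[1:N_CUTPOINTS])
        g_theta[N_CUTPOINTS:] = g_beta
        return nll, g_theta


def _nll_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    return _Likelihood(X, y)(theta)


class _NaturalLikelihood:
    """NLL, gradient and Hessian in the natural parameterization
    (alpha_1..alpha_5, slopes).

    Each row's log-probability log(sigma(z_u) - sigma(z_l)) couples at most
    two *adjacent* cutpoints, so the alpha-block of the Hessian is
    tridiagonal; boundary categories (0 and 5) drop the corresponding
    sigmoid term entirely.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y
        n = len(y)
        self._idx = np.arange(n)
        self._at_top = y == N_CUTPOINTS
        self._at_bottom = y == 0
        self._iu = np.minimum(y, N_CUTPOINTS - 1)
        self._il = np.maximum(y - 1, 0)
        self._mid = (~self._at_top) & (~self._at_bottom)

    def nll(self, alpha: np.ndarray, beta: np.ndarray) -> float:
        X, y = self.X, self.y
        eta = X @ beta if X.shape[1] else np.zeros(len(y))
        su = expit(alpha[self._iu] - eta)
        su[self._at_top] = 1.0
        sl = expit(alpha[self._il] - eta)
        sl[self._at_bottom] = 0.0
        prob = np.clip(su - sl, 1e-300, None)
        return -float(np.sum(np.log(prob)))

    def nll_grad_hess(
        self, alpha: np.ndarray, beta: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        X = self.X
        n, p = X.shape
        iu, il = self._iu, self._il
        eta = X @ beta if p else np.zeros(n)

        su = expit(alpha[iu] - eta)
        su[self._at_top] = 1.0
        sl = expit(alpha[il] - eta)
        sl[self._at_bottom] = 0.0
        fu = su * (1.0 - su)
        fu[self._at_top] = 0.0
        fl = sl * (1.0 - sl)
        fl[self._at_bottom] = 0.0
        dfu = fu * (1.0 - 2.0 * su)  # d f / d z at upper cutpoint
        dfl = fl * (1.0 - 2.0 * sl)
        prob = np.clip(su - sl, 1e-300, None)
        nll = -float(np.sum(np.log(prob)))

        ip = 1.0 / prob
        ip2 = ip * ip

        # gradient of the *log-likelihood*; negate at the end
        g_alpha = np.bincount(iu, weights=fu * ip, minlength=N_CUTPOINTS)
        g_alpha -= np.bincount(il, weights=fl * ip, minlength=N_CUTPOINTS)
        d_eta = -(fu - fl) * ip
        g_beta = X.T @ d_eta if p else np.empty(0)

        # Hessian blocks (log-likelihood)
        h_uu = dfu * ip - fu * fu * ip2
        h_ll = -dfl * ip - fl * fl * ip2
        h_ul = fu * fl * ip2  # couples adjacent cutpoints, rows with 0<y<5
        h_ee = (dfu - dfl) * ip - (fu - fl) ** 2 * ip2
        h_ue = -dfu * ip + fu * (fu - fl) * ip2
        h_le = dfl * ip - fl * (fu - fl) * ip2

        k = N_CUTPOINTS
        H = np.zeros((k + p, k + p))
        diag = np.bincount(iu, weights=h_uu, minlength=k) + np.bincount(
            il, weights=h_ll, minlength=k
        )
        H[np.arange(k), np.arange(k)] = diag
        off = np.bincount(il[self._mid], weights=h_ul[self._mid], minlength=k)[: k - 1]
        H[np.arange(k - 1), np.arange(1, k)] = off
        H[np.arange(1, k), np.arange(k - 1)] = off
        if p:
            W = np.zeros((n, k))
            np.add.at(W, (self._idx, iu), h_ue)
            np.add.at(W, (self._idx, il), h_le)
            H[:k, k:] = W.T @ X
            H[k:, :k] = H[:k, k:].T
            H[k:, k:] = (X * h_ee[:, None]).T @ X
        grad = np.concatenate([g_alpha, g_beta])
        return nll, -grad, -H


def _newton_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha0: np.ndarray,
    beta0: np.ndarray,
    gtol: float,
    maxiter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Damped Newton on the natural parameters; keeps cutpoints ordered by
    step halving.  Returns (alpha, beta, nll, converged, n_iter)."""
    lik = _NaturalLikelihood(X, y)
    k = N_CUTPOINTS
    phi = np.concatenate([alpha0, beta0])
    nll, grad, H = lik.nll_grad_hess(phi[:k], phi[k:])
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(H)), -grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(40):
            cand = phi + scale * step
            if np.all(np.diff(cand[:k]) > 0):
                cand_nll = lik.nll(cand[:k], cand[k:])
                if cand_nll <= nll + 1e-12:
                    phi = cand
                    improved = True
                    break
            scale *= 0.5
        if not improved:
            break
        nll, grad, H = lik.nll_grad_hess(phi[:k], phi[k:])
    else:
        it = maxiter
    if not converged and np.max(np.abs(grad)) < gtol:
        converged = True
    return phi[:k], phi[k:], nll, converged, it


def _intercept_only_start(y: np.ndarray) -> np.ndarray:
    """Closed-form cutpoints from cumulative outcome frequencies."""
    counts = np.bincount(y, minlength=N_CATEGORIES).astype(float)
    # regularize so empty categories still give finite, ordered cutpoints
    counts += 0.5
    cumfreq = np.cumsum(counts)[:N_CUTPOINTS] / counts.sum()
    return logit(cumfreq)


def _full_rank_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    if X.shape[1] == 0:
        return np.empty(0, dtype=int)
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return np.sort(piv[:rank])


DEFAULT_OPTIONS = {"gtol": 1e-6, "maxiter": 500, "separation_threshold": 30.0}


def fit_proportional_odds(
    rows: pd.DataFrame,
    include_treatment: bool = False,
    options: Mapping | None = None,
    warm_start: np.ndarray | None = None,
    design: DesignSpec | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the cumulative-logit model.

    Cutpoints are optimized as (alpha_1, log successive increments) so the
    ordering constraint is built in; slopes are unconstrained.  Convergence
    is declared at gradient sup-norm below ``gtol``.  Non-convergence is
    reported via ``converged=False``, never an exception.  ``design`` lets
    callers reuse a precomputed encoding (the permutation test mutates only
    the treatment column); ``warm_start`` is a packed parameter vector.
    """
    opts = dict(DEFAULT_OPTIONS)
    if options:
        opts.update(options)
    spec = design if design is not None else encode_design(rows, include_treatment)
    X, y = spec.X, spec.y
    dropped = {k: list(v) for k, v in spec.dropped_levels.items()}

    keep = _full_rank_columns(X)
    if keep.size < X.shape[1]:
        removed = [spec.labels[j] for j in range(X.shape[1]) if j not in set(keep.tolist())]
        dropped["rank_deficient"] = removed
        labels = [spec.labels[j] for j in keep]
        X = X[:, keep]
    else:
        labels = list(spec.labels)

    p = X.shape[1]
    if warm_start is not None and warm_start.size == N_CUTPOINTS + p:
        theta0 = np.asarray(warm_start, dtype=float)
    else:
        theta0 = np.concatenate([
            np.array([_intercept_only_start(y)[0]]),
            np.log(np.clip(np.diff(_intercept_only_start(y)), 1e-3, None)),
            np.zeros(p),
        ])

    # absolute gradient tolerance, scaled mildly with the number of rows
    gtol = opts["gtol"] * max(1.0, len(y) / 100.0)
    alpha0, beta0 = _unpack(theta0, p)
    alpha, beta, nll, converged, n_iter = _newton_fit(
        X, y, alpha0, beta0, gtol=gtol, maxiter=opts["maxiter"]
    )
    if not converged:
        # damped Newton stalled (e.g. near-separation flattens the Hessian);
        # polish with quasi-Newton from wherever it stopped
        lik = _Likelihood(X, y)
        res = minimize(
            lik,
            _pack(alpha, beta),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": opts["maxiter"], "gtol": opts["gtol"], "ftol": 1e-12},
        )
        nll_res, grad = lik(res.x)
        if nll_res <= nll:
            alpha, beta = _unpack(res.x, p)
            nll = nll_res
        converged = bool(res.success) or float(np.max(np.abs(grad))) < gtol * 10
        n_iter += int(res.nit)
    beta_lev: dict[LevCode, float] = {}
    beta_base: dict[int, float] = {}
    beta_auto: dict[int, float] = {}
    beta_trt = 0.0
    for label, b in zip(labels, beta):
        kind, _, lvl = label.partition(":")
        if kind == "lev":
            beta_lev[LevCode.from_label(lvl)] = float(b)
        elif kind == "base":
            beta_base[int(lvl)] = float(b)
        elif kind == "auto":
            beta_auto[int(lvl)] = float(b)
        elif kind == "trt":
            beta_trt = float(b)
    coeffs = CoefficientSet(
        cutpoints=alpha,
        beta_lev=beta_lev,
        beta_base=beta_base,
        beta_auto=beta_auto,
        beta_trt=beta_trt,
    )
    separation = bool(p and np.max(np.abs(beta)) > opts["separation_threshold"])
    fit = FitResult(
        coefficients=coeffs,
        log_likelihood=float(-nll),
        converged=converged,
        n_rows=int(len(y)),
        dropped_levels=dropped,
        separation=separation,
        n_iter=int(n_iter),
    )
    fit.theta_ = _pack(alpha, beta)  # packed parameters, reusable as warm start
    fit.labels_ = labels  # slope labels matching theta_[5:]
    return fit


# ---------------------------------------------------------------------------
# prediction and sampling
# ---------------------------------------------------------------------------


def cumulative_probabilities(
    coeffs: CoefficientSet, lev: LevCode, y_base: int, y_auto: int, arm: int
) -> np.ndarray:
    """P(Y<=k) for k=0..5 (last entry exactly 1)."""
    eta = coeffs.linear_predictor(lev, y_base, y_auto, arm)
    cum = expit(coeffs.cutpoints - eta)
    return np.append(cum, 1.0)


def predict_category_probabilities(
    coeffs: CoefficientSet, lev: LevCode, y_base: int, y_auto: int, arm: int
) -> np.ndarray:
    """The six category probabilities at the given covariate setting."""
    cum = cumulative_probabilities(coeffs, lev, y_base, y_auto, arm)
    return np.diff(cum, prepend=0.0)


def sample_score(
    coeffs: CoefficientSet,
    lev: LevCode,
    y_base: int,
    y_auto: int,
    arm: int,
    rng: np.random.Generator,
) -> int:
    """Draw one outcome category; inverse-CDF so a single uniform suffices."""
    cum = cumulative_probabilities(coeffs, lev, y_base, y_auto, arm)
    return int(np.searchsorted(cum, rng.random(), side="right"))
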