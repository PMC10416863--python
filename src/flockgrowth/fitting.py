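"""Non-linear least-squares fitting of growth curves with goodness of fit.

The optimizer is a damped Gauss–Newton (Levenberg-style) iteration with
analytic Jacobians.  The iteration loop is first-class: accepted iterations
are counted and the residual-sum-of-squares trace is kept, because the
iteration count is itself a model-comparison metric for these curves (the
von Bertalanffy fit characteristically needs far more iterations than the
logistic or Gompertz–Laird fits on 35-d broiler data, whose asymptote lies
far beyond the observed ages).

Initialization is data-driven, since six-point weekly series are unforgiving
of poor starts: the logistic start linearizes logit(BW / W_A0) in age, the
Gompertz–Laird start regresses log growth increments, and the von
Bertalanffy start profiles a cube-root linearization over a small grid of
rate constants.

AIC/BIC use the Gaussian-likelihood form with the residual variance counted
as a parameter (p + 1): ``AIC = n ln(RSS/n) + 2(p+1)``.  Absolute values of
these criteria are convention-dependent; only differences between models
fitted to the same data are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import (
    GOMPERTZ_LAIRD,
    LOGISTIC,
    MODEL_TAGS,
    PARAM_CLASS,
    PARAM_NAMES,
    VON_BERTALANFFY,
    DerivedTraits,
    InflectionUndefinedError,
    Params,
    UnknownModelError,
    _curve,
    _jacobian,
    derive_traits,
)


class FitInputError(ValueError):
    """The series cannot be fitted (too few points, degenerate values...)."""


class GofError(ValueError):
    """Goodness-of-fit metrics are undefined for this input."""


@dataclass(frozen=True)
class GoodnessOfFit:
    r2: float
    rmse: float      # g
    aic: float
    aicc: float
    bic: float
    n_iter: int
    converged: bool


@dataclass
class FitResult:
    model: str
    params: Params
    derived: DerivedTraits | None
    gof: GoodnessOfFit
    residuals: np.ndarray       # observed - predicted, g
    ages: np.ndarray
    rss_trace: list[float]
    warnings: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.residuals)


def compute_gof(
    observed,
    predicted,
    p: int,
    n_iter: int = 1,
    converged: bool = True,
) -> GoodnessOfFit:
    """Goodness-of-fit for a fitted curve with ``p`` mean parameters.

    ``r2 = 1 - RSS/TSS`` (TSS about the mean), ``rmse = sqrt(RSS/n)``,
    ``aic = n ln(RSS/n) + 2(p+1)``, ``bic = n ln(RSS/n) + (p+1) ln(n)``,
    ``aicc = aic + 2(p+1)(p+2)/(n-p-2)`` (infinite when n <= p+2).
    A perfect fit (RSS = 0) sends the information criteria to -inf.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise GofError("observed and predicted must have equal length")
    n = obs.size
    if n <= p:
        raise GofError(f"need n > p to define fit metrics (n={n}, p={p})")
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise GofError("all observations equal: R2 undefined")
    r2 = 1.0 - rss / tss
    rmse = math.sqrt(rss / n)
    k = p + 1  # residual variance counted as a parameter
    if rss > 0.0:
        base = n * math.log(rss / n)
        aic = base + 2 * k
        bic = base + k * math.log(n)
    else:
        aic = bic = -math.inf
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n > p + 2 else math.inf
    return GoodnessOfFit(
        r2=r2, rmse=rmse, aic=aic, aicc=aicc, bic=bic,
        n_iter=n_iter, converged=converged,
    )


# ---------------------------------------------------------------------------
# initialization


def _linreg(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _init_logistic(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    w_a0 = 2.0 * float(np.max(y))
    diffs = np.diff(y) / np.diff(t)
    j = int(np.argmax(diffs))
    t_i0 = 0.5 * (t[j] + t[j + 1])  # midpoint of the steepest interval
    z = np.clip(y / w_a0, 1e-6, 1 - 1e-6)
    slope, intercept = _linreg(t, np.log(z / (1.0 - z)))
    k0 = max(slope, 1e-3)
    if slope > 0:
        t_i0 = -intercept / slope  # logit crosses 0 at the inflection
    return np.array([w_a0, k0, max(t_i0, 1.0)])


def _init_gompertz_laird(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    w_00 = max(float(y[0]), 1e-6)
    # d log(y)/dt = L exp(-K t): regress log increments at interval midpoints
    dlog = np.diff(np.log(y)) / np.diff(t)
    mid = 0.5 * (t[:-1] + t[1:])
    pos = dlog > 0
    if pos.sum() >= 2:
        slope, intercept = _linreg(mid[pos], np.log(dlog[pos]))
        k0 = max(-slope, 1e-3)
        l0 = max(math.exp(intercept), k0 * 1.5)
    else:
        k0, l0 = 0.05, 0.15
    return np.array([w_00, l0, k0])


def _init_von_bertalanffy(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    # cube-root linearization: y^(1/3) = A - (A B) exp(-K t); profile over K
    cbrt = np.cbrt(y)
    best = None
    for k0 in np.geomspace(0.005, 0.3, 24):
        x = np.exp(-k0 * t)
        slope, intercept = _linreg(x, cbrt)
        resid = cbrt - (intercept + slope * x)
        rss = float(resid @ resid)
        if intercept <= 0 or slope >= 0:
            continue
        if best is None or rss < best[0]:
            best = (rss, k0, intercept, slope)
    if best is None:
        w_a0 = (2.0 * float(np.max(y)))
        return np.array([w_a0, 0.9, 0.05])
    _, k0, a, s = best
    b0 = min(-s / a, 0.999)
    return np.array([a**3, b0, k0])


_INITIALIZERS = {
    LOGISTIC: _init_logistic,
    GOMPERTZ_LAIRD: _init_gompertz_laird,
    VON_BERTALANFFY: _init_von_bertalanffy,
}


# ---------------------------------------------------------------------------
# optimizer


def _levenberg_fit(
    model: str,
    t: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    max_iter: int,
    rss_tol: float,
    step_tol: float,
) -> tuple[np.ndarray, list[float], int, bool]:
    """Damped Gauss–Newton minimization of the residual sum of squares.

    Returns (theta, rss_trace, n_iter, converged).  Only steps that do not
    increase the RSS are accepted, so the trace is non-increasing; n_iter
    counts accepted iterations.
    """
    theta = theta0.astype(float).copy()
    r = y - _curve(model, theta, t)
    rss = float(r @ r)
    trace = [rss]
    lam = 1e-3
    n_iter = 0
    converged = False
    for _ in range(max_iter):
        jac = _jacobian(model, theta, t)
        grad = jac.T @ r
        hess = jac.T @ jac
        diag = np.diag(hess).copy()
        diag[diag <= 0] = 1e-12
        accepted = False
        step = np.zeros_like(theta)
        for _ in range(40):
            try:
                step = np.linalg.solve(hess + lam * np.diag(diag), grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + step
            pred = _curve(model, cand, t)
            if not np.all(np.isfinite(pred)):
                lam *= 10.0
                continue
            r_new = y - pred
            rss_new = float(r_new @ r_new)
            if rss_new <= rss:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        n_iter += 1
        drop = rss - rss_new
        theta, r, rss = cand, r_new, rss_new
        trace.append(rss)
        lam = max(lam / 10.0, 1e-14)
        rel_step = float(np.linalg.norm(step)) / max(float(np.linalg.norm(theta)), 1e-12)
        if drop <= rss_tol * max(rss, 1e-300) or rel_step < step_tol:
            converged = True
            break
    if n_iter == 0:
        n_iter = 1  # the initial evaluation counts as one (degenerate) iteration
    return theta, trace, n_iter, converged


def fit_model(
    ages,
    bw,
    model: str,
    max_iter: int = 500,
    rss_tol: float = 1e-10,
    step_tol: float = 1e-8,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit one growth model to a BW-versus-age series.

    Requires at least 4 distinct ages (3 mean parameters + 1 df) and
    positive body weights.  Convergence is declared when the relative RSS
    drop falls below ``rss_tol`` or the relative parameter step below
    ``step_tol``; non-convergence returns the best-so-far parameters with
    ``gof.converged = False``.  Inadmissible optima (e.g. Gompertz–Laird
    with L <= K) are flagged in ``warnings``, never clamped.
    """
    if model not in MODEL_TAGS:
        raise UnknownModelError(f"unknown model tag {model!r}")
    t = np.asarray(ages, dtype=float)
    y = np.asarray(bw, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise FitInputError("ages and bw must be equal-length 1-D series")
    if len(np.unique(t)) < 4:
        raise FitInputError("need at least 4 distinct ages to fit 3 parameters")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise FitInputError("body weights must be finite and positive")
    if np.ptp(y) == 0.0:
        raise FitInputError("degenerate data: all body weights equal")

    if theta0 is None:
        theta0 = _INITIALIZERS[model](t, y)
    theta, trace, n_iter, converged = _levenberg_fit(
        model, t, y, np.asarray(theta0, dtype=float), max_iter, rss_tol, step_tol
    )

    params = PARAM_CLASS[model](*theta)
    warnings: list[str] = []
    derived: DerivedTraits | None = None
    try:
        params.validate()
        derived = derive_traits(model, params)
    except InflectionUndefinedError as exc:
        warnings.append(f"inflection undefined at optimum: {exc}")
    except ValueError as exc:
        warnings.append(f"inadmissible optimum: {exc}")

    predicted = _curve(model, theta, t)
    gof = compute_gof(y, predicted, p=3, n_iter=n_iter, converged=converged)
    return FitResult(
        model=model,
        params=params,
        derived=derived,
        gof=gof,
        residuals=y - predicted,
        ages=t,
        rss_trace=trace,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# model comparison

#: comparison criteria: (gof attribute, True if higher is better)
_CRITERIA = (("r2", True), ("aic", False), ("bic", False), ("rmse", False), ("n_iter", False))


def compare_models(fits: list[FitResult]):
    """Rank fits of different models to the *same* data.

    The preferred model has the highest R2 and the lowest AIC, BIC, RMSE and
    iteration count.  Returns a DataFrame with one row per model: the metric
    values, per-criterion ranks (1 = best, ties share the mean rank) and a
    composite mean rank; rows are ordered best-first with ties broken by
    fewer iterations, then lower RMSE.
    """
    import pandas as pd
    from scipy.stats import rankdata

    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    n0 = fits[0].n_obs
    if any(f.n_obs != n0 for f in fits):
        raise ValueError("fits are not comparable: different data lengths")

    rows = []
    for f in fits:
        rows.append({
            "model": f.model,
            "r2": f.gof.r2,
            "aic": f.gof.aic,
            "bic": f.gof.bic,
            "rmse": f.gof.rmse,
            "n_iter": f.gof.n_iter,
            "converged": f.gof.converged,
        })
    df = pd.DataFrame(rows)
    rank_cols = []
    for attr, higher_better in _CRITERIA:
        vals = df[attr].to_numpy(dtype=float)
        ranks = rankdata(-vals if higher_better else vals)
        col = f"rank_{attr}"
        df[col] = ranks
        rank_cols.append(col)
    df["composite_rank"] = df[rank_cols].mean(axis=1)
    df["tie"] = df["composite_rank"].duplicated(keep=False) & (
        df.duplicated(subset=rank_cols, keep=False)
    )
    df = df.sort_values(
        ["composite_rank", "n_iter", "rmse"], kind="mergesort"
    ).reset_index(drop=True)
    return df
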