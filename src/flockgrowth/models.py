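"""Three-parameter growth curves and their inflection-point traits.

Implements the three sigmoid growth functions classically used for broiler
body weight, BW(t) in grams at age t in days:

* **logistic** — ``y = W_A / (1 + exp(-K (t - t_i)))`` with asymptotic
  weight ``W_A``, exponential growth rate ``K`` (per day) and age at the
  inflection point ``t_i`` (days).
* **Gompertz–Laird** — ``y = W_0 exp((L/K) (1 - exp(-K t)))`` with hatch
  weight ``W_0``, initial growth rate ``L`` and rate of exponential decay
  ``K``.
* **von Bertalanffy** — ``y = W_A (1 - B exp(-K t))^3`` with asymptote
  ``W_A``, integration constant ``B`` and maximum relative growth ``K``.

Derived traits follow the standard closed forms: the logistic inflection
weight is ``W_i = W_A / 2`` with maximum daily increment ``MI = K W_i / 2``;
von Bertalanffy has ``t_i = ln(3B)/K`` and ``W_i = W_A · 8/27``; the
Gompertz–Laird inflection age is ``t_i = ln(L/K)/K`` (natural log) with
asymptote ``W_A = W_0 exp(L/K)`` and ``W_i = W_A / e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LOGISTIC = "logistic"
GOMPERTZ_LAIRD = "gompertz_laird"
VON_BERTALANFFY = "von_bertalanffy"
MODEL_TAGS = (LOGISTIC, GOMPERTZ_LAIRD, VON_BERTALANFFY)


class UnknownModelError(ValueError):
    """Model tag is not one of MODEL_TAGS."""


class InvalidParamsError(ValueError):
    """Parameters violate the model's admissibility constraints."""


class InflectionUndefinedError(ValueError):
    """The parameter set places the inflection point at t <= 0 (no interior
    inflection): Gompertz–Laird needs L > K, von Bertalanffy needs 3B > 1."""


@dataclass(frozen=True)
class LogisticParams:
    w_a: float  # asymptotic BW, g
    k: float    # exponential growth rate, 1/d
    t_i: float  # age at inflection, d

    def validate(self) -> None:
        if not (self.w_a > 0 and self.k > 0 and self.t_i > 0):
            raise InvalidParamsError(f"logistic params out of domain: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_a, self.k, self.t_i], dtype=float)


@dataclass(frozen=True)
class GompertzLairdParams:
    w_0: float  # initial BW, g
    l: float    # initial growth rate, 1/d
    k: float    # rate of exponential decay, 1/d

    def validate(self) -> None:
        if not (self.w_0 > 0 and self.l > 0 and self.k > 0):
            raise InvalidParamsError(f"Gompertz-Laird params out of domain: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_0, self.l, self.k], dtype=float)


@dataclass(frozen=True)
class VonBertalanffyParams:
    w_a: float  # asymptotic BW, g
    b: float    # integration constant, dimensionless
    k: float    # maximum relative growth, 1/d

    def validate(self) -> None:
        if not (self.w_a > 0 and self.b > 0 and self.k > 0):
            raise InvalidParamsError(f"von Bertalanffy params out of domain: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_a, self.b, self.k], dtype=float)


Params = LogisticParams | GompertzLairdParams | VonBertalanffyParams

PARAM_CLASS = {
    LOGISTIC: LogisticParams,
    GOMPERTZ_LAIRD: GompertzLairdParams,
    VON_BERTALANFFY: VonBertalanffyParams,
}
PARAM_NAMES = {
    LOGISTIC: ("w_a", "k", "t_i"),
    GOMPERTZ_LAIRD: ("w_0", "l", "k"),
    VON_BERTALANFFY: ("w_a", "b", "k"),
}


@dataclass(frozen=True)
class DerivedTraits:
    """Inflection-point traits of a fitted curve.

    ``mi`` (maximum increment, g/d) is reported for the logistic model only,
    following the convention of broiler growth studies; the peak gain of the
    other models is available through :func:`predict_gain`.
    """

    model: str
    t_i: float   # age at inflection, d
    w_i: float   # BW at inflection, g
    w_a: float   # asymptotic BW, g
    mi: float | None = None  # maximum increment, g/d (logistic only)


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (3655/2 -> 1828)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _check_tag(model: str) -> None:
    if model not in MODEL_TAGS:
        raise UnknownModelError(f"unknown model tag {model!r}; expected one of {MODEL_TAGS}")


def _curve(model: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the model mean from a raw parameter vector (fit internals)."""
    if model == LOGISTIC:
        w_a, k, t_i = theta
        return w_a / (1.0 + np.exp(-k * (t - t_i)))
    if model == GOMPERTZ_LAIRD:
        w_0, l, k = theta
        return w_0 * np.exp((l / k) * (1.0 - np.exp(-k * t)))
    if model == VON_BERTALANFFY:
        w_a, b, k = theta
        return w_a * (1.0 - b * np.exp(-k * t)) ** 3
    raise UnknownModelError(model)


def _gain(model: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic dBW/dt from a raw parameter vector."""
    y = _curve(model, theta, t)
    if model == LOGISTIC:
        w_a, k, _ = theta
        return k * y * (1.0 - y / w_a)
    if model == GOMPERTZ_LAIRD:
        _, l, k = theta
        return y * l * np.exp(-k * t)
    if model == VON_BERTALANFFY:
        w_a, b, k = theta
        u = 1.0 - b * np.exp(-k * t)
        return 3.0 * w_a * u**2 * b * k * np.exp(-k * t)
    raise UnknownModelError(model)


def _jacobian(model: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(curve)/d(theta), shape (len(t), 3)."""
    if model == LOGISTIC:
        w_a, k, t_i = theta
        e = np.exp(-k * (t - t_i))
        denom = (1.0 + e) ** 2
        return np.column_stack([
            1.0 / (1.0 + e),
            w_a * e * (t - t_i) / denom,
            -w_a * e * k / denom,
        ])
    if model == GOMPERTZ_LAIRD:
        w_0, l, k = theta
        ekt = np.exp(-k * t)
        g = (1.0 - ekt) / k
        y = w_0 * np.exp(l * g)
        dg_dk = (t * ekt * k - (1.0 - ekt)) / k**2
        return np.column_stack([y / w_0, y * g, y * l * dg_dk])
    if model == VON_BERTALANFFY:
        w_a, b, k = theta
        ekt = np.exp(-k * t)
        u = 1.0 - b * ekt
        return np.column_stack([
            u**3,
            -3.0 * w_a * u**2 * ekt,
            3.0 * w_a * u**2 * b * t * ekt,
        ])
    raise UnknownModelError(model)


def predict_bw(model: str, params: Params, t):
    """Model mean body weight (g) at age(s) ``t`` (days)."""
    _check_tag(model)
    params.validate()
    t_arr = np.asarray(t, dtype=float)
    out = _curve(model, params.as_array(), t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def predict_gain(model: str, params: Params, t):
    """Analytic daily body-weight gain dBW/dt (g/d) at age(s) ``t``.

    For the logistic curve the maximum over t is ``K·W_A/4``, attained at
    ``t = t_i``.
    """
    _check_tag(model)
    params.validate()
    t_arr = np.asarray(t, dtype=float)
    out = _gain(model, params.as_array(), t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def derive_traits(model: str, params: Params) -> DerivedTraits:
    """Closed-form inflection-point traits for a parameter set.

    Raises :class:`InflectionUndefinedError` when the inflection age would
    not be positive (Gompertz–Laird with L <= K, von Bertalanffy with
    3B <= 1).
    """
    _check_tag(model)
    params.validate()
    if model == LOGISTIC:
        w_i = params.w_a / 2.0
        return DerivedTraits(
            model=model,
            t_i=params.t_i,
            w_i=w_i,
            w_a=params.w_a,
            mi=params.k * w_i / 2.0,
        )
    if model == GOMPERTZ_LAIRD:
        if params.l <= params.k:
            raise InflectionUndefinedError(
                f"Gompertz-Laird inflection needs L > K; got L={params.l}, K={params.k}"
            )
        w_a = params.w_0 * math.exp(params.l / params.k)
        return DerivedTraits(
            model=model,
            t_i=math.log(params.l / params.k) / params.k,
            w_i=w_a / math.e,
            w_a=w_a,
        )
    # von Bertalanffy
    if 3.0 * params.b <= 1.0:
        raise InflectionUndefinedError(
            f"von Bertalanffy inflection needs 3B > 1; got B={params.b}"
        )
    return DerivedTraits(
        model=model,
        t_i=math.log(3.0 * params.b) / params.k,
        w_i=params.w_a * 8.0 / 27.0,
        w_a=params.w_a,
    )


def find_crossover(
    params_a: Params,
    params_b: Params,
    model: str,
    quantity: str = "bw",
    window: tuple[float, float] = (0.0, 35.0),
    resolution: float = 0.01,
) -> float | None:
    """Smallest age in ``window`` where curve A minus curve B changes sign.

    ``quantity`` selects body weight (``"bw"``) or daily gain (``"gain"``).
    The bracket is found on a coarse scan and refined by bisection to
    ``resolution`` days; returns None when the difference keeps its sign on
    the whole window.
    """
    _check_tag(model)
    if quantity not in ("bw", "gain"):
        raise ValueError(f"quantity must be 'bw' or 'gain', got {quantity!r}")
    t_lo, t_hi = window
    if not t_hi > t_lo:
        raise ValueError("empty crossover window")
    fn = predict_bw if quantity == "bw" else predict_gain

    def diff(t: float) -> float:
        return fn(model, params_a, t) - fn(model, params_b, t)

    grid = np.arange(t_lo, t_hi + resolution / 2, max(resolution, 1e-4) * 25)
    grid[-1] = t_hi
    vals = np.array([diff(t) for t in grid])
    signs = np.sign(vals)
    if np.all(signs == 0.0):
        return None  # curves coincide on the window: no crossing
    changed = np.nonzero((signs[:-1] != signs[1:]) | (signs[:-1] == 0))[0]
    if changed.size == 0:
        return None
    i = int(changed[0])
    if signs[i] == 0.0:
        return float(grid[i])
    if signs[i + 1] == 0.0:
        return float(grid[i + 1])
    lo, hi = float(grid[i]), float(grid[i + 1])
    f_lo = diff(lo)
    while hi - lo > resolution / 2:
        mid = 0.5 * (lo + hi)
        f_mid = diff(mid)
        if f_mid == 0.0:
            return mid
        if math.copysign(1.0, f_mid) == math.copysign(1.0, f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
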