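"""Time-course models of cumulative word production and their fitting.

The fused Bousfieldian function (FBF)

    n(t) = c · [1 − (1 + α r t / c)^(−1/α)]

unifies the two classical recall curves — exponential (α → 0) and
hyperbolic (α = 1) — in one three-parameter family, with

    c      asymptote (words),
    r      reciprocal of the elementary process duration (s⁻¹),
    α      dimensionless shape factor.

When c and α grow together with k = c/α fixed, the FBF degenerates to the
unbounded logarithmic curve n(t) = k·ln(1 + r t / k), the time course most
verbal-fluency data follow.

Every curve in the family determines the retrieval probabilities of the
successive words through p_{n+1} = n′(t_n)/r, where t_n is the time at
which the curve passes word n.  For the logarithmic curve this sequence is
exactly geometric, p_{n+1} = e^{−n/k}: each produced word halves (ratio
e^{−1/k}) the odds of retrieving the next one, the signature of an
all-tuples connectivity structure.

``fit`` performs nonlinear least squares of word index against onset time
and selects among candidate models by small-sample-corrected AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FBFParams",
    "LogParams",
    "TwoParams",
    "FitResult",
    "ModelFit",
    "MODEL_NAMES",
    "fbf_curve",
    "log_curve",
    "exponential_curve",
    "hyperbolic_curve",
    "retrieval_probabilities",
    "word_times",
    "fit",
]

MODEL_NAMES = ("fbf", "logarithmic", "exponential", "hyperbolic")

PARAM_LO, PARAM_HI = 1e-6, 1e6


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"parameter {name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class FBFParams:
    """Parameters of the fused Bousfieldian function."""

    c: float      # asymptote, words
    r: float      # s^-1
    alpha: float  # dimensionless

    def __post_init__(self):
        _check_positive(c=self.c, r=self.r, alpha=self.alpha)

    @property
    def k(self) -> float:
        """Derived scale k = c/α (words)."""
        return self.c / self.alpha


@dataclass(frozen=True)
class LogParams:
    """Parameters of the logarithmic curve n(t) = k·ln(1 + rt/k)."""

    k: float  # words
    r: float  # s^-1

    def __post_init__(self):
        _check_positive(k=self.k, r=self.r)


@dataclass(frozen=True)
class TwoParams:
    """Parameters (c, r) of the exponential and hyperbolic special cases."""

    c: float
    r: float

    def __post_init__(self):
        _check_positive(c=self.c, r=self.r)


def fbf_curve(t, p: FBFParams):
    """Cumulative words n(t) = c·[1 − (1 + αrt/c)^(−1/α)]."""
    t = _check_times(t)
    return p.c * (1.0 - np.power(1.0 + p.alpha * p.r * t / p.c, -1.0 / p.alpha))


def log_curve(t, p: LogParams):
    """Cumulative words n(t) = k·ln(1 + rt/k) (unbounded, concave)."""
    t = _check_times(t)
    return p.k * np.log1p(p.r * t / p.k)


def exponential_curve(t, p: TwoParams):
    """Classical exponential recall curve n(t) = c·(1 − e^(−rt/c))."""
    t = _check_times(t)
    return p.c * (-np.expm1(-p.r * t / p.c))


def hyperbolic_curve(t, p: TwoParams):
    """Classical hyperbolic recall curve n(t) = c·rt/(c + rt)."""
    t = _check_times(t)
    return p.c * p.r * t / (p.c + p.r * t)


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


# ---------------------------------------------------------------------------
# retrieval probabilities
#
# All four curves are analytically invertible, so t_n (the word times) and
# the derivative at t_n have closed forms:
#
#   logarithmic: t_n = (k/r)(e^{n/k} − 1),       p_{n+1} = e^{−n/k}
#   fbf:         t_n = c/(αr)·[(1−n/c)^{−α} − 1], p_{n+1} = (1 − n/c)^{1+α}
#   exponential: t_n = −(c/r)·ln(1 − n/c),        p_{n+1} = 1 − n/c
#   hyperbolic:  t_n = (c/r)·n/(c − n),           p_{n+1} = (1 − n/c)²
# ---------------------------------------------------------------------------

Params = FBFParams | LogParams | TwoParams


def word_times(params: Params, n_max: int, model: str | None = None) -> np.ndarray:
    """Times t_0..t_{n_max-1} at which the curve passes 0, 1, ..., n_max−1
    words (t_0 = 0)."""
    model = _model_of(params, model)
    n = np.arange(n_max, dtype=float)
    _check_reachable(params, model, n_max - 1)
    if model == "logarithmic":
        k, r = params.k, params.r
        return (k / r) * np.expm1(n / k)
    c, r = params.c, params.r
    if model == "fbf":
        a = params.alpha
        return c / (a * r) * (np.power(1.0 - n / c, -a) - 1.0)
    if model == "exponential":
        return -(c / r) * np.log1p(-n / c)
    return (c / r) * n / (c - n)  # hyperbolic


def retrieval_probabilities(params: Params, n_max: int, model: str | None = None) -> np.ndarray:
    """Probabilities p_1..p_{n_max} of retrieving the next word.

    p_{n+1} = n′(t_n)/r with t_n the time of the n-th word (t_0 = 0); p_1 is
    always 1 since every curve has initial slope r.  For the logarithmic
    model the sequence is the decreasing geometric sequence e^{−n/k}.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    model = _model_of(params, model)
    n = np.arange(n_max, dtype=float)
    _check_reachable(params, model, n_max - 1)
    if model == "logarithmic":
        return np.exp(-n / params.k)
    frac = 1.0 - n / params.c
    if model == "fbf":
        return np.power(frac, 1.0 + params.alpha)
    if model == "exponential":
        return frac
    return frac**2  # hyperbolic


def _model_of(params: Params, model: str | None) -> str:
    if model is None:
        if isinstance(params, FBFParams):
            return "fbf"
        if isinstance(params, LogParams):
            return "logarithmic"
        raise ValueError(
            "model name required for TwoParams (exponential or hyperbolic)"
        )
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    return model


def _check_reachable(params: Params, model: str, n: int) -> None:
    if model != "logarithmic" and n >= params.c:
        raise ValueError(
            f"word {n} is beyond the asymptote c={params.c}; the bounded "
            f"{model} curve never reaches it"
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFit:
    """One candidate model's least-squares fit."""

    model: str
    params: Params
    sse: float
    aicc: float
    n_points: int
    at_bounds: bool
    success: bool
    message: str = ""


@dataclass(frozen=True)
class FitResult:
    """Fits of all candidate models; ``model`` minimizes AICc."""

    model: str
    params: Params
    sse: float
    aicc: float
    candidates: Mapping[str, ModelFit] = field(default_factory=dict)

    @property
    def selected(self) -> ModelFit:
        return self.candidates[self.model]


_CURVES = {
    "fbf": lambda t, th: fbf_curve(t, FBFParams(*th)),
    "logarithmic": lambda t, th: log_curve(t, LogParams(*th)),
    "exponential": lambda t, th: exponential_curve(t, TwoParams(*th)),
    "hyperbolic": lambda t, th: hyperbolic_curve(t, TwoParams(*th)),
}

_PARAM_CLASSES = {
    "fbf": FBFParams,
    "logarithmic": LogParams,
    "exponential": TwoParams,
    "hyperbolic": TwoParams,
}


def fit(record, candidates: Sequence[str] = MODEL_NAMES) -> FitResult:
    """Fit candidate time-course models to a production record.

    *record* is anything exposing ``onsets`` (seconds, strictly increasing)
    — word j is taken to appear at onset j, j = 1..n — or a plain sequence
    of onsets.  Each candidate is fitted by bounded nonlinear least squares
    of word index against time; the selected model minimizes the
    small-sample-corrected Akaike criterion

        AICc = m·ln(SSE/m) + 2p + 2p(p+1)/(m − p − 1),

    with m points and p = (#curve parameters) + 1 (error variance).
    """
    t = np.asarray(getattr(record, "onsets", record), dtype=float)
    if t.ndim != 1 or t.size < 4:
        raise ValueError(
            f"need at least 4 produced words to fit a time course, got {t.size}"
        )
    if np.any(np.diff(t) <= 0) or t[0] <= 0:
        raise ValueError("onsets must be positive and strictly increasing")
    for name in candidates:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    y = np.arange(1, t.size + 1, dtype=float)
    fits: dict[str, ModelFit] = {}
    for name in candidates:
        fits[name] = _fit_one(name, t, y)
    best = min(fits.values(), key=lambda f: f.aicc)
    return FitResult(
        model=best.model, params=best.params, sse=best.sse, aicc=best.aicc,
        candidates=fits,
    )


def _fit_one(name: str, t: np.ndarray, y: np.ndarray) -> ModelFit:
    curve = _CURVES[name]
    starts = _starting_points(name, t, y)
    best = None
    message = ""
    for theta0 in starts:
        try:
            sol = least_squares(
                lambda th: curve(t, th) - y,
                theta0,
                bounds=(PARAM_LO, PARAM_HI),
                method="trf",
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            message = str(exc)
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError(f"optimizer failed for model {name!r}: {message}")
    sse, sol = best
    theta = sol.x
    n_par = theta.size + 1  # + error variance
    m = t.size
    aicc = _aicc(sse, m, n_par)
    at_bounds = bool(
        np.any(np.isclose(theta, PARAM_LO)) or np.any(np.isclose(theta, PARAM_HI))
    )
    return ModelFit(
        model=name,
        params=_PARAM_CLASSES[name](*theta),
        sse=sse,
        aicc=aicc,
        n_points=m,
        at_bounds=at_bounds,
        success=bool(sol.success),
        message=str(sol.message),
    )


def _aicc(sse: float, m: int, p: int) -> float:
    sse = max(sse, 1e-300)  # keep the log finite on perfect fits
    aic = m * math.log(sse / m) + 2 * p
    if m - p - 1 > 0:
        aic += 2 * p * (p + 1) / (m - p - 1)
    else:
        aic = math.inf  # too few points to correct; never selected over a
        # candidate with a valid correction
    return aic


def _starting_points(name: str, t: np.ndarray, y: np.ndarray):
    eps = 1e-9
    r0 = 2.0 / (t[1] - 0.0 + eps)  # two words produced by the second onset
    c0 = 1.5 * y[-1]
    k0 = max(y[-1] / max(math.log1p(t[-1] * r0 / max(y[-1], 1.0)), 1e-3), 0.5)
    if name == "fbf":
        return [np.array([c0, r0, a0]) for a0 in (0.01, 0.1, 1.0, 10.0)]
    if name == "logarithmic":
        return [np.array([k0, r0]), np.array([1.4427, r0])]
    return [np.array([c0, r0])]
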