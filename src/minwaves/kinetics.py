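"""Phenomenological sigmoid model of cell-free expression kinetics.

The concentration time course of a protein synthesized in a batch cell-free
reaction is described by

    y(t) = k' + k * t^n / (t^n + K^n)

with offset ``k'`` (uM), final yield ``k`` (uM), half-rise time ``K`` (min)
and steepness exponent ``n``.  Two derived quantities summarize a fit:

* expression lifespan (plateau time)  T_plateau = 2K/n + K  [min] — the
  intercept of the tangent at t = K with the plateau level, i.e. when
  production effectively stops;
* apparent translation rate  v_translation = k n / (4K)  [uM/min] — the slope
  of the curve at its half-rise time t = K.

Fitting is per biological replicate by nonlinear least squares; replicate
fits are then aggregated as mean +- sample SD.  Condition comparisons use the
two-tailed Welch (unequal-variance) t test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "sigmoid_eval",
    "derived_quantities",
    "SigmoidFit",
    "fit_sigmoid",
    "SigmoidExpressionModel",
    "AggregateFit",
    "aggregate_replicates",
    "WelchResult",
    "welch_t_test",
    "fit_kinetics_dataset",
    "FitDomainError",
]

_PARAM_NAMES = ("k_prime", "k", "K", "n")


class FitDomainError(ValueError):
    """The data cannot be described by a non-decreasing sigmoid."""


def _validate_params(k_prime: float, k: float, K: float, n: float) -> None:
    if K <= 0:
        raise ValueError("K (half-rise time) must be positive")
    if n <= 0:
        raise ValueError("n (steepness exponent) must be positive")
    if k < 0:
        raise ValueError("k (final yield) must be non-negative")
    if k_prime < 0:
        raise ValueError("k_prime (offset) must be non-negative")


def sigmoid_eval(
    t: np.ndarray | float, k_prime: float, k: float, K: float, n: float
) -> np.ndarray | float:
    """Evaluate y = k' + k t^n / (t^n + K^n) for t >= 0 (minutes)."""
    _validate_params(k_prime, k, K, n)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    # stable form y = k' + k / (1 + (K/t)^n): an overflowing (K/t)^n (t << K
    # at large n) cleanly saturates y at k'
    y = np.full(t.shape, float(k_prime))
    pos = t > 0
    with np.errstate(over="ignore"):
        r = np.exp(n * (np.log(K) - np.log(t[pos])))
    y[pos] = k_prime + k / (1.0 + r)
    return y if y.ndim else float(y)


def derived_quantities(k: float, K: float, n: float) -> tuple[float, float]:
    """Return (t_plateau [min], v_translation [uM/min]).

    ``t_plateau = 2K/n + K`` and ``v_translation = k n / (4K)``, the analytic
    slope dy/dt at t = K.
    """
    _validate_params(0.0, k, K, n)
    return 2 * K / n + K, k * n / (4 * K)


@dataclass
class SigmoidFit:
    """One replicate's fitted sigmoid with derived quantities."""

    k_prime: float
    k: float
    K: float
    n: float
    t_plateau: float
    v_translation: float
    rmse: float
    converged: bool
    protein: str = ""
    replicate: object = None

    def as_dict(self) -> dict:
        return asdict(self)


class SigmoidExpressionModel(BaseEstimator, RegressorMixin):
    """Sigmoid expression-kinetics regressor (one replicate's curve).

    Parameters
    ----------
    xtol : float
        Relative parameter tolerance declaring convergence.
    max_nfev : int
        Function-evaluation budget of the trust-region solver.

    Attributes
    ----------
    k_prime_, k_, K_, n_ : float
        Fitted sigmoid parameters (uM, uM, min, dimensionless).
    t_plateau_, v_translation_ : float
        Derived expression lifespan (min) and apparent translation rate
        (uM/min).
    rmse_ : float
        Root-mean-square residual of the fit (uM).
    converged_ : bool
        Whether the solver reported convergence.
    """

    def __init__(self, xtol: float = 1e-8, max_nfev: int = 500):
        self.xtol = xtol
        self.max_nfev = max_nfev

    @staticmethod
    def _prepare(X, y) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("time and concentration arrays must have equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("time and concentration values must be finite")
        if np.any(t < 0):
            raise ValueError("time points must be non-negative")
        if np.unique(t).size < 4:
            raise FitDomainError("need >= 4 distinct timepoints to fit 4 parameters")
        order = np.argsort(t)
        return t[order], y[order]

    def fit(self, X, y):
        """Fit the sigmoid to one replicate's (t [min], y [uM]) curve."""
        t, y = self._prepare(X, y)
        y_min, y_max = float(np.min(y)), float(np.max(y))
        if y_max <= y_min:
            raise FitDomainError("constant data: no expression signal to fit")
        if np.all(np.diff(y) <= 0):
            raise FitDomainError("monotonically decreasing data is outside the model domain")

        k0 = y_max - y_min
        half = y_min + k0 / 2
        above = t[(y > half) & (t > 0)]
        K0 = float(above[0]) if above.size else float((t[0] + t[-1]) / 2)
        if K0 <= 0:
            K0 = float((t[0] + t[-1]) / 2)
        x0 = np.array([y_min, k0, K0, 2.0])
        eps = 1e-12
        lower = np.array([0.0, eps, eps, 0.2])
        upper = np.array([y_max, 2 * y_max, 2 * float(np.max(t)) + eps, 12.0])
        x0 = np.clip(x0, lower + eps, upper - eps)

        def residuals(p):
            return sigmoid_eval(t, *p) - y

        res = optimize.least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            xtol=self.xtol,
            ftol=self.xtol,
            gtol=None,
            max_nfev=self.max_nfev,
        )
        self.k_prime_, self.k_, self.K_, self.n_ = (float(v) for v in res.x)
        self.t_plateau_, self.v_translation_ = derived_quantities(self.k_, self.K_, self.n_)
        self.rmse_ = float(np.sqrt(np.mean(res.fun**2)))
        self.converged_ = bool(res.success)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return sigmoid_eval(t, self.k_prime_, self.k_, self.K_, self.n_)


def fit_sigmoid(
    t_min: np.ndarray, conc_uM: np.ndarray, protein: str = "", replicate=None
) -> SigmoidFit:
    """Fit one replicate's curve; thin functional wrapper over
    :class:`SigmoidExpressionModel`."""
    m = SigmoidExpressionModel().fit(t_min, conc_uM)
    return SigmoidFit(
        k_prime=m.k_prime_,
        k=m.k_,
        K=m.K_,
        n=m.n_,
        t_plateau=m.t_plateau_,
        v_translation=m.v_translation_,
        rmse=m.rmse_,
        converged=m.converged_,
        protein=protein,
        replicate=replicate,
    )


@dataclass
class AggregateFit:
    """Mean +- sample SD of fitted parameters across converged replicates."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_replicates: int
    excluded: list = field(default_factory=list)


_AGG_FIELDS = ("k_prime", "k", "K", "n", "t_plateau", "v_translation")


def aggregate_replicates(fits: list[SigmoidFit]) -> AggregateFit:
    """Aggregate per-replicate fits: arithmetic mean and sample SD (ddof=1,
    zero for a single replicate) over converged fits only."""
    converged = [f for f in fits if f.converged]
    excluded = [f.replicate for f in fits if not f.converged]
    if not converged:
        raise ValueError("no converged fits to aggregate")
    mean, sd = {}, {}
    for name in _AGG_FIELDS:
        vals = np.array([getattr(f, name) for f in converged], dtype=float)
        mean[name] = float(np.mean(vals))
        sd[name] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return AggregateFit(mean=mean, sd=sd, n_replicates=len(converged), excluded=excluded)


@dataclass
class WelchResult:
    """Two-tailed Welch (unequal-variance) t test."""

    t_stat: float
    df: float
    p_two_tailed: float
    significant_at_0_05: bool


def welch_t_test(a, b) -> WelchResult:
    """Welch's t test with Welch-Satterthwaite degrees of freedom.

    Convention: if both samples have zero variance and equal means, the test
    is degenerate and reports t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, False)
        raise ValueError("zero variance in both samples with unequal means")
    sa, sb = va / a.size, vb / b.size
    t_stat = (np.mean(a) - np.mean(b)) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t_stat), df)
    return WelchResult(float(t_stat), float(df), float(p), bool(p < 0.05))


def fit_kinetics_dataset(
    data: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, AggregateFit]]:
    """Fit every (protein, replicate) curve of a tidy kinetics table.

    ``data`` needs columns ``protein, replicate, time_min, conc_uM``.  Returns
    the per-replicate fit table and a per-protein :class:`AggregateFit` dict.
    """
    required = {"protein", "replicate", "time_min", "conc_uM"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"kinetics table missing columns: {sorted(missing)}")

    rows, aggregates = [], {}
    for protein, group in data.groupby("protein", sort=False):
        fits = []
        for rep, curve in group.groupby("replicate", sort=False):
            fit = fit_sigmoid(
                curve["time_min"].to_numpy(),
                curve["conc_uM"].to_numpy(),
                protein=protein,
                replicate=rep,
            )
            fits.append(fit)
            rows.append(fit.as_dict())
        aggregates[protein] = aggregate_replicates(fits)
    return pd.DataFrame(rows), aggregates
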