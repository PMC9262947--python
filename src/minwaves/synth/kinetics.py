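"""Synthetic cell-free expression time courses.

Protein accumulation in a batch transcription-translation reaction follows a
sigmoid (Hill-type) curve: a lag, a near-linear production phase, and a
plateau once resources are exhausted.  The generator evaluates that model at
requested time points per replicate and adds Gaussian noise truncated at zero
(concentrations cannot be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from minwaves.kinetics import sigmoid_eval

__all__ = [
    "KineticsSimParams",
    "simulate_kinetics",
    "sigmoid_params_from_observables",
    "DEFAULT_EXPRESSION_PARAMS",
]


def sigmoid_params_from_observables(
    yield_uM: float,
    v_translation_uM_min: float,
    t_plateau_min: float,
    yield_time_min: float | None = None,
) -> tuple[float, float, float, float]:
    """Invert the derived-quantity formulas to sigmoid parameters.

    Given the three observables usually reported for an expression curve —
    a yield, the apparent translation rate ``v = k n / (4K)`` and the
    expression lifespan ``T = 2K/n + K`` — solve for ``(k', k, K, n)`` with
    ``k' = 0``.  Eliminating ``n`` gives ``v = k / (2 (T - K))``.

    When ``yield_time_min`` is None, ``yield_uM`` is the final yield ``k``
    and the inversion is algebraic: ``K = T - k / (2v)``, ``n = 2K/(T-K)``.
    When a time is given (e.g. 180 min for an endpoint assay), ``yield_uM``
    is ``y(yield_time_min)`` and ``K`` is found by root-finding — the
    distinction matters for slow expressers whose lifespan extends past the
    endpoint, where the endpoint concentration undershoots ``k``.
    """
    if yield_uM <= 0 or v_translation_uM_min <= 0 or t_plateau_min <= 0:
        raise ValueError("observables must be positive")
    v, T = v_translation_uM_min, t_plateau_min
    if yield_time_min is None:
        rise = yield_uM / (2 * v)
        K = T - rise
        if K <= 0:
            raise ValueError("inconsistent observables: implied half-rise time K <= 0")
        return 0.0, yield_uM, K, 2 * K / rise

    from scipy.optimize import brentq

    def endpoint_mismatch(K: float) -> float:
        k = 2 * v * (T - K)
        n = 2 * K / (T - K)
        return sigmoid_eval(yield_time_min, 0.0, k, K, n) - yield_uM

    eps = 1e-9
    if endpoint_mismatch(eps) < 0:
        raise ValueError(
            "inconsistent observables: endpoint yield exceeds v * T_plateau"
        )
    K = float(brentq(endpoint_mismatch, eps, T - eps, xtol=1e-10))
    k = 2 * v * (T - K)
    return 0.0, k, K, 2 * K / (T - K)


#: Default per-protein sigmoid parameters (k', k [uM], K [min], n) emulating
#: co-expression of the division/positioning proteins in a reconstituted
#: cell-free system: endpoint concentrations ~1.5 / 4.2 / 3.2 uM after 3 h,
#: translation rates ~0.018 / 0.043 / 0.027 uM/min, lifespans ~119 / 144 /
#: 250 min.
DEFAULT_EXPRESSION_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "FtsA": sigmoid_params_from_observables(1.5, 0.018, 119.0, yield_time_min=180.0),
    "MinD": sigmoid_params_from_observables(4.2, 0.043, 144.0, yield_time_min=180.0),
    "MinE": sigmoid_params_from_observables(3.2, 0.027, 250.0, yield_time_min=180.0),
}

#: Default sampling: every 30 min over a 6-h expression time course.
DEFAULT_TIMEPOINTS_MIN: tuple[float, ...] = tuple(float(t) for t in range(0, 361, 30))


@dataclass
class KineticsSimParams:
    """Ground truth for a synthetic expression-kinetics table.

    ``proteins`` maps protein label to sigmoid parameters ``(k', k, K, n)``
    with concentrations in uM and times in minutes.
    """

    proteins: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_PARAMS)
    )
    timepoints_min: tuple[float, ...] = DEFAULT_TIMEPOINTS_MIN
    n_replicates: int = 3
    noise_sd_uM: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd_uM < 0:
            raise ValueError("noise_sd_uM must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.timepoints_min, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints_min must be strictly increasing")
        for name, (k_prime, k, K, n) in self.proteins.items():
            if k < 0 or K <= 0 or n <= 0 or k_prime < 0:
                raise ValueError(f"invalid sigmoid parameters for {name!r}")


def simulate_kinetics(params: KineticsSimParams) -> pd.DataFrame:
    """Simulate a tidy expression-kinetics table.

    Returns a DataFrame with columns ``protein, replicate, time_min, conc_uM``;
    each value is the sigmoid model evaluated at the time point plus Gaussian
    noise (sd ``noise_sd_uM``) truncated at zero.  Identical seed and
    parameters give identical tables.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.timepoints_min, dtype=float)

    records = []
    for protein, (k_prime, k, K, n) in params.proteins.items():
        clean = sigmoid_eval(t, k_prime=k_prime, k=k, K=K, n=n)
        for rep in range(1, params.n_replicates + 1):
            noisy = clean + rng.normal(0.0, params.noise_sd_uM, size=t.shape) \
                if params.noise_sd_uM > 0 else clean.copy()
            noisy = np.clip(noisy, 0.0, None)
            records.append(
                pd.DataFrame(
                    {
                        "protein": protein,
                        "replicate": rep,
                        "time_min": t,
                        "conc_uM": noisy,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
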