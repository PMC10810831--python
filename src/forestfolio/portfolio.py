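"""CVaR portfolio optimization of the stand-type allocation.

The decision variable is the allocation array w (P planning units x S stand
types, each row a composition summing to one).  The objective is the
Conditional Value at Risk at level alpha of the enterprise annuity,

    CVaR_alpha(w) = (1 / (alpha n)) * sum_{i in I_alpha(w)} R_i(w),

the mean of the realizations below the empirical alpha-quantile (the Value
at Risk).  Because the set I_alpha(w) moves with w, the problem is
non-smooth and is solved with differential evolution over the box
[0, 1]^(P x S); the row-sum constraint is enforced by a normalization
repair (each row divided by its sum; all-zero rows reset to uniform), which
keeps the box geometry intact and the constraint exact.

Top-down planning solves one joint problem over all units; bottom-up
planning solves each unit's S-dimensional problem on its own CVaR and is
afterwards evaluated at enterprise level.  The risk-neutral case alpha = 1
separates into per-unit linear programs whose exact solution puts all
weight on the stand type with the highest mean annuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .economics import aggregate_realization

__all__ = [
    "DEConfig",
    "PortfolioResult",
    "BottomUpResult",
    "cvar",
    "normalize_rows",
    "optimize_topdown",
    "optimize_bottomup",
    "risk_neutral_mode",
]


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings (population is popsize x dimension)."""

    popsize: int = 10
    maxiter: int = 2000
    tol: float = 1e-6
    mutation: float | tuple[float, float] = 0.8
    recombination: float = 0.9
    polish: bool = True
    init: str = "latinhypercube"


@dataclass(frozen=True)
class PortfolioResult:
    """Optimized allocation with its risk/return profile."""

    w: np.ndarray                  # (P, S), row-stochastic
    cvar: float                    # Eur ha-1 a-1
    var: float                     # Value at Risk, Eur ha-1 a-1
    mean_return: float             # expected annuity
    risk: float                    # standard deviation of the annuity
    mode: str                      # top-down | bottom-up | risk-neutral
    alpha: float


@dataclass(frozen=True)
class BottomUpResult:
    """Per-unit optima plus their enterprise-level evaluation."""

    units: tuple[PortfolioResult, ...]
    enterprise: PortfolioResult


def cvar(realizations: Sequence[float] | np.ndarray, alpha: float) -> tuple[float, float]:
    """Empirical (CVaR, VaR) of a sample of annuity realizations.

    VaR is the ceil(alpha n)-th order statistic; CVaR is the mean of the
    floor(alpha n) smallest realizations (at alpha = 1 the sample mean).
    """
    r = np.asarray(realizations, dtype=float)
    n = r.size
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if n * alpha < 1.0:
        raise ValueError("need at least 1/alpha realizations for the empirical quantile")
    k = int(np.floor(alpha * n))
    m = int(np.ceil(alpha * n))
    srt = np.sort(r)
    return float(srt[:k].mean()), float(srt[m - 1])


def normalize_rows(w: np.ndarray) -> np.ndarray:
    """Repair an allocation array onto the simplex constraint (rows sum to 1)."""
    w = np.asarray(w, dtype=float)
    sums = w.sum(axis=-1, keepdims=True)
    out = np.where(sums > 0, w / np.where(sums > 0, sums, 1.0), 1.0 / w.shape[-1])
    return out


def _cvar_of_population(r: np.ndarray, k: int) -> np.ndarray:
    """CVaR of each row of a (K, n) realization matrix (mean of k smallest)."""
    part = np.partition(r, k - 1, axis=-1)[..., :k]
    return part.mean(axis=-1)


def _evaluate(w: np.ndarray, annuities: np.ndarray, areas: np.ndarray, alpha: float,
              mode: str) -> PortfolioResult:
    r = aggregate_realization(w, annuities, areas)
    c, v = cvar(r, alpha)
    return PortfolioResult(
        w=w, cvar=c, var=v, mean_return=float(r.mean()), risk=float(r.std(ddof=1)),
        mode=mode, alpha=alpha,
    )


def _optimize(annuities: np.ndarray, areas: np.ndarray, alpha: float,
              de: DEConfig, seed: int, mode: str) -> PortfolioResult:
    n, n_units, n_types = annuities.shape
    if n_types == 1:
        return _evaluate(np.ones((n_units, 1)), annuities, areas, alpha, mode)
    k = int(np.floor(alpha * n))
    if k < 1:
        raise ValueError("need at least 1/alpha replicates")
    weights = (areas / areas.sum())[:, None]
    # (P, S, n) tensor so a population of flattened w maps to realizations in one product
    tensor = np.moveaxis(annuities, 0, -1)
    dim = n_units * n_types

    def objective(x: np.ndarray) -> np.ndarray:
        single = x.ndim == 1
        pop = x[:, None] if single else x            # (dim, K)
        w = normalize_rows(pop.T.reshape(-1, n_units, n_types)) * weights
        r = np.einsum("kps,psn->kn", w, tensor)
        vals = -_cvar_of_population(r, k)
        return float(vals[0]) if single else vals

    result = differential_evolution(
        objective,
        bounds=[(0.0, 1.0)] * dim,
        popsize=de.popsize,
        maxiter=de.maxiter,
        tol=de.tol,
        mutation=de.mutation,
        recombination=de.recombination,
        init=de.init,
        polish=de.polish,
        vectorized=True,
        updating="deferred",
        rng=seed,
    )
    w_opt = normalize_rows(result.x.reshape(n_units, n_types))
    return _evaluate(w_opt, annuities, areas, alpha, mode)


def optimize_topdown(
    annuities: np.ndarray,
    areas: Sequence[float],
    alpha: float = 0.10,
    de_config: DEConfig | None = None,
    seed: int = 0,
) -> PortfolioResult:
    """Jointly optimize all planning units' compositions on the enterprise CVaR."""
    areas = np.asarray(areas, dtype=float)
    return _optimize(annuities, areas, alpha, de_config or DEConfig(), seed, "top-down")


def optimize_bottomup(
    annuities: np.ndarray,
    areas: Sequence[float],
    alpha: float = 0.10,
    de_config: DEConfig | None = None,
    seed: int = 0,
) -> BottomUpResult:
    """Optimize each planning unit's own CVaR independently.

    The concatenated allocation is then evaluated at enterprise level so the
    two planning perspectives can be compared on the same joint
    distribution.
    """
    areas = np.asarray(areas, dtype=float)
    de = de_config or DEConfig()
    unit_results = []
    rows = []
    for p in range(annuities.shape[1]):
        sub = annuities[:, p : p + 1, :]
        res = _optimize(sub, areas[p : p + 1], alpha, de, seed + p, "bottom-up")
        unit_results.append(res)
        rows.append(res.w[0])
    w = np.vstack(rows)
    enterprise = _evaluate(w, annuities, areas, alpha, "bottom-up")
    return BottomUpResult(units=tuple(unit_results), enterprise=enterprise)


def risk_neutral_mode(annuities: np.ndarray, areas: Sequence[float]) -> PortfolioResult:
    """Exact risk-neutral (alpha = 1) solution.

    The expected enterprise annuity is separable over units, so each unit
    puts full weight on its stand type with the highest mean annuity (ties
    to the lower stand-type index).  Serves as the closed-form oracle for
    the optimizer at alpha = 1 and as the risk-neutral sensitivity case.
    """
    areas = np.asarray(areas, dtype=float)
    means = annuities.mean(axis=0)              # (P, S)
    n_units, n_types = means.shape
    w = np.zeros((n_units, n_types))
    w[np.arange(n_units), np.argmax(means, axis=1)] = 1.0
    return _evaluate(w, annuities, areas, 1.0, "risk-neutral")
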