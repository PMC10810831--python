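"""Pre-optimization of rotation periods and mixture shares.

The allocation optimization compares only economically optimal stand
management, so two decisions are fixed before the main stage:

1. **Rotation periods** (deterministic, risk-integrated Faustmann): for
   each candidate rotation T on a 10-year grid, the expected land value of
   one stochastic rotation is computed by weighting the cash flows of every
   possible salvage-harvest age and of the planned final harvest with their
   occurrence probabilities from the decade-wise hazards,

       LEV(T) = -c_init + E[NPV of one rotation] / (1 - E[(1+r)^-tau]),

   with tau = min(first disturbance age, T).  Re-establishment costs are
   attributed at the termination age (their natural-regeneration share
   depends on it).  The candidate maximizing the expected annuity r*LEV is
   selected; ties break toward the shorter rotation.  Mixture variants use
   mixture-adjusted hazards, so stabilization can lengthen rotations.

2. **Species shares of mixed stand types** (stochastic): each share on the
   10 % grid is simulated with the stand simulator under common random
   numbers and the share maximizing the stand-level CVaR of the annuity is
   selected, ties breaking toward the larger share of the first-listed
   (conifer) species.

This stage uses exogenous mean prices (or the external price bootstrap for
the stochastic step) and omits the endogenous market feedback, which is
only defined for a full enterprise composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import economics as econmod
from .economics import EconParams, species_group
from .events import ExtremeEventScenario
from .simulate import (
    StandPrescription,
    decade_hazard_vector,
    simulate_unit_standtype,
    yield_table_for,
)
from .synthetic import CostTable, Enterprise, HazardModel, PlanningUnit, PriceSeries

__all__ = [
    "StandType",
    "DEFAULT_ROTATION_GRID",
    "expected_annuity",
    "optimal_rotation",
    "optimal_mixture_shares",
    "preoptimize_stand_types",
]

DEFAULT_ROTATION_GRID: tuple[int, ...] = tuple(range(40, 190, 10))
DEFAULT_SHARE_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass(frozen=True)
class StandType:
    """A pre-optimized stand type for one planning unit."""

    id: str
    species: tuple[str, ...]
    shares: tuple[float, ...]
    rotation: int
    pre_opt_cvar: float | None = None

    @property
    def prescription(self) -> StandPrescription:
        return StandPrescription(species=self.species, shares=self.shares, rotation=self.rotation)


def expected_annuity(
    species: tuple[str, ...],
    shares: tuple[float, ...],
    rotation: int,
    unit: PlanningUnit,
    models: dict[str, HazardModel],
    costs: CostTable,
    econ: EconParams,
) -> float:
    """Risk-integrated expected annuity of one stand type at a fixed rotation.

    Decade-wise termination probabilities come from the (mixture-adjusted)
    hazards; salvage harvests carry the quality and cost penalties, planned
    final harvests do not.  Prices are the exogenous means (multiplier 1).
    """
    pr = StandPrescription(species=species, shares=shares, rotation=rotation)
    t_dec = rotation // 10
    h = decade_hazard_vector(models, unit, pr)
    r = econ.interest_rate
    disc = (1.0 + r) ** (-10.0 * np.arange(t_dec + 1))
    surv = np.concatenate([[1.0], np.cumprod(1.0 - h)])  # S_k, k = 0..t_dec

    npv = 0.0
    e_disc_tau = 0.0
    c_init = 0.0
    for sp, share in zip(pr.species, pr.shares):
        tb = yield_table_for(sp, unit)
        quality = 1.0 - econ.quality_loss[species_group(sp)]
        c_init += share * costs.planting_cost[sp] * (1.0 - costs.initial_regen_share(sp))
        for k in range(1, t_dec + 1):
            age = 10 * k
            if k < t_dec:
                vol = share * tb.thinning_volume[k]
                net_thin = vol * (
                    float(econmod.gross_price_per_m3(sp, tb.thinning_qmd[k]))
                    - float(econmod.harvest_cost_per_m3(sp, tb.thinning_qmd[k]))
                )
                npv += surv[k - 1] * disc[k] * net_thin
            # salvage at age 10k (probability surv[k-1] * h[k-1])
            vol_s = share * tb.standing_volume[k]
            if k == t_dec:
                vol_s = share * (tb.standing_volume[k] + tb.thinning_volume[k])
            net_salv = vol_s * (
                float(econmod.gross_price_per_m3(sp, tb.standing_qmd[k])) * quality
                - float(econmod.harvest_cost_per_m3(sp, tb.standing_qmd[k])) * econ.salvage_cost_factor
            )
            replant = share * econmod.planting_cost(sp, float(age), "salvage", costs)
            npv += surv[k - 1] * h[k - 1] * disc[k] * (net_salv - replant)
        # planned final harvest at T (probability surv[t_dec])
        vol_f = share * (tb.standing_volume[t_dec] + tb.thinning_volume[t_dec])
        net_fin = vol_f * (
            float(econmod.gross_price_per_m3(sp, tb.standing_qmd[t_dec]))
            - float(econmod.harvest_cost_per_m3(sp, tb.standing_qmd[t_dec]))
        )
        replant_f = share * econmod.planting_cost(sp, float(rotation), "final", costs)
        npv += surv[t_dec] * disc[t_dec] * (net_fin - replant_f)
    e_disc_tau = float(np.sum(surv[:-1] * h * disc[1:]) + surv[t_dec] * disc[t_dec])
    if e_disc_tau >= 1.0:
        return -np.inf
    lev = -c_init + npv / (1.0 - e_disc_tau)
    return econmod.annuity(lev, r)


def optimal_rotation(
    species: tuple[str, ...],
    shares: tuple[float, ...],
    unit: PlanningUnit,
    *,
    models: dict[str, HazardModel],
    costs: CostTable,
    econ: EconParams,
    candidates: tuple[int, ...] = DEFAULT_ROTATION_GRID,
) -> tuple[int, float]:
    """Rotation on the candidate grid maximizing the expected annuity.

    Returns (rotation years, expected annuity); raises if no candidate
    yields a finite value.
    """
    if not candidates:
        raise ValueError("candidate rotation grid is empty")
    best_t, best_val = None, -np.inf
    for t in candidates:
        val = expected_annuity(species, shares, t, unit, models, costs, econ)
        if np.isfinite(val) and val > best_val:
            best_t, best_val = t, val
    if best_t is None:
        raise econmod.ConfigurationError("no rotation candidate yields a finite annuity")
    return best_t, best_val


def optimal_mixture_shares(
    pair: tuple[str, str],
    enterprise: Enterprise,
    unit_index: int,
    *,
    models: dict[str, HazardModel],
    costs: CostTable,
    econ: EconParams,
    scenario: ExtremeEventScenario,
    price_series: PriceSeries | None,
    n_reps: int = 1000,
    seed: int = 0,
    candidate_shares: tuple[float, ...] = DEFAULT_SHARE_GRID,
    rotation_candidates: tuple[int, ...] = DEFAULT_ROTATION_GRID,
    stands_per_1000ha: float = 1.0,
    hazard_range: tuple[float, float] | None = None,
    exposures: np.ndarray | None = None,
    price_mult: dict[str, np.ndarray] | None = None,
) -> tuple[tuple[float, float], int, float]:
    """Species shares of a mixed stand type maximizing the stand-level CVaR.

    Every candidate share (first-listed conifer share on the grid) gets its
    own pre-optimized rotation, is simulated with common random numbers, and
    is scored by the CVaR_alpha of its annuity realizations.  Returns
    (shares, rotation, cvar); ties break toward the larger conifer share.
    """
    from .portfolio import cvar as cvar_fn

    unit = enterprise.units[unit_index]
    best: tuple[tuple[float, float], int, float] | None = None
    for share in candidate_shares:
        shares = (round(share, 10), round(1.0 - share, 10))
        rot, _ = optimal_rotation(pair, shares, unit, models=models, costs=costs, econ=econ,
                                  candidates=rotation_candidates)
        ann = simulate_unit_standtype(
            enterprise,
            unit_index,
            StandPrescription(species=pair, shares=shares, rotation=rot),
            scenario=scenario,
            models=models,
            price_series=price_series,
            costs=costs,
            econ=econ,
            n_reps=n_reps,
            stands_per_1000ha=stands_per_1000ha,
            seed=seed,
            hazard_range=hazard_range,
            exposures=exposures,
            price_mult=price_mult,
        )
        c, _ = cvar_fn(ann, econ.alpha)
        if best is None or c >= best[2]:  # >= breaks ties toward larger conifer share
            best = (shares, rot, c)
    assert best is not None
    return best


def preoptimize_stand_types(
    enterprise: Enterprise,
    stand_type_species: tuple[tuple[str, ...], ...],
    *,
    models: dict[str, HazardModel],
    costs: CostTable,
    econ: EconParams,
    scenario: ExtremeEventScenario,
    price_series: PriceSeries | None,
    preopt_reps: int = 400,
    seed: int = 0,
    rotation_candidates: tuple[int, ...] = DEFAULT_ROTATION_GRID,
    candidate_shares: tuple[float, ...] = DEFAULT_SHARE_GRID,
    stands_per_1000ha: float = 1.0,
    hazard_range: tuple[float, float] | None = None,
    exposures: np.ndarray | None = None,
    price_mult: dict[str, np.ndarray] | None = None,
) -> list[list[StandPrescription]]:
    """Stages 1 and 2 for every (planning unit, stand type) combination.

    Monocultures get their risk-integrated optimal rotation; mixtures
    additionally get CVaR-optimal shares under the given extreme-event
    scenario.  Returns ``prescriptions[p][s]`` ready for the main
    simulation.
    """
    out: list[list[StandPrescription]] = []
    for p, unit in enumerate(enterprise.units):
        row: list[StandPrescription] = []
        for species in stand_type_species:
            if len(species) == 1:
                rot, _ = optimal_rotation(species, (1.0,), unit, models=models, costs=costs,
                                          econ=econ, candidates=rotation_candidates)
                row.append(StandPrescription(species=species, shares=(1.0,), rotation=rot))
            else:
                shares, rot, _ = optimal_mixture_shares(
                    species,  # type: ignore[arg-type]
                    enterprise,
                    p,
                    models=models,
                    costs=costs,
                    econ=econ,
                    scenario=scenario,
                    price_series=price_series,
                    n_reps=preopt_reps,
                    seed=seed,
                    candidate_shares=candidate_shares,
                    rotation_candidates=rotation_candidates,
                    stands_per_1000ha=stands_per_1000ha,
                    hazard_range=hazard_range,
                    exposures=exposures,
                    price_mult=price_mult,
                )
                row.append(StandPrescription(species=species, shares=shares, rotation=rot))
        out.append(row)
    return out
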