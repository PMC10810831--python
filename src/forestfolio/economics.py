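"""Wood valuation, market feedback, and land expectation value.

Cash flows per hectare arise from planting, thinnings, planned final
harvests, and salvage harvests after disturbances.  Wood is valued through a
parametric net-revenue model: the gross price per m3 rises logistically with
the quadratic mean diameter (qmd) of the harvested trees and the harvest
cost per m3 falls as a power law of qmd.  Salvage harvests suffer quality
losses (15 % of revenue for deciduous, 5 % for softwood) and 15 % higher
harvest costs; when the regional salvage supply exceeds twice the planned
final-harvest area, a capacity shortage adds 10 % to logging costs.

Regional oversupply feeds back on prices by market group (softwood vs
deciduous markets are distinct): the relative price multiplier is
1 - 0.05 * A_salv_rel for softwood and 1 - 0.03 * A_salv_rel for deciduous
species, where A_salv_rel is the salvage-harvest area relative to the
expected final-harvest area without disturbances.

Profitability is expressed as the land expectation value (LEV), the net
present value of managing bare land, approximated by discounting the cash
flows of the 500 simulated years; the annuity (land rent) is R = r * LEV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .synthetic import DECIDUOUS_SPECIES, SOFTWOOD_SPECIES, ConfigurationError, CostTable

__all__ = [
    "CashFlow",
    "EconParams",
    "species_group",
    "gross_price_per_m3",
    "harvest_cost_per_m3",
    "net_revenue",
    "market_multiplier",
    "planting_cost",
    "lev",
    "annuity",
    "aggregate_realization",
    "salvage_area_ratio",
    "expected_final_harvest_area",
]

# logistic-in-log-diameter gross price: pmax / (1 + exp(-(ln q - ln d0)/width))
_PRICE_PARAMS: dict[str, tuple[float, float, float]] = {
    # species: (pmax Eur/m3, inflection diameter cm, log width)
    "beech": (95.0, 35.0, 0.45),
    "oak": (180.0, 50.0, 0.45),
    "pine": (80.0, 28.0, 0.45),
    "spruce": (110.0, 28.0, 0.45),
    "douglas_fir": (125.0, 30.0, 0.45),
}

# power-law harvest cost: cref * (q / 30 cm)^-gamma
_COST_PARAMS: dict[str, tuple[float, float]] = {
    "beech": (30.0, 0.45),
    "oak": (30.0, 0.45),
    "pine": (27.0, 0.45),
    "spruce": (27.0, 0.45),
    "douglas_fir": (27.0, 0.45),
}


@dataclass(frozen=True)
class CashFlow:
    """Per-period cash-flow components in Eur per ha; zero when no activity."""

    t: int
    planting_cost: float = 0.0
    thinning_revenue: float = 0.0
    thinning_cost: float = 0.0
    harvest_revenue: float = 0.0
    harvest_cost: float = 0.0

    @property
    def net(self) -> float:
        return (
            -self.planting_cost
            + self.thinning_revenue
            - self.thinning_cost
            + self.harvest_revenue
            - self.harvest_cost
        )


@dataclass(frozen=True)
class EconParams:
    """Economic parameters with the study defaults."""

    interest_rate: float = 0.015
    alpha: float = 0.10                      # CVaR quantile
    quality_loss: dict[str, float] = field(
        default_factory=lambda: {"deciduous": 0.15, "softwood": 0.05}
    )
    salvage_cost_factor: float = 1.15
    capacity_threshold: float = 2.0
    capacity_surcharge: float = 0.10
    market_coef: dict[str, float] = field(
        default_factory=lambda: {"softwood": 0.05, "deciduous": 0.03}
    )
    market_floor: float = 0.0


def species_group(species: str) -> str:
    """Market group of a species: 'softwood' or 'deciduous'."""
    if species in SOFTWOOD_SPECIES:
        return "softwood"
    if species in DECIDUOUS_SPECIES:
        return "deciduous"
    raise ConfigurationError(f"unknown species label {species!r}")


def gross_price_per_m3(species: str, qmd) -> np.ndarray:
    """Gross wood revenue per m3, rising and saturating with diameter."""
    pmax, d0, width = _PRICE_PARAMS[species]
    q = np.maximum(np.asarray(qmd, dtype=float), 1e-6)
    return pmax / (1.0 + np.exp(-(np.log(q) - math.log(d0)) / width))


def harvest_cost_per_m3(species: str, qmd) -> np.ndarray:
    """Harvest cost per m3, falling with diameter (small trees are expensive)."""
    cref, gamma = _COST_PARAMS[species]
    q = np.maximum(np.asarray(qmd, dtype=float), 5.0)
    return cref * (q / 30.0) ** (-gamma)


def net_revenue(
    species: str,
    qmd: float,
    volume: float,
    salvage: bool = False,
    capacity_shortage: bool = False,
    econ: EconParams | None = None,
) -> tuple[float, float]:
    """(revenue, cost) in Eur per ha for harvesting ``volume`` m3 at ``qmd``.

    Salvage applies the group's quality loss to revenues and the salvage
    surcharge to costs; a capacity shortage adds the logging surcharge.
    External price fluctuation and the endogenous market multiplier are
    applied separately by the simulator (they act on all wood sold in a
    period, not only on the salvaged stand).
    """
    if volume < 0:
        raise ValueError("volume must be nonnegative")
    if qmd <= 0:
        raise ValueError("qmd must be positive")
    econ = econ or EconParams()
    revenue = float(gross_price_per_m3(species, qmd)) * volume
    cost = float(harvest_cost_per_m3(species, qmd)) * volume
    if salvage:
        revenue *= 1.0 - econ.quality_loss[species_group(species)]
        cost *= econ.salvage_cost_factor
    if capacity_shortage:
        cost *= 1.0 + econ.capacity_surcharge
    return revenue, cost


def market_multiplier(salvage_area_ratio, group: str, econ: EconParams | None = None) -> np.ndarray:
    """Relative price multiplier under regional salvage oversupply."""
    econ = econ or EconParams()
    ratio = np.asarray(salvage_area_ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("salvage area ratio must be nonnegative")
    return np.maximum(1.0 - econ.market_coef[group] * ratio, econ.market_floor)


def planting_cost(
    species: str,
    age_at_removal: float,
    cause: str,
    costs: CostTable,
) -> float:
    """Re-establishment cost after a removal at the given stand age.

    The payable share is 1 minus the natural-regeneration share, which
    increases with the age of the removed stand (young salvaged stands are
    almost fully replanted) and switches to the species-specific inventory
    share for stands of 100 a and older.  ``cause`` ('final' or 'salvage')
    does not alter the schedule; it is kept for bookkeeping.
    """
    if age_at_removal < 0:
        raise ValueError("age_at_removal must be nonnegative")
    if cause not in ("final", "salvage"):
        raise ValueError("cause must be 'final' or 'salvage'")
    share = costs.natural_regen_share(species, age_at_removal)
    return costs.planting_cost[species] * (1.0 - share)


def lev(cashflows: Iterable[CashFlow], r: float) -> float:
    """Net present value of the cash-flow sequence, discounting with (1+r)^-t."""
    if r <= -1:
        raise ValueError("interest rate must exceed -1")
    return float(sum(cf.net / (1.0 + r) ** cf.t for cf in cashflows))


def annuity(lev_value: float, r: float = 0.015) -> float:
    """Land rent R = r * LEV in Eur per ha per year."""
    return r * lev_value


def aggregate_realization(w: np.ndarray, annuities: np.ndarray, areas: Sequence[float]) -> np.ndarray:
    """Enterprise annuity realization R_i for every Monte-Carlo replicate.

    ``annuities`` has shape (n, P, S) with the replicate index aligned
    across units and stand types so that shared event fields and price paths
    carry their spatial correlation into the joint distribution;
    R_i = sum_p (A_p / A) sum_s w[p, s] * annuities[i, p, s].
    """
    w = np.asarray(w, dtype=float)
    annuities = np.asarray(annuities, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if annuities.ndim != 3 or w.shape != annuities.shape[1:] or areas.shape[0] != w.shape[0]:
        raise ValueError("misaligned dimensions between w, annuities and areas")
    weights = (areas / areas.sum())[:, None] * w
    return np.einsum("ips,ps->i", annuities, weights)


def expected_final_harvest_area(weights: Sequence[float], rotations: Sequence[float]) -> float:
    """Expected final-harvest area per decade without disturbances.

    Each simulated stand contributes weight/rotation * 10 a (in steady state
    a fraction 10/T of the area reaches rotation age per decade).
    """
    weights = np.asarray(weights, dtype=float)
    rotations = np.asarray(rotations, dtype=float)
    return float(np.sum(weights * 10.0 / rotations))


def salvage_area_ratio(salvaged_area, expected_final_area: float) -> np.ndarray:
    """A_salv_rel: salvage-harvest area over the expected final-harvest area."""
    if expected_final_area <= 0:
        raise ZeroDivisionError("expected final-harvest area is zero; ratio undefined")
    return np.asarray(salvaged_area, dtype=float) / expected_final_area
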