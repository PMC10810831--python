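"""Run configuration: one structured-text (YAML) object drives the pipeline.

The defaults reproduce the study setting: five species, eight stand types,
the four extreme-event scenario families, interest rate 1.5 %, CVaR
quantile 10 %, a 500-year horizon in 10-year steps, and one simulated stand
per 1000 ha of planning-unit area.  Two profiles are shipped: a desk-scale
profile (6 units, 1,000 replicates) for interactive work and tests, and the
paper-scale profile (24 units, 10,000 replicates).

Sensitivity switches cover the swept parameters: hazard band of extreme
events, planting-cost scaling (including deciduous-only reductions),
interest rate, market-feedback coefficients, quality-loss scaling, the CVaR
quantile (including the risk-neutral case alpha = 1), and the
extrapolated-climate survival assumption.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .economics import EconParams
from .synthetic import DECIDUOUS_SPECIES, STAND_TYPES, CostTable

__all__ = ["RunConfig", "desk_profile", "paper_profile"]

_DEFAULT_SCENARIOS = ("none", "baseline", "intensified_more", "intensive_more")


@dataclass(frozen=True)
class RunConfig:
    # enterprise
    n_units: int = 6
    region_side: float = 250.0
    seed: int = 0
    # simulation sizes
    n_reps: int = 1000
    preopt_reps: int = 400
    stands_per_1000ha: float = 1.0
    horizon_periods: int = 50
    # scenarios (Table-style defaults; names resolved by events.default_scenarios)
    scenarios: tuple[str, ...] = _DEFAULT_SCENARIOS
    baseline_radius: float = 28.9
    hazard_band: tuple[float, float] = (0.7, 0.99)
    # economics
    interest_rate: float = 0.015
    alpha: float = 0.10
    quality_loss_scale: float = 1.0
    market_coef_scale: float = 1.0
    planting_cost_factor: float = 1.0
    deciduous_cost_factor: float = 1.0
    apply_extrapolation_rescale: bool = True
    market_feedback: bool = True
    # prices
    price_years: int = 300
    price_sigma: float = 0.20
    price_phi: float = 0.70
    # optimizer
    de_popsize: int = 10
    de_maxiter: int = 300
    de_tol: float = 1e-6
    rotation_grid: tuple[int, int] = (40, 180)
    stand_types: tuple[tuple[str, ...], ...] = STAND_TYPES

    def econ_params(self) -> EconParams:
        base = EconParams()
        return EconParams(
            interest_rate=self.interest_rate,
            alpha=self.alpha,
            quality_loss={g: v * self.quality_loss_scale for g, v in base.quality_loss.items()},
            market_coef={g: v * self.market_coef_scale for g, v in base.market_coef.items()},
        )

    def cost_table(self) -> CostTable:
        costs = CostTable().scaled(self.planting_cost_factor)
        if self.deciduous_cost_factor != 1.0:
            costs = costs.scaled(self.deciduous_cost_factor, DECIDUOUS_SPECIES)
        return costs

    def rotation_candidates(self) -> tuple[int, ...]:
        lo, hi = self.rotation_grid
        return tuple(range(lo, hi + 10, 10))

    # -- serialization ------------------------------------------------------

    def to_yaml(self) -> str:
        data = asdict(self)
        data["scenarios"] = list(self.scenarios)
        data["hazard_band"] = list(self.hazard_band)
        data["rotation_grid"] = list(self.rotation_grid)
        data["stand_types"] = [list(st) for st in self.stand_types]
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "scenarios" in data:
            data["scenarios"] = tuple(data["scenarios"])
        if "hazard_band" in data:
            data["hazard_band"] = tuple(data["hazard_band"])
        if "rotation_grid" in data:
            data["rotation_grid"] = tuple(data["rotation_grid"])
        if "stand_types" in data:
            data["stand_types"] = tuple(tuple(st) for st in data["stand_types"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def with_(self, **changes) -> "RunConfig":
        return replace(self, **changes)


def desk_profile(seed: int = 0) -> RunConfig:
    """Desk-scale default: 6 units, 1,000 replicates."""
    return RunConfig(seed=seed)


def paper_profile(seed: int = 0) -> RunConfig:
    """Study-scale setting: 24 units, 10,000 replicates, full optimizer budget."""
    return RunConfig(
        seed=seed,
        n_units=24,
        n_reps=10_000,
        preopt_reps=1000,
        de_maxiter=2000,
        scenarios=(
            "none",
            "baseline",
            "intensified_larger",
            "intensified_more",
            "intensive_larger",
            "intensive_more",
        ),
    )
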