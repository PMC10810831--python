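"""Monte-Carlo simulation of stand trajectories over 500 years.

Stands develop on a 10-year grid: they grow according to their yield table,
are thinned every decade, and face a per-decade damage probability (hazard)
from the species' survival model.  A damaged stand is salvage-harvested in
full and replanted with the same stand type; an undamaged stand reaching its
rotation age is final-harvested and replanted.  Extreme weather events raise
hazards for all stands in covered planning units in the same period, which
correlates disturbances across space.

Within a period the order of operations is: growth, thinning, disturbance
draw, planned final harvest.  A disturbance therefore salvages the
post-thinning stock, and a stand at rotation age that is hit in the same
decade is salvaged rather than final-harvested.

Randomness is organized in named substreams of one root seed: one stream for
the extreme-event field, one for the price bootstrap, and one per
(planning unit, stand-type family) for the stand-level Bernoulli draws.  The
event field and price path are shared by all stand types and units within a
replicate — this is what makes the joint annuity distribution carry the
spatial correlation — while the per-family stand streams give common random
numbers across mixture-share candidates in the pre-optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import economics as econmod
from .economics import EconParams, species_group
from .events import EventDisc, ExtremeEventScenario, extreme_hazard, unit_exposure
from .synthetic import (
    MIXTURE_PAIRS,
    SPECIES,
    ConfigurationError,
    CostTable,
    Enterprise,
    HazardModel,
    PlanningUnit,
    PriceSeries,
    YieldTable,
    generate_hazard_model,
    generate_yield_table,
)

__all__ = [
    "StandPrescription",
    "StandEventRecord",
    "StandTrajectory",
    "SimulationResult",
    "StandSummary",
    "period_hazard",
    "rescale_extrapolated",
    "attainable_hazard_range",
    "decade_hazard_vector",
    "simulate_event_exposures",
    "bootstrap_price_multipliers",
    "simulate_stand",
    "simulate_unit_standtype",
    "simulate_annuity_matrix",
    "default_hazard_models",
    "yield_table_for",
]

HORIZON_PERIODS = 50  # 500 years in 10-a steps


@dataclass(frozen=True)
class StandPrescription:
    """A resolved stand type for one planning unit: species, shares, rotation."""

    species: tuple[str, ...]
    shares: tuple[float, ...]
    rotation: int  # years, multiple of 10

    def __post_init__(self) -> None:
        if len(self.species) not in (1, 2) or len(self.species) != len(self.shares):
            raise ValueError("a stand type carries one or two species with matching shares")
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError("species shares must sum to 1")
        if self.rotation % 10 != 0 or self.rotation <= 0:
            raise ValueError("rotation must be a positive multiple of 10 years")

    @property
    def label(self) -> str:
        if len(self.species) == 1:
            return self.species[0]
        return "+".join(f"{sp}:{sh:.1f}" for sp, sh in zip(self.species, self.shares))

    @property
    def is_mixture(self) -> bool:
        return len(self.species) == 2


@dataclass(frozen=True)
class StandEventRecord:
    """One management or disturbance event of a stand trajectory."""

    t: int                               # simulation year (10-a grid)
    event: str                           # planting|thinning|final_harvest|salvage_harvest
    volumes: dict[str, float]            # m3 ha-1 per species
    qmd: dict[str, float]                # cm per species
    age_at_event: int                    # years


@dataclass(frozen=True)
class StandTrajectory:
    """Ordered event records of one simulated stand over the horizon."""

    records: tuple[StandEventRecord, ...]
    replicate: int
    unit_id: str
    stand_type: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for sp in rec.volumes:
                rows.append(
                    {
                        "replicate": self.replicate,
                        "unit": self.unit_id,
                        "stand_type": self.stand_type,
                        "t": rec.t,
                        "event": rec.event,
                        "species": sp,
                        "volume_m3_ha": rec.volumes[sp],
                        "qmd_cm": rec.qmd[sp],
                        "age_at_event_a": rec.age_at_event,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StandSummary:
    """Monte-Carlo summary of one (unit, stand type): removal-age table.

    ``removal_counts[a, c]`` counts removals at age 10a (a = 1..T/10) with
    cause c (0 = final harvest, 1 = salvage); the normalized table is the
    empirical harvest-age distribution feeding the expected-structure
    reports.
    """

    prescription: StandPrescription
    removal_counts: np.ndarray  # (T_dec + 1, 2)

    @property
    def termination_probabilities(self) -> np.ndarray:
        total = self.removal_counts.sum()
        if total == 0:
            out = np.zeros_like(self.removal_counts, dtype=float)
            out[-1, 0] = 1.0  # degenerate: everything survives to rotation
            return out
        return self.removal_counts / total


@dataclass
class SimulationResult:
    """Joint Monte-Carlo output for a whole enterprise.

    ``annuities[i, p, s]`` is the annuity realization of stand type s in
    unit p in replicate i (mean over the unit's simulated stands), aligned
    across (p, s) by the shared event field and price path.
    """

    annuities: np.ndarray                      # (n, P, S)
    summaries: list[list[StandSummary]]        # [P][S]
    salvage_ratio: dict[str, np.ndarray]       # group -> (n, periods)
    prescriptions: list[list[StandPrescription]]


# ---------------------------------------------------------------------------
# hazards
# ---------------------------------------------------------------------------


def default_hazard_models() -> dict[str, HazardModel]:
    return {sp: generate_hazard_model(sp) for sp in SPECIES}


def period_hazard(model: HazardModel, age: float, climate: np.ndarray | None = None,
                  admix_share: float = 0.0) -> float:
    """Probability of stand damage in the decade starting at ``age``.

    h = 1 - S(age + 10) / S(age), multiplied by the mixture stabilization
    factor and clipped to [0, 1]; if S(age) has already vanished the stand
    cannot survive the step (h = 1).
    """
    if age < 0:
        raise ValueError("age must be nonnegative")
    s0 = float(model.survival(age, climate))
    s1 = float(model.survival(age + 10, climate))
    if s0 <= 0.0:
        return 1.0
    h = (1.0 - s1 / s0) * model.mixture_multiplier(admix_share)
    return float(np.clip(h, 0.0, 1.0))


def rescale_extrapolated(model: HazardModel, climate: np.ndarray | None,
                         envelope: float | None = None) -> HazardModel:
    """Apply the extrapolated-climate survival rescaling where needed.

    If the unit's climate score exceeds the species envelope (the 99 %
    region of the climates the survival family is considered valid for), the
    species is treated as barely viable: the survival curve is power-rescaled so the
    monoculture survival to age 100 is exactly 1 %.  Inside the envelope the
    model is returned unchanged.  The returned model is specific to the
    climate it was rescaled for.
    """
    limit = model.envelope_shift if envelope is None else envelope
    if model.climate_score(climate) <= limit:
        return model
    s100 = float(model.survival(100.0, climate))
    if s100 <= 0.0 or s100 >= 1.0:  # degenerate curve, no finite power rescale
        return model
    beta = math.log(0.01) / math.log(s100)
    return replace(model, rescale_beta=model.rescale_beta * beta)


def decade_hazard_vector(
    models: dict[str, HazardModel],
    unit: PlanningUnit,
    prescription: StandPrescription,
    *,
    apply_envelope: bool = True,
) -> np.ndarray:
    """Stand-level per-decade hazards h[a] for a = 0..T/10-1 of a stand type.

    Mixed stands are destroyed jointly; their hazard is the share-weighted
    mean of the species hazards, each with its own mixture stabilization
    (only stabilized conifers have multipliers below one).
    """
    t_dec = prescription.rotation // 10
    h = np.zeros(t_dec)
    for sp, share in zip(prescription.species, prescription.shares):
        model = models[sp]
        if apply_envelope:
            model = rescale_extrapolated(model, unit.climate)
        admix = (1.0 - share) if prescription.is_mixture else 0.0
        h_sp = model.decade_hazards(prescription.rotation, unit.climate, admix_share=admix)
        h += share * h_sp[:t_dec]
    return np.clip(h, 0.0, 1.0)


def attainable_hazard_range(
    models: dict[str, HazardModel],
    enterprise: Enterprise,
    max_age: int = 180,
) -> tuple[float, float]:
    """[h_lo, h_hi]: extreme per-decade monoculture hazards over species, age
    and the enterprise's climates; anchors the affine extreme-event rescale."""
    lo, hi = 1.0, 0.0
    for sp, model in models.items():
        for unit in enterprise.units:
            m = rescale_extrapolated(model, unit.climate)
            h = m.decade_hazards(max_age, unit.climate)
            lo = min(lo, float(h.min()))
            hi = max(hi, float(h.max()))
    return lo, hi


# ---------------------------------------------------------------------------
# shared stochastic fields
# ---------------------------------------------------------------------------


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def stand_stream_key(species: tuple[str, ...]) -> int:
    """Stable substream key per stand-type family (shares do not enter, so
    mixture-share candidates reuse the same uniforms: common random numbers)."""
    if len(species) == 1:
        return SPECIES.index(species[0])
    return len(SPECIES) + MIXTURE_PAIRS.index(tuple(species))  # type: ignore[arg-type]


def simulate_event_exposures(
    scenario: ExtremeEventScenario,
    enterprise: Enterprise,
    n_reps: int,
    n_periods: int = HORIZON_PERIODS,
    seed: int = 0,
) -> np.ndarray:
    """Per-unit probability of being affected by an extreme event.

    Returns an array (P, n_reps, n_periods): for each decade the Poisson
    event field is drawn once and shared by all units; a unit's exposure is
    the probability that a stand in it lies in an affected area, combining
    the area fractions covered by the period's events.
    """
    from .events import _event_region, _overlap_fraction_arrays

    n_units = len(enterprise.units)
    out = np.zeros((n_units, n_reps, n_periods))
    if scenario.lam == 0:
        return out
    rng = _stream(seed, 2)
    side, offset, factor = _event_region(enterprise, scenario.radius)
    counts = rng.poisson(scenario.lam * factor, size=n_reps * n_periods)
    total = int(counts.sum())
    centers = rng.uniform(-offset, side - offset, size=(total, 2))
    slot = np.repeat(np.arange(n_reps * n_periods), counts)
    for p, unit in enumerate(enterprise.units):
        d = np.hypot(centers[:, 0] - unit.center[0], centers[:, 1] - unit.center[1])
        frac = _overlap_fraction_arrays(unit.disc_radius_km, scenario.radius, d)
        log_miss = np.log(np.maximum(1.0 - frac, 1e-300))
        acc = np.zeros(n_reps * n_periods)
        np.add.at(acc, slot, log_miss)
        out[p] = (1.0 - np.exp(acc)).reshape(n_reps, n_periods)
    return out


def bootstrap_price_multipliers(
    price_series: PriceSeries | None,
    species: Sequence[str],
    n_reps: int,
    n_periods: int = HORIZON_PERIODS,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Bootstrapped decade price multipliers per species, (n_reps, n_periods).

    Each decade draws one year of the 10-year floating-average relative
    price series (the same year for all species, preserving the historic
    cross-species correlation); ``None`` yields constant prices of 1.
    """
    if price_series is None:
        return {sp: np.ones((n_reps, n_periods)) for sp in species}
    floating = price_series.floating_average()
    m = len(next(iter(floating.values())))
    rng = _stream(seed, 3)
    idx = rng.integers(0, m, size=(n_reps, n_periods))
    return {sp: floating[sp][idx] for sp in species}


# ---------------------------------------------------------------------------
# vectorized stand dynamics
# ---------------------------------------------------------------------------


def _simulate_block(
    hazards: np.ndarray,        # (T_dec,)
    hazards_extreme: np.ndarray,  # (T_dec,)
    exposure: np.ndarray,       # (n_reps, n_periods)
    u_damage: np.ndarray,       # (n_reps, n_stands, n_periods)
    u_affected: np.ndarray,     # (n_reps, n_stands, n_periods)
) -> tuple[np.ndarray, np.ndarray]:
    """Age and salvage paths of all stands of one (unit, stand type) block.

    Returns ``ages`` (n_reps, n_stands, n_periods + 1) in decades after the
    period's operations, and ``salvage`` marking periods whose removal was a
    disturbance.  The stand-level and extreme-event damage channels combine
    as one Bernoulli draw at max(stand hazard, extreme hazard) for affected
    stands, which preserves both channels without double counting.
    """
    t_dec = hazards.shape[0]
    n_reps, n_stands, n_periods = u_damage.shape
    ages = np.zeros((n_reps, n_stands, n_periods + 1), dtype=np.int16)
    salvage = np.zeros((n_reps, n_stands, n_periods + 1), dtype=bool)
    age = np.zeros((n_reps, n_stands), dtype=np.int16)
    for j in range(1, n_periods + 1):
        pre = age + 1
        h_base = hazards[pre - 1]
        affected = u_affected[:, :, j - 1] < exposure[:, None, j - 1]
        h_eff = np.where(affected, np.maximum(h_base, hazards_extreme[pre - 1]), h_base)
        damaged = u_damage[:, :, j - 1] < h_eff
        removal = damaged | (pre >= t_dec)
        age = np.where(removal, 0, pre).astype(np.int16)
        ages[:, :, j] = age
        salvage[:, :, j] = damaged
    return ages, salvage


@dataclass(frozen=True)
class _SpeciesCash:
    """Per-species cash-flow lookup tables indexed by age in decades."""

    thin_rev: np.ndarray
    thin_cost: np.ndarray
    salv_rev: np.ndarray
    salv_cost: np.ndarray
    final_rev: float
    final_cost: float
    replant: np.ndarray
    initial_plant: float


def _species_cash_tables(
    sp: str,
    share: float,
    table: YieldTable,
    t_dec: int,
    costs: CostTable,
    econ: EconParams,
) -> _SpeciesCash:
    ages_dec = np.arange(t_dec + 1)
    thin_vol = share * table.thinning_volume[ages_dec]
    thin_rev = thin_vol * econmod.gross_price_per_m3(sp, table.thinning_qmd[ages_dec])
    thin_cost = thin_vol * econmod.harvest_cost_per_m3(sp, table.thinning_qmd[ages_dec])
    # salvage removes the post-thinning stock; at rotation age no separate
    # thinning happened, so the full pre-thinning stock is salvaged
    salv_vol = share * table.standing_volume[ages_dec].copy()
    salv_vol[t_dec] = share * (table.standing_volume[t_dec] + table.thinning_volume[t_dec])
    quality = 1.0 - econ.quality_loss[species_group(sp)]
    salv_rev = salv_vol * econmod.gross_price_per_m3(sp, table.standing_qmd[ages_dec]) * quality
    salv_cost = (
        salv_vol * econmod.harvest_cost_per_m3(sp, table.standing_qmd[ages_dec]) * econ.salvage_cost_factor
    )
    fin_vol = share * (table.standing_volume[t_dec] + table.thinning_volume[t_dec])
    final_rev = float(fin_vol * econmod.gross_price_per_m3(sp, table.standing_qmd[t_dec]))
    final_cost = float(fin_vol * econmod.harvest_cost_per_m3(sp, table.standing_qmd[t_dec]))
    replant = np.array(
        [share * econmod.planting_cost(sp, 10.0 * a, "final", costs) for a in range(t_dec + 1)]
    )
    initial = share * costs.planting_cost[sp] * (1.0 - costs.initial_regen_share(sp))
    return _SpeciesCash(thin_rev, thin_cost, salv_rev, salv_cost, final_rev, final_cost, replant, initial)


def _block_annuities(
    ages: np.ndarray,
    salvage: np.ndarray,
    prescription: StandPrescription,
    tables: dict[str, YieldTable],
    price_mult: dict[str, np.ndarray],      # sp -> (n_reps, n_periods)
    market_mult: dict[str, np.ndarray],     # group -> (n_reps, n_periods)
    cost_factor: np.ndarray,                # (n_reps, n_periods) capacity surcharge
    costs: CostTable,
    econ: EconParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Annuities (n_reps, n_stands) and removal-age counts of one block."""
    t_dec = prescription.rotation // 10
    n_reps, n_stands, n_p1 = ages.shape
    n_periods = n_p1 - 1
    r = econ.interest_rate
    disc = (1.0 + r) ** (-10.0 * np.arange(n_periods + 1))
    cash = {
        sp: _species_cash_tables(sp, share, tables[sp], t_dec, costs, econ)
        for sp, share in zip(prescription.species, prescription.shares)
    }
    levs = np.full((n_reps, n_stands), -sum(c.initial_plant for c in cash.values()))
    removal_counts = np.zeros((t_dec + 1, 2))
    for j in range(1, n_periods + 1):
        pre = (ages[:, :, j - 1] + 1).astype(np.intp)
        sal = salvage[:, :, j]
        rem = ages[:, :, j] == 0
        fin = rem & ~sal
        thin = pre < t_dec
        capj = cost_factor[:, j - 1][:, None]
        net = np.zeros((n_reps, n_stands))
        for sp, c in cash.items():
            pmj = price_mult[sp][:, j - 1][:, None]
            mmj = market_mult[species_group(sp)][:, j - 1][:, None]
            net += np.where(thin, c.thin_rev[pre] * pmj * mmj - c.thin_cost[pre] * capj, 0.0)
            net += np.where(sal, c.salv_rev[pre] * pmj * mmj - c.salv_cost[pre] * capj, 0.0)
            net += np.where(fin, c.final_rev * pmj * mmj - c.final_cost * capj, 0.0)
            net -= np.where(rem, c.replant[pre], 0.0)
        levs += net * disc[j]
        if rem.any():
            pre_rem = pre[rem]
            cause = sal[rem].astype(int)
            np.add.at(removal_counts, (pre_rem, cause), 1.0)
    return r * levs, removal_counts


def _block_uniforms(seed: int, unit_index: int, species: tuple[str, ...],
                    n_reps: int, n_stands: int, n_periods: int) -> tuple[np.ndarray, np.ndarray]:
    rng = _stream(seed, 4, unit_index, stand_stream_key(species))
    u = rng.random((2, n_reps, n_stands, n_periods))
    return u[0], u[1]


def _n_stands(unit: PlanningUnit, stands_per_1000ha: float) -> int:
    return max(1, math.ceil(unit.area / 1000.0 * stands_per_1000ha))


# ---------------------------------------------------------------------------
# public simulation entry points
# ---------------------------------------------------------------------------


def yield_table_for(sp: str, unit: PlanningUnit) -> YieldTable:
    return generate_yield_table(sp, unit.site_index[sp])


def simulate_unit_standtype(
    enterprise: Enterprise,
    unit_index: int,
    prescription: StandPrescription,
    *,
    scenario: ExtremeEventScenario,
    models: dict[str, HazardModel] | None = None,
    price_series: PriceSeries | None = None,
    costs: CostTable | None = None,
    econ: EconParams | None = None,
    n_reps: int = 10_000,
    stands_per_1000ha: float = 1.0,
    n_periods: int = HORIZON_PERIODS,
    seed: int = 0,
    hazard_range: tuple[float, float] | None = None,
    exposures: np.ndarray | None = None,
    price_mult: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Annuity realizations of one stand type in one planning unit.

    Each replicate simulates one stand per 1000 ha of the unit (independent
    stand-level draws, shared extreme-event field and price path) and
    returns the mean annuity of those stands as the replicate's realization.
    Endogenous market feedback needs the enterprise-wide simulation and is
    not applied here.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    models = models or default_hazard_models()
    costs = costs or CostTable()
    econ = econ or EconParams()
    unit = enterprise.units[unit_index]
    if hazard_range is None:
        hazard_range = attainable_hazard_range(models, enterprise)
    h = decade_hazard_vector(models, unit, prescription)
    h_ext = extreme_hazard(h, scenario.hazard_band, hazard_range)
    if exposures is None:
        exposures = simulate_event_exposures(scenario, enterprise, n_reps, n_periods, seed)
    if price_mult is None:
        price_mult = bootstrap_price_multipliers(price_series, prescription.species, n_reps, n_periods, seed)
    n_stands = _n_stands(unit, stands_per_1000ha)
    u_dam, u_aff = _block_uniforms(seed, unit_index, prescription.species, n_reps, n_stands, n_periods)
    ages, salv = _simulate_block(h, h_ext, exposures[unit_index], u_dam, u_aff)
    tables = {sp: yield_table_for(sp, unit) for sp in prescription.species}
    ones = np.ones((n_reps, n_periods))
    market = {"softwood": ones, "deciduous": ones}
    annuities, _ = _block_annuities(
        ages, salv, prescription, tables, price_mult, market, ones, costs, econ
    )
    return annuities.mean(axis=1)


def simulate_annuity_matrix(
    enterprise: Enterprise,
    prescriptions: list[list[StandPrescription]],
    *,
    scenario: ExtremeEventScenario,
    models: dict[str, HazardModel] | None = None,
    price_series: PriceSeries | None = None,
    costs: CostTable | None = None,
    econ: EconParams | None = None,
    n_reps: int = 10_000,
    stands_per_1000ha: float = 1.0,
    n_periods: int = HORIZON_PERIODS,
    seed: int = 0,
    market_feedback: bool = True,
) -> SimulationResult:
    """Joint simulation of all (unit, stand type) combinations.

    ``prescriptions[p][s]`` resolves stand type s in unit p (species, shares,
    rotation).  The simulation runs in two passes: the first resolves the
    disturbance dynamics of every stand (these are price-independent) and
    accumulates the regional salvage supply per market group; the second
    replays the identical dynamics and prices the cash flows with the
    resulting endogenous market multipliers and capacity surcharges.
    Replicates share one event field and one price path across all blocks.
    """
    models = models or default_hazard_models()
    costs = costs or CostTable()
    econ = econ or EconParams()
    n_units = len(enterprise.units)
    n_types = len(prescriptions[0])
    all_species = sorted({sp for row in prescriptions for pr in row for sp in pr.species})
    hazard_range = attainable_hazard_range(models, enterprise)
    exposures = simulate_event_exposures(scenario, enterprise, n_reps, n_periods, seed)
    price_mult = bootstrap_price_multipliers(price_series, all_species, n_reps, n_periods, seed)

    hazard_vecs = [
        [decade_hazard_vector(models, enterprise.units[p], prescriptions[p][s]) for s in range(n_types)]
        for p in range(n_units)
    ]

    def dynamics(p: int, s: int) -> tuple[np.ndarray, np.ndarray]:
        pr = prescriptions[p][s]
        n_stands = _n_stands(enterprise.units[p], stands_per_1000ha)
        u_dam, u_aff = _block_uniforms(seed, p, pr.species, n_reps, n_stands, n_periods)
        h = hazard_vecs[p][s]
        h_ext = extreme_hazard(h, scenario.hazard_band, hazard_range)
        return _simulate_block(h, h_ext, exposures[p], u_dam, u_aff)

    # pass 1: regional salvage supply per market group (stand dynamics only)
    group_weight_total = {"softwood": 0.0, "deciduous": 0.0}
    expected_final = {"softwood": 0.0, "deciduous": 0.0}
    salv_supply = {g: np.zeros((n_reps, n_periods)) for g in ("softwood", "deciduous")}
    for p in range(n_units):
        for s in range(n_types):
            pr = prescriptions[p][s]
            n_stands = _n_stands(enterprise.units[p], stands_per_1000ha)
            shares_by_group = {"softwood": 0.0, "deciduous": 0.0}
            for sp, share in zip(pr.species, pr.shares):
                shares_by_group[species_group(sp)] += share
            if market_feedback:
                _, salv = dynamics(p, s)
                salv_per_period = salv[:, :, 1:].sum(axis=1)  # (n_reps, n_periods)
            for g, share in shares_by_group.items():
                if share == 0.0:
                    continue
                group_weight_total[g] += n_stands * share
                expected_final[g] += n_stands * share / (pr.rotation / 10.0)
                if market_feedback:
                    salv_supply[g] += share * salv_per_period

    ones = np.ones((n_reps, n_periods))
    if market_feedback:
        ratios = {
            g: econmod.salvage_area_ratio(salv_supply[g], expected_final[g])
            if expected_final[g] > 0
            else np.zeros((n_reps, n_periods))
            for g in salv_supply
        }
        market = {g: econmod.market_multiplier(ratios[g], g, econ) for g in ratios}
        total_expected = sum(expected_final.values())
        total_ratio = (salv_supply["softwood"] + salv_supply["deciduous"]) / total_expected
        cost_factor = np.where(
            total_ratio >= econ.capacity_threshold, 1.0 + econ.capacity_surcharge, 1.0
        )
    else:
        ratios = {g: np.zeros((n_reps, n_periods)) for g in salv_supply}
        market = {g: ones for g in salv_supply}
        cost_factor = ones

    # pass 2: replay identical dynamics and price the cash flows
    annuities = np.empty((n_reps, n_units, n_types))
    summaries: list[list[StandSummary]] = []
    for p in range(n_units):
        row: list[StandSummary] = []
        unit = enterprise.units[p]
        for s in range(n_types):
            pr = prescriptions[p][s]
            ages, salv = dynamics(p, s)
            tables = {sp: yield_table_for(sp, unit) for sp in pr.species}
            ann, counts = _block_annuities(
                ages, salv, pr, tables, price_mult, market, cost_factor, costs, econ
            )
            annuities[:, p, s] = ann.mean(axis=1)
            row.append(StandSummary(prescription=pr, removal_counts=counts))
        summaries.append(row)
    return SimulationResult(
        annuities=annuities,
        summaries=summaries,
        salvage_ratio=ratios,
        prescriptions=prescriptions,
    )


# ---------------------------------------------------------------------------
# record-level single-stand simulation (audit, small tests)
# ---------------------------------------------------------------------------


def simulate_stand(
    prescription: StandPrescription,
    unit: PlanningUnit,
    *,
    event_field: Sequence[Sequence[EventDisc]] | None = None,
    rng: np.random.Generator,
    models: dict[str, HazardModel] | None = None,
    hazard_band: tuple[float, float] = (0.7, 0.99),
    hazard_range: tuple[float, float] = (0.0, 1.0),
    conditional_event_hazard: np.ndarray | None = None,
    n_periods: int = HORIZON_PERIODS,
    replicate: int = 0,
) -> StandTrajectory:
    """Simulate one stand trajectory with explicit event records.

    ``event_field`` lists the extreme events of each period (or ``None`` for
    none); the stand is affected by an event with probability equal to the
    unit's area fraction the event covers.  This record-level path mirrors
    the vectorized engine and is meant for audits, exports and tests rather
    than for the 10,000-replicate production runs.
    """
    models = models or default_hazard_models()
    tables = {sp: yield_table_for(sp, unit) for sp in prescription.species}
    t_dec = prescription.rotation // 10
    h = decade_hazard_vector(models, unit, prescription)
    h_ext = (
        conditional_event_hazard
        if conditional_event_hazard is not None
        else extreme_hazard(h, hazard_band, hazard_range)
    )
    records: list[StandEventRecord] = []

    def _volumes(kind: str, age_dec: int) -> tuple[dict[str, float], dict[str, float]]:
        vols, qmds = {}, {}
        for sp, share in zip(prescription.species, prescription.shares):
            tb = tables[sp]
            if kind == "thinning":
                vols[sp] = share * float(tb.thinning_volume[age_dec])
                qmds[sp] = float(tb.thinning_qmd[age_dec])
            else:
                vol = tb.standing_volume[age_dec]
                if age_dec == t_dec:
                    vol = vol + tb.thinning_volume[age_dec]
                vols[sp] = share * float(vol)
                qmds[sp] = float(tb.standing_qmd[age_dec])
        return vols, qmds

    def _plant(t: int, age_at_event: int) -> None:
        records.append(
            StandEventRecord(t=t, event="planting", volumes={sp: 0.0 for sp in prescription.species},
                             qmd={sp: 0.0 for sp in prescription.species}, age_at_event=age_at_event)
        )

    _plant(0, 0)
    age = 0
    for j in range(1, n_periods + 1):
        t = 10 * j
        pre = age + 1
        if pre < t_dec:
            vols, qmds = _volumes("thinning", pre)
            if any(v > 0 for v in vols.values()):
                records.append(
                    StandEventRecord(t=t, event="thinning", volumes=vols, qmd=qmds, age_at_event=10 * pre)
                )
        exposure = 0.0
        if event_field is not None and len(event_field) >= j:
            miss = 1.0
            for ev in event_field[j - 1]:
                miss *= 1.0 - unit_exposure(ev, unit)
            exposure = 1.0 - miss
        affected = rng.random() < exposure
        h_eff = max(h[pre - 1], h_ext[pre - 1]) if affected else h[pre - 1]
        damaged = rng.random() < h_eff
        if damaged or pre >= t_dec:
            kind = "salvage_harvest" if damaged else "final_harvest"
            vols, qmds = _volumes("harvest", pre)
            records.append(StandEventRecord(t=t, event=kind, volumes=vols, qmd=qmds, age_at_event=10 * pre))
            _plant(t, 10 * pre)
            age = 0
        else:
            age = pre
    return StandTrajectory(
        records=tuple(records),
        replicate=replicate,
        unit_id=unit.id,
        stand_type=prescription.label,
    )
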