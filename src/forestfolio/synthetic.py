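"""Synthetic generators for enterprise structure, growth, hazards, prices and costs.

The analysis needs five kinds of input that real forest enterprises treat as
operational data: planning-unit geometry with climate/site covariates,
species- and age-resolved yield tables, climate-sensitive survival (hazard)
models, correlated wood-price series, and planting-cost schedules.  This
module generates all of them from documented parametric families so that the
full simulation-optimization pipeline runs end-to-end on data with the same
statistical structure:

* planning units: areas uniform on a configurable range (default 5,500 to
  19,000 ha), centers uniform in a square core region, climate covariates on
  a smooth spatial gradient plus noise so neighbouring units are similar;
* yield tables: Chapman-Richards cumulative volume production scaled by site
  index, with a fixed fraction of each decade's increment removed as
  thinnings and a power-law quadratic-mean-diameter (qmd) curve;
* hazards: two-parameter Weibull survival with log-linear (accelerated
  failure time) climate scaling and a mixture multiplier that lowers hazards
  of stabilized conifers admixed with a deciduous species;
* prices: mean-one multiplicative indices from a stationary AR(1) process
  with a target cross-species correlation of innovations;
* costs: full planting cost per species with an age-increasing natural
  regeneration share and a species-specific share for old stands.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "DECIDUOUS_SPECIES",
    "SOFTWOOD_SPECIES",
    "STAND_TYPES",
    "MIXTURE_PAIRS",
    "ConfigurationError",
    "PlanningUnit",
    "Enterprise",
    "YieldTable",
    "HazardModel",
    "PriceSeries",
    "CostTable",
    "generate_enterprise",
    "generate_yield_table",
    "generate_hazard_model",
    "generate_price_series",
    "default_cost_table",
    "default_price_correlation",
]


class ConfigurationError(ValueError):
    """Raised when a species label or configuration entry is unknown."""


#: the five species of the default configuration
SPECIES: tuple[str, ...] = ("beech", "oak", "pine", "spruce", "douglas_fir")
DECIDUOUS_SPECIES: frozenset[str] = frozenset({"beech", "oak"})
SOFTWOOD_SPECIES: frozenset[str] = frozenset({"pine", "spruce", "douglas_fir"})

#: default stand types: 5 monocultures plus the three stabilized mixtures
#: (conifer listed first; shares are resolved by the pre-optimization)
STAND_TYPES: tuple[tuple[str, ...], ...] = (
    ("beech",),
    ("oak",),
    ("pine",),
    ("spruce",),
    ("douglas_fir",),
    ("douglas_fir", "beech"),
    ("spruce", "beech"),
    ("douglas_fir", "oak"),
)

#: stabilized two-species combinations offered as mixed stand types
MIXTURE_PAIRS: tuple[tuple[str, str], ...] = (
    ("douglas_fir", "beech"),
    ("spruce", "beech"),
    ("douglas_fir", "oak"),
)

# ---------------------------------------------------------------------------
# species parameter tables (documented defaults of the synthetic families)
# ---------------------------------------------------------------------------

# Chapman-Richards cumulative volume G(a) = vmax*(1-exp(-k a))^m with
# vmax proportional to site index; si_ref is the site index at which the
# reference asymptote applies.  qmd100 is the quadratic mean diameter (cm)
# reached at age 100 on a reference site.
_YIELD_PARAMS: dict[str, dict[str, float]] = {
    "beech":       {"vmax": 950.0,  "k": 0.018, "m": 2.8, "si_ref": 30.0, "qmd100": 40.0},
    "oak":         {"vmax": 750.0,  "k": 0.015, "m": 2.8, "si_ref": 26.0, "qmd100": 45.0},
    "pine":        {"vmax": 800.0,  "k": 0.022, "m": 2.2, "si_ref": 28.0, "qmd100": 32.0},
    "spruce":      {"vmax": 1200.0, "k": 0.025, "m": 2.6, "si_ref": 34.0, "qmd100": 38.0},
    "douglas_fir": {"vmax": 1400.0, "k": 0.025, "m": 2.4, "si_ref": 40.0, "qmd100": 45.0},
}

# Weibull survival under reference climate: S(half_life) = 0.5; shape > 1
# gives hazards increasing with age.  climate weights map the (temperature,
# precipitation) covariates onto the log acceleration of stand age; positive
# shift shortens survival.  envelope_shift is the species' 99 % climate
# envelope: beyond it the species is treated as barely viable and the curve
# is rescaled so S(100) = 0.01 (see stand simulator).
_HAZARD_PARAMS: dict[str, dict[str, float]] = {
    "beech":       {"half_life": 120.0, "shape": 1.4, "w_temp": 0.20, "w_precip": 0.15, "envelope_shift": math.inf},
    "oak":         {"half_life": 150.0, "shape": 1.3, "w_temp": 0.12, "w_precip": 0.10, "envelope_shift": math.inf},
    "pine":        {"half_life": 90.0,  "shape": 1.6, "w_temp": 0.25, "w_precip": 0.15, "envelope_shift": math.inf},
    "spruce":      {"half_life": 60.0,  "shape": 1.8, "w_temp": 0.45, "w_precip": 0.30, "envelope_shift": 0.55},
    "douglas_fir": {"half_life": 80.0,  "shape": 1.8, "w_temp": 0.30, "w_precip": 0.20, "envelope_shift": 0.90},
}

# site-index response to the climate covariates (log-linear); the gradients
# are strong enough that the default 24-unit enterprise shows at least a
# two-fold spread in per-species site index.
_SITE_RESPONSE: dict[str, tuple[float, float]] = {
    # (coefficient on temperature covariate, on precipitation covariate)
    "beech":       (0.20, 0.36),
    "oak":         (0.26, 0.30),
    "pine":        (0.30, 0.26),
    "spruce":      (-0.26, 0.36),
    "douglas_fir": (0.22, 0.36),
}

#: species whose hazard is lowered by admixture of a deciduous companion
_STABILIZED: frozenset[str] = frozenset({"spruce", "douglas_fir"})
_MIXTURE_DELTA = 0.5   # maximum hazard reduction of a stabilized species
_MIXTURE_ETA = 0.35    # curvature: strong effect already at 10 % admixture

_PLANTING_COST: dict[str, float] = {
    "beech": 7500.0,
    "oak": 12000.0,
    "pine": 4000.0,
    "spruce": 3000.0,
    "douglas_fir": 6500.0,
}

# share of natural regeneration assumed for stands >= 100 a (national
# inventory style species-specific shares)
_NFI_REGEN_SHARE: dict[str, float] = {
    "beech": 0.9,
    "oak": 0.5,
    "pine": 0.5,
    "spruce": 0.7,
    "douglas_fir": 0.3,
}


def _check_species(species: str) -> None:
    if species not in SPECIES:
        raise ConfigurationError(f"unknown species label {species!r}; expected one of {SPECIES}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanningUnit:
    """One internally homogeneous forest district of the enterprise."""

    id: str
    area: float                      # ha
    center: tuple[float, float]      # planar km
    climate: np.ndarray              # (temperature index, precipitation index)
    site_index: dict[str, float]     # per-species height at age 100 proxy, m

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("unit area must be positive")
        if any(si <= 0 for si in self.site_index.values()):
            raise ValueError("site indices must be strictly positive")

    @property
    def disc_radius_km(self) -> float:
        """Radius of the equal-area disc representing the unit (1 km2 = 100 ha)."""
        return math.sqrt(self.area / 100.0 / math.pi)


@dataclass(frozen=True)
class Enterprise:
    """A multi-unit forest enterprise embedded in a study region.

    ``region_side`` is the side (km) of the core square containing the unit
    centers; ``region_area`` is the study-region area A_region (km2)
    *including* the extreme-event buffer zone, defaulting to 100,000 km2.
    """

    units: tuple[PlanningUnit, ...]
    region_side: float
    region_area: float = 100_000.0

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("enterprise needs at least one unit")
        if self.region_area < self.region_side**2:
            raise ValueError("region_area must cover the core region")

    @property
    def total_area(self) -> float:
        return float(sum(u.area for u in self.units))

    @property
    def areas(self) -> np.ndarray:
        return np.array([u.area for u in self.units])

    @property
    def centers(self) -> np.ndarray:
        return np.array([u.center for u in self.units])

    def to_frame(self) -> pd.DataFrame:
        """Tidy unit table (areas in ha, coordinates in km, site indices in m)."""
        rows = []
        for u in self.units:
            row = {
                "unit": u.id,
                "area_ha": u.area,
                "x_km": u.center[0],
                "y_km": u.center[1],
                "temperature_index": float(u.climate[0]),
                "precipitation_index": float(u.climate[1]),
            }
            row.update({f"site_index_{sp}_m": si for sp, si in u.site_index.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, region_side: float, region_area: float = 100_000.0) -> "Enterprise":
        units = []
        si_cols = [c for c in frame.columns if c.startswith("site_index_")]
        for _, row in frame.iterrows():
            units.append(
                PlanningUnit(
                    id=str(row["unit"]),
                    area=float(row["area_ha"]),
                    center=(float(row["x_km"]), float(row["y_km"])),
                    climate=np.array([row["temperature_index"], row["precipitation_index"]]),
                    site_index={c[len("site_index_"):-2]: float(row[c]) for c in si_cols},
                )
            )
        return cls(units=tuple(units), region_side=region_side, region_area=region_area)


@dataclass(frozen=True)
class YieldTable:
    """Volume and quadratic mean diameter over age for one species and site.

    ``standing_volume[j]`` is the stock (m3 ha-1) present at age ``ages[j]``
    after the thinning of that age step; ``thinning_volume[j]`` is what that
    thinning removed.  A final harvest at age a therefore removes
    ``standing_volume[a] + thinning_volume[a]``.
    """

    species: str
    site_index: float
    ages: np.ndarray                # years, 10-a grid starting at 0
    standing_volume: np.ndarray     # m3 ha-1
    thinning_volume: np.ndarray     # m3 ha-1 removed at this age step
    standing_qmd: np.ndarray        # cm
    thinning_qmd: np.ndarray        # cm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_a": self.ages,
                "standing_volume_m3_ha": self.standing_volume,
                "thinning_volume_m3_ha": self.thinning_volume,
                "standing_qmd_cm": self.standing_qmd,
                "thinning_qmd_cm": self.thinning_qmd,
            }
        )


@dataclass(frozen=True)
class HazardModel:
    """Age-parametric survival of one species with climate acceleration.

    Survival is Weibull, S(a) = exp(-(a_eff / b)^shape) with the effective
    age a_eff = a * exp(climate_sensitivity * shift) and the climate shift a
    linear score of the covariates plus ``baseline_shift``.  ``half_life`` is
    the age with S = 0.5 under reference climate (shift 0).  ``rescale_beta``
    applies a power transform S -> S^beta used for climates outside the
    species envelope (see ``rescale_extrapolated``).  The mixture multiplier
    m(q) = 1 - delta * q^eta (q = admixed share) lowers hazards of stabilized
    species; delta = 0 disables it.
    """

    species: str
    half_life: float
    shape: float
    climate_weights: tuple[float, float]
    climate_sensitivity: float = 1.0
    baseline_shift: float = 0.0
    envelope_shift: float = math.inf
    mixture_delta: float = 0.0
    mixture_eta: float = _MIXTURE_ETA
    rescale_beta: float = 1.0

    @property
    def scale(self) -> float:
        """Weibull scale b with S(half_life) = 0.5 at reference climate."""
        return self.half_life / math.log(2.0) ** (1.0 / self.shape)

    def climate_score(self, climate: np.ndarray | None) -> float:
        shift = self.baseline_shift
        if climate is not None:
            wt, wp = self.climate_weights
            shift += wt * float(climate[0]) - wp * float(climate[1])
        return shift

    def survival(self, age, climate: np.ndarray | None = None) -> np.ndarray:
        """S(age) under the given climate covariates (vectorized over age)."""
        shift = self.climate_score(climate)
        a_eff = np.asarray(age, dtype=float) * math.exp(self.climate_sensitivity * shift)
        s = np.exp(-((a_eff / self.scale) ** self.shape))
        if self.rescale_beta != 1.0:
            s = s**self.rescale_beta
        return s

    def mixture_multiplier(self, admix_share: float) -> float:
        """Hazard multiplier in (0, 1]; equals 1 at admixed share 0."""
        if admix_share < 0 or admix_share > 1:
            raise ValueError("admixed share must be in [0, 1]")
        if self.mixture_delta == 0.0 or admix_share == 0.0:
            return 1.0
        return 1.0 - self.mixture_delta * admix_share**self.mixture_eta

    def decade_hazards(self, max_age: int, climate: np.ndarray | None = None,
                       admix_share: float = 0.0) -> np.ndarray:
        """Per-decade damage probabilities h[j] for the step age 10j -> 10(j+1).

        h = 1 - S(a+10)/S(a), times the mixture multiplier, clipped to [0, 1];
        where S(a) underflows to 0 the stand cannot survive the step (h = 1).
        """
        ages = np.arange(0, max_age + 10, 10, dtype=float)
        s = self.survival(ages, climate)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = 1.0 - s[1:] / s[:-1]
        h = np.where(s[:-1] <= 0.0, 1.0, h)
        h = np.clip(h * self.mixture_multiplier(admix_share), 0.0, 1.0)
        return h


@dataclass(frozen=True)
class PriceSeries:
    """Mean-one multiplicative wood-price indices per species."""

    years: np.ndarray
    relative_price: dict[str, np.ndarray]
    correlation: pd.DataFrame        # generation target, species x species

    def floating_average(self, window: int = 10) -> dict[str, np.ndarray]:
        """Trailing moving average; the enterprise sells wood collectively, so
        decade periods see the smoothed rather than the annual index."""
        out = {}
        for sp, series in self.relative_price.items():
            kernel = np.ones(window) / window
            out[sp] = np.convolve(series, kernel, mode="valid")
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years}
        data.update({f"relative_price_{sp}": v for sp, v in self.relative_price.items()})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class CostTable:
    """Planting costs and natural-regeneration shares.

    ``natural_regen_share(age)`` is the fraction of the area regenerating
    naturally when a stand removed at that age is re-established (increasing
    with age, capped); stands >= 100 a use the species-specific inventory
    share instead.  Douglas-fir pays full planting at its first
    establishment.
    """

    planting_cost: dict[str, float] = field(default_factory=lambda: dict(_PLANTING_COST))
    nfi_regen_share: dict[str, float] = field(default_factory=lambda: dict(_NFI_REGEN_SHARE))
    regen_cap: float = 0.6
    regen_full_age: float = 100.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.planting_cost.values()):
            raise ValueError("planting costs must be nonnegative")
        if not all(0.0 <= s <= 1.0 for s in self.nfi_regen_share.values()):
            raise ValueError("regeneration shares must be fractions")

    def natural_regen_share(self, species: str, age: float) -> float:
        """Fraction regenerating naturally after removal at the given age."""
        if age >= self.regen_full_age:
            return self.nfi_regen_share[species]
        return self.regen_cap * min(age, self.regen_full_age) / self.regen_full_age

    def initial_regen_share(self, species: str) -> float:
        """Regeneration share at the first establishment on bare land."""
        if species == "douglas_fir":
            return 0.0
        return self.nfi_regen_share[species]

    def scaled(self, factor: float, species: set[str] | frozenset[str] | None = None) -> "CostTable":
        """Return a copy with planting costs scaled (sensitivity analyses)."""
        sel = set(species) if species is not None else set(self.planting_cost)
        costs = {sp: c * factor if sp in sel else c for sp, c in self.planting_cost.items()}
        return replace(self, planting_cost=costs)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_enterprise(
    n_units: int = 24,
    region_side: float = 250.0,
    seed: int = 0,
    *,
    area_range: tuple[float, float] = (5500.0, 19000.0),
    region_area: float | None = None,
    climate_noise: float = 0.12,
) -> Enterprise:
    """Generate a synthetic multi-unit enterprise with spatial heterogeneity.

    Unit areas are uniform on ``area_range`` (ha) and centers uniform in the
    ``region_side`` km core square.  The temperature covariate increases
    along x and the precipitation covariate along y (each spanning about
    [-1.1, 1.1] plus noise), so neighbouring units have similar climates.
    Per-species site indices respond log-linearly (and monotonically) to the
    covariates.
    """
    if n_units < 1:
        raise ValueError("n_units must be at least 1")
    if region_side <= 0:
        raise ValueError("region_side must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    areas = rng.uniform(*area_range, size=n_units)
    centers = rng.uniform(0.0, region_side, size=(n_units, 2))
    temp = (centers[:, 0] / region_side - 0.5) * 2.2 + rng.normal(0.0, climate_noise, n_units)
    precip = (centers[:, 1] / region_side - 0.5) * 2.2 + rng.normal(0.0, climate_noise, n_units)
    units = []
    for i in range(n_units):
        climate = np.array([temp[i], precip[i]])
        site_index = {
            sp: _YIELD_PARAMS[sp]["si_ref"]
            * math.exp(_SITE_RESPONSE[sp][0] * temp[i] + _SITE_RESPONSE[sp][1] * precip[i])
            for sp in SPECIES
        }
        units.append(
            PlanningUnit(
                id=f"unit_{i:02d}",
                area=float(areas[i]),
                center=(float(centers[i, 0]), float(centers[i, 1])),
                climate=climate,
                site_index=site_index,
            )
        )
    if region_area is None:
        region_area = max(100_000.0, region_side**2)
    return Enterprise(units=tuple(units), region_side=region_side, region_area=region_area)


def chapman_richards_volume(species: str, site_index: float, age) -> np.ndarray:
    """Cumulative volume production G(a) = vmax * (1 - exp(-k a))^m, with the
    asymptote scaled proportionally to site index."""
    _check_species(species)
    p = _YIELD_PARAMS[species]
    vmax = p["vmax"] * site_index / p["si_ref"]
    a = np.asarray(age, dtype=float)
    return vmax * (1.0 - np.exp(-p["k"] * a)) ** p["m"]


def generate_yield_table(
    species: str,
    site_index: float,
    *,
    max_age: int = 200,
    thin_fraction: float = 0.30,
    thin_start_age: int = 20,
) -> YieldTable:
    """Yield table on a 10-year age grid from the Chapman-Richards family.

    From ``thin_start_age`` onward a fixed fraction of each decade's gross
    increment is removed as thinning; the standing stock is the cumulative
    production minus all removals.  qmd grows as a power law reaching the
    species' reference diameter at age 100 (scaled with the square root of
    relative site index); thinning qmd is 70 % of the standing qmd (thinning
    from below).
    """
    _check_species(species)
    if site_index <= 0:
        raise ValueError("site_index must be strictly positive")
    ages = np.arange(0, max_age + 10, 10)
    gross = chapman_richards_volume(species, site_index, ages)
    increment = np.diff(gross, prepend=0.0)
    thinning = np.where(ages >= thin_start_age, thin_fraction * increment, 0.0)
    standing = gross - np.cumsum(thinning)
    p = _YIELD_PARAMS[species]
    qmd = p["qmd100"] * math.sqrt(site_index / p["si_ref"]) * (ages / 100.0) ** 0.8
    return YieldTable(
        species=species,
        site_index=site_index,
        ages=ages,
        standing_volume=standing,
        thinning_volume=thinning,
        standing_qmd=qmd,
        thinning_qmd=0.7 * qmd,
    )


def generate_hazard_model(
    species: str,
    base_half_life: float | None = None,
    climate_shift: float = 0.0,
) -> HazardModel:
    """Hazard model with species defaults; ``climate_shift`` adds a constant
    acceleration (positive = worse climate, shorter survival)."""
    _check_species(species)
    p = _HAZARD_PARAMS[species]
    half_life = p["half_life"] if base_half_life is None else float(base_half_life)
    if half_life <= 0:
        raise ValueError("base_half_life must be positive")
    return HazardModel(
        species=species,
        half_life=half_life,
        shape=p["shape"],
        climate_weights=(p["w_temp"], p["w_precip"]),
        baseline_shift=climate_shift,
        envelope_shift=p["envelope_shift"],
        mixture_delta=_MIXTURE_DELTA if species in _STABILIZED else 0.0,
    )


def default_price_correlation(species: tuple[str, ...] = SPECIES) -> pd.DataFrame:
    """Target correlation of log price changes: high within the softwood and
    deciduous market groups, moderate across."""
    n = len(species)
    corr = np.full((n, n), 0.5)
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            if i == j:
                corr[i, j] = 1.0
            elif (si in SOFTWOOD_SPECIES) == (sj in SOFTWOOD_SPECIES):
                corr[i, j] = 0.8
    return pd.DataFrame(corr, index=species, columns=species)


def generate_price_series(
    n_years: int = 300,
    target_corr: pd.DataFrame | None = None,
    seed: int = 0,
    *,
    sigma: float = 0.20,
    phi: float = 0.70,
) -> PriceSeries:
    """Correlated stationary relative price indices.

    Log indices follow a mean-reverting AR(1), x_t = phi x_{t-1} + e_t, with
    innovations drawn from a Gaussian with the target correlation and
    stationary standard deviation ``sigma``.  Because all species share the
    same phi, the cross-correlation of log changes equals the innovation
    correlation.  The exponentiated series are normalized to mean one.
    """
    if n_years < 50:
        raise ValueError("n_years must be at least 50")
    if target_corr is None:
        target_corr = default_price_correlation()
    species = tuple(target_corr.columns)
    corr = np.asarray(target_corr, dtype=float)
    if not np.allclose(corr, corr.T):
        raise ValueError("target correlation matrix must be symmetric")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix must be positive definite") from exc
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    burnin = 100
    eps = rng.standard_normal((n_years + burnin, len(species))) @ chol.T
    eps *= sigma * math.sqrt(1.0 - phi**2)
    x = np.empty_like(eps)
    x[0] = eps[0] / math.sqrt(1.0 - phi**2)
    for t in range(1, len(x)):
        x[t] = phi * x[t - 1] + eps[t]
    x = x[burnin:]
    rel = np.exp(x)
    rel /= rel.mean(axis=0, keepdims=True)
    return PriceSeries(
        years=np.arange(n_years),
        relative_price={sp: rel[:, i] for i, sp in enumerate(species)},
        correlation=target_corr,
    )


def default_cost_table() -> CostTable:
    """Cost schedule with the package's default planting costs (spruce the
    cheapest, oak the most expensive) and regeneration shares."""
    return CostTable()
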