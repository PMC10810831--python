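"""Diversity indicators and expected forest-structure summaries.

Stand-type diversity of an allocation is reported at three scales:
within planning units (count and Shannon evenness, the alpha scale),
between units (pairwise Bray-Curtis dissimilarity of compositions, the
beta scale), and for the enterprise as a whole (count and evenness of the
area-weighted composition, the gamma scale).  The shares of mixed-species
stand types and of deciduous species serve as simplified structural and
functional proxies.

Forest-structure expectations (age distribution, standing volume, harvest
volumes and areas, mean diameter) are derived from the Monte-Carlo
harvest-age tables by a stationary renewal argument: a stand type whose
cycles terminate at age tau spends, in the long run, a share of time
proportional to P(tau > a) in age class a, and completes one cycle per
E[tau] years.  This is equivalent to time-averaging the 500-year
trajectories but far less noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import StandPrescription, StandSummary, yield_table_for
from .synthetic import DECIDUOUS_SPECIES, Enterprise

__all__ = [
    "DiversityReport",
    "StructureReport",
    "evenness",
    "bray_curtis",
    "gamma_metrics",
    "functional_proxies",
    "diversity_report",
    "expected_structure",
]


def evenness(w_p: np.ndarray) -> float:
    """Normalized Shannon evenness W of one composition, in [0, 1].

    W = -sum_s w_s ln w_s / ln S with 0 ln 0 = 0; a single available stand
    type (S = 1) is defined as evenness 0.
    """
    w = np.asarray(w_p, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    s = w.size
    if s == 1:
        return 0.0
    pos = w[w > 0]
    return float(-(pos * np.log(pos)).sum() / np.log(s))


def bray_curtis(w_p1: np.ndarray, w_p2: np.ndarray) -> float:
    """Bray-Curtis dissimilarity of two compositions: half the L1 distance.

    0 means identical compositions, 1 maximum dissimilarity (disjoint
    supports).
    """
    a = np.asarray(w_p1, dtype=float)
    b = np.asarray(w_p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("compositions must cover the same stand types")
    return float(np.abs(a - b).sum() / 2.0)


def _counts(composition: np.ndarray, threshold: float) -> int:
    if threshold == 0:
        return int((composition > 0).sum())
    return int((composition >= threshold).sum())


def gamma_metrics(w: np.ndarray, areas: np.ndarray, threshold: float = 0.01) -> tuple[np.ndarray, int, float]:
    """Enterprise-scale composition, stand-type count, and evenness.

    The composition is the area-weighted sum of the units' rows; the count
    applies a reporting threshold (default 1 %) because continuous
    optimization leaves numerical dust on unused stand types.
    """
    w = np.asarray(w, dtype=float)
    areas = np.asarray(areas, dtype=float)
    composition = (areas / areas.sum()) @ w
    return composition, _counts(composition, threshold), evenness(composition)


def functional_proxies(
    w: np.ndarray,
    areas: np.ndarray,
    mixture_flags: np.ndarray,
    deciduous_fraction: np.ndarray,
) -> tuple[float, float]:
    """(mixed-stand share, deciduous share) of the enterprise allocation.

    ``mixture_flags[p, s]`` marks mixed stand types; ``deciduous_fraction
    [p, s]`` is the deciduous species share inside stand type s of unit p
    (0.1 for a 90/10 spruce-beech stand), so species-level fractions inside
    mixtures count toward the deciduous share.
    """
    w = np.asarray(w, dtype=float)
    areas = np.asarray(areas, dtype=float)
    aw = (areas / areas.sum())[:, None] * w
    mixed = float((aw * np.asarray(mixture_flags, dtype=float)).sum())
    deciduous = float((aw * np.asarray(deciduous_fraction, dtype=float)).sum())
    return mixed, deciduous


def standtype_metadata(prescriptions: list[list[StandPrescription]]) -> tuple[np.ndarray, np.ndarray]:
    """(mixture_flags, deciduous_fraction), each (P, S), from the resolved plans."""
    n_units = len(prescriptions)
    n_types = len(prescriptions[0])
    mix = np.zeros((n_units, n_types))
    dec = np.zeros((n_units, n_types))
    for p in range(n_units):
        for s in range(n_types):
            pr = prescriptions[p][s]
            mix[p, s] = 1.0 if pr.is_mixture else 0.0
            dec[p, s] = sum(sh for sp, sh in zip(pr.species, pr.shares) if sp in DECIDUOUS_SPECIES)
    return mix, dec


@dataclass(frozen=True)
class DiversityReport:
    """Alpha, beta, and gamma diversity of one optimized allocation."""

    unit_counts: np.ndarray            # stand types per unit (threshold applied)
    unit_evenness: np.ndarray          # W_p per unit
    pairwise_bray_curtis: np.ndarray   # condensed upper triangle
    enterprise_composition: np.ndarray
    enterprise_count: int
    enterprise_evenness: float
    mixed_share: float
    deciduous_share: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "mean_unit_count", "value": float(self.unit_counts.mean())},
            {"metric": "mean_unit_evenness", "value": float(self.unit_evenness.mean())},
            {"metric": "mean_bray_curtis", "value": float(self.pairwise_bray_curtis.mean())
             if self.pairwise_bray_curtis.size else np.nan},
            {"metric": "enterprise_count", "value": float(self.enterprise_count)},
            {"metric": "enterprise_evenness", "value": self.enterprise_evenness},
            {"metric": "mixed_share", "value": self.mixed_share},
            {"metric": "deciduous_share", "value": self.deciduous_share},
        ]
        return pd.DataFrame(rows)


def diversity_report(
    w: np.ndarray,
    areas: np.ndarray,
    prescriptions: list[list[StandPrescription]],
    threshold: float = 0.01,
) -> DiversityReport:
    """All seven diversity indicators for one allocation array."""
    w = np.asarray(w, dtype=float)
    areas = np.asarray(areas, dtype=float)
    n_units = w.shape[0]
    counts = np.array([_counts(w[p], threshold) for p in range(n_units)])
    even = np.array([evenness(w[p]) for p in range(n_units)])
    pairs = [bray_curtis(w[p1], w[p2]) for p1 in range(n_units) for p2 in range(p1 + 1, n_units)]
    comp, count, ent_even = gamma_metrics(w, areas, threshold)
    mix_flags, dec_frac = standtype_metadata(prescriptions)
    mixed, deciduous = functional_proxies(w, areas, mix_flags, dec_frac)
    return DiversityReport(
        unit_counts=counts,
        unit_evenness=even,
        pairwise_bray_curtis=np.array(pairs),
        enterprise_composition=comp,
        enterprise_count=count,
        enterprise_evenness=ent_even,
        mixed_share=mixed,
        deciduous_share=deciduous,
    )


@dataclass(frozen=True)
class StructureReport:
    """Long-run expected forest structure under an allocation."""

    age_class_shares: np.ndarray         # share per 10-a class, sums to 1
    expected_standing_volume: float      # m3 ha-1
    expected_annual_harvest_volume: float  # m3 ha-1 a-1
    harvest_salvage_share: float         # fraction of harvest volume from salvage
    annual_harvested_area_fraction: float
    area_salvage_share: float            # fraction of harvested area from salvage
    expected_qmd: float                  # cm, area-weighted over age classes

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "expected_standing_volume_m3_ha", "value": self.expected_standing_volume},
            {"metric": "expected_annual_harvest_volume_m3_ha_a", "value": self.expected_annual_harvest_volume},
            {"metric": "harvest_salvage_share", "value": self.harvest_salvage_share},
            {"metric": "annual_harvested_area_fraction", "value": self.annual_harvested_area_fraction},
            {"metric": "area_salvage_share", "value": self.area_salvage_share},
            {"metric": "expected_qmd_cm", "value": self.expected_qmd},
        ]
        frame = pd.DataFrame(rows)
        age_rows = pd.DataFrame(
            {
                "metric": [f"age_share_{10*a}_{10*(a+1)}" for a in range(self.age_class_shares.size)],
                "value": self.age_class_shares,
            }
        )
        return pd.concat([frame, age_rows], ignore_index=True)


def _standtype_structure(summary: StandSummary, enterprise: Enterprise, unit_index: int) -> dict[str, np.ndarray | float]:
    """Renewal-theory expectations of one (unit, stand type)."""
    pr = summary.prescription
    t_dec = pr.rotation // 10
    q = summary.termination_probabilities  # (t_dec + 1, 2); index = age decades
    q_total = q.sum(axis=1)
    survive = 1.0 - np.cumsum(q_total)     # P(tau > 10a) at a = 0.. (index shifted by 1)
    g = np.concatenate([[1.0], survive[1:t_dec]])  # P(tau > 10a), a = 0..t_dec-1
    g = np.clip(g, 0.0, 1.0)
    e_tau = 10.0 * float(g.sum())          # E[tau] in years
    age_shares = 10.0 * g / e_tau          # share of time in class [10a, 10a+10)

    tables = {sp: yield_table_for(sp, enterprise.units[unit_index]) for sp in pr.species}
    ages = np.arange(t_dec + 1)
    standing = np.zeros(t_dec + 1)
    qmd = np.zeros(t_dec + 1)
    thin_vol = np.zeros(t_dec + 1)
    removal_vol = np.zeros(t_dec + 1)
    for sp, share in zip(pr.species, pr.shares):
        tb = tables[sp]
        standing += share * tb.standing_volume[ages]
        qmd += share * tb.standing_qmd[ages]
        thin_vol += share * tb.thinning_volume[ages]
        vol_rem = share * tb.standing_volume[ages].copy()
        vol_rem[t_dec] += share * tb.thinning_volume[t_dec]
        removal_vol += vol_rem

    exp_standing = float((age_shares * standing[:t_dec]).sum())
    exp_qmd = float((age_shares * qmd[:t_dec]).sum())
    # per-cycle volumes: thinning at age 10a happens with probability
    # P(tau > 10(a-1)); removals weight the termination distribution
    thin_cycle = float(sum(g[a - 1] * thin_vol[a] for a in range(1, t_dec)))
    final_cycle = float((q[:, 0] * removal_vol).sum())
    salv_cycle = float((q[:, 1] * removal_vol).sum())
    harvest_per_year = (thin_cycle + final_cycle + salv_cycle) / e_tau
    salvage_vol_share = salv_cycle / (thin_cycle + final_cycle + salv_cycle) if harvest_per_year > 0 else 0.0
    area_fraction = 1.0 / e_tau
    area_salv_share = float(q[:, 1].sum())
    return {
        "age_shares": age_shares,
        "standing": exp_standing,
        "qmd": exp_qmd,
        "harvest": harvest_per_year,
        "salvage_vol_share": salvage_vol_share,
        "area_fraction": area_fraction,
        "area_salv_share": area_salv_share,
    }


def expected_structure(
    summaries: list[list[StandSummary]],
    enterprise: Enterprise,
    w: np.ndarray,
    max_age_classes: int = 19,
) -> StructureReport:
    """Enterprise-level structure expectations aggregated over the allocation.

    Every (unit, stand type) contributes its stationary renewal
    expectations, weighted by A_p / A * w[p, s].
    """
    w = np.asarray(w, dtype=float)
    areas = enterprise.areas
    aw = (areas / areas.sum())[:, None] * w
    total = aw.sum()
    if total <= 0:
        raise ValueError("allocation carries no area")
    aw = aw / total  # expectations are per allocated hectare
    age = np.zeros(max_age_classes)
    standing = qmd = harvest = salv_vol = area_frac = salv_area = 0.0
    for p in range(w.shape[0]):
        for s in range(w.shape[1]):
            weight = aw[p, s]
            if weight <= 0:
                continue
            st = _standtype_structure(summaries[p][s], enterprise, p)
            shares = st["age_shares"]
            age[: len(shares)] += weight * shares
            standing += weight * st["standing"]
            qmd += weight * st["qmd"]
            harvest += weight * st["harvest"]
            salv_vol += weight * st["harvest"] * st["salvage_vol_share"]
            area_frac += weight * st["area_fraction"]
            salv_area += weight * st["area_fraction"] * st["area_salv_share"]
    return StructureReport(
        age_class_shares=age,
        expected_standing_volume=standing,
        expected_annual_harvest_volume=harvest,
        harvest_salvage_share=salv_vol / harvest if harvest > 0 else 0.0,
        annual_harvested_area_fraction=area_frac,
        area_salvage_share=salv_area / area_frac if area_frac > 0 else 0.0,
        expected_qmd=qmd,
    )
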