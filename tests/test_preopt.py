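"""Rotation and mixture-share pre-optimization against enumeration oracles."""

from dataclasses import replace

import numpy as np
import pytest

from forestfolio import CostTable, EconParams
from forestfolio.preopt import (
    expected_annuity,
    optimal_mixture_shares,
    optimal_rotation,
)
from forestfolio.simulate import (
    StandPrescription,
    bootstrap_price_multipliers,
    simulate_event_exposures,
    simulate_unit_standtype,
    yield_table_for,
)
import forestfolio.economics as em


def zero_hazard(models):
    return {sp: replace(m, half_life=1e12, mixture_delta=0.0) for sp, m in models.items()}


def classical_faustmann_annuity(sp, unit, rotation, costs, econ):
    """Independent oracle: textbook Faustmann annuity of a deterministic
    rotation, r * [cycle NPV / (1 - (1+r)^-T)], with re-establishment costs
    at the harvest age."""
    tb = yield_table_for(sp, unit)
    r = econ.interest_rate
    t_dec = rotation // 10
    npv = 0.0
    for k in range(1, t_dec):
        q = tb.thinning_qmd[k]
        npv += (
            tb.thinning_volume[k]
            * (float(em.gross_price_per_m3(sp, q)) - float(em.harvest_cost_per_m3(sp, q)))
            / (1 + r) ** (10 * k)
        )
    vol = tb.standing_volume[t_dec] + tb.thinning_volume[t_dec]
    q = tb.standing_qmd[t_dec]
    npv += (
        vol * (float(em.gross_price_per_m3(sp, q)) - float(em.harvest_cost_per_m3(sp, q)))
        - em.planting_cost(sp, float(rotation), "final", costs)
    ) / (1 + r) ** rotation
    init = costs.planting_cost[sp] * (1 - costs.initial_regen_share(sp))
    return r * (-init + npv / (1 - (1 + r) ** (-rotation)))


class TestOptimalRotation:
    def test_zero_hazard_matches_classical_faustmann_enumeration(
        self, enterprise, models, costs, econ
    ):
        grid = tuple(range(40, 190, 10))
        z = zero_hazard(models)
        for sp in ("spruce", "beech", "oak"):
            unit = enterprise.units[0]
            rot, val = optimal_rotation((sp,), (1.0,), unit, models=z, costs=costs,
                                        econ=econ, candidates=grid)
            oracle = {t: classical_faustmann_annuity(sp, unit, t, costs, econ) for t in grid}
            t_star = max(oracle, key=oracle.get)
            assert rot == t_star
            assert val == pytest.approx(oracle[t_star], rel=1e-9)

    def test_higher_hazard_never_lengthens_rotation(self, enterprise, models, costs, econ):
        """Scaling hazards up (shorter half-life) must not increase the
        optimal rotation; verified against grid enumeration at each level."""
        unit = enterprise.units[1]
        grid = tuple(range(40, 190, 10))
        rotations = []
        for half_life in (200.0, 100.0, 60.0, 40.0):
            m = {"spruce": replace(models["spruce"], half_life=half_life)}
            rot, _ = optimal_rotation(("spruce",), (1.0,), unit, models=m, costs=costs,
                                      econ=econ, candidates=grid)
            enumerated = max(
                grid,
                key=lambda t: expected_annuity(("spruce",), (1.0,), t, unit, m, costs, econ),
            )
            assert rot == enumerated
            rotations.append(rot)
        assert rotations == sorted(rotations, reverse=True)

    def test_single_candidate_returned(self, enterprise, models, costs, econ):
        rot, _ = optimal_rotation(("pine",), (1.0,), enterprise.units[0], models=models,
                                  costs=costs, econ=econ, candidates=(110,))
        assert rot == 110

    def test_empty_grid_rejected(self, enterprise, models, costs, econ):
        with pytest.raises(ValueError):
            optimal_rotation(("pine",), (1.0,), enterprise.units[0], models=models,
                             costs=costs, econ=econ, candidates=())


class TestDeterministicVsMonteCarlo:
    def test_expected_annuity_matches_simulation(self, enterprise, models, costs, econ,
                                                 scenarios):
        """The deterministic risk integration agrees with a Monte-Carlo
        estimate of the same expected annuity within 3 standard errors
        (stand-level disturbances only, exogenous mean prices)."""
        unit_index = 0
        pr = StandPrescription(species=("spruce",), shares=(1.0,), rotation=90)
        det = expected_annuity(("spruce",), (1.0,), 90, enterprise.units[unit_index],
                               models, costs, econ)
        ann = simulate_unit_standtype(
            enterprise, unit_index, pr, scenario=scenarios["none"], models=models,
            price_series=None, costs=costs, econ=econ, n_reps=4000, seed=17,
        )
        se = ann.std(ddof=1) / np.sqrt(ann.size)
        assert abs(ann.mean() - det) < 3 * se + 1e-9


class TestMixtureShares:
    def test_single_candidate_returned(self, enterprise, models, costs, econ, scenarios):
        shares, rot, c = optimal_mixture_shares(
            ("spruce", "beech"), enterprise, 0, models=models, costs=costs, econ=econ,
            scenario=scenarios["none"], price_series=None, n_reps=200, seed=3,
            candidate_shares=(0.5,),
        )
        assert shares == (0.5, 0.5)
        assert rot % 10 == 0

    def test_argmax_matches_manual_grid_enumeration(self, enterprise, models, costs, econ,
                                                    scenarios):
        """The selected share reproduces an explicit enumeration over the
        candidate grid with identical common-random-number simulations."""
        from forestfolio.portfolio import cvar

        grid = (0.3, 0.6, 0.9)
        pair = ("spruce", "beech")
        n_reps, seed = 250, 7
        exposures = simulate_event_exposures(scenarios["baseline"], enterprise, n_reps, 50, seed)
        kwargs = dict(models=models, costs=costs, econ=econ, scenario=scenarios["baseline"],
                      price_series=None, n_reps=n_reps, seed=seed)
        best_share, best_c = None, -np.inf
        for share in grid:
            shares = (share, round(1 - share, 10))
            rot, _ = optimal_rotation(pair, shares, enterprise.units[2], models=models,
                                      costs=costs, econ=econ)
            ann = simulate_unit_standtype(
                enterprise, 2, StandPrescription(species=pair, shares=shares, rotation=rot),
                exposures=exposures, **kwargs,
            )
            c, _ = cvar(ann, econ.alpha)
            if c >= best_c:
                best_share, best_c = shares, c
        shares, _, c = optimal_mixture_shares(
            pair, enterprise, 2, candidate_shares=grid, exposures=exposures, **kwargs
        )
        assert shares == best_share
        assert c == pytest.approx(best_c)

    def test_strong_stabilization_selects_ninety_ten(self, enterprise, models, costs, econ,
                                                     scenarios):
        """With a drastic hazard reduction already at 10 % admixture and an
        unattractive companion, the CVaR-optimal mixture keeps 90 % of the
        conifer (grid-enumeration-backed construction)."""
        strong = dict(models)
        strong["spruce"] = replace(models["spruce"], mixture_delta=0.95, mixture_eta=0.05)
        shares, _, _ = optimal_mixture_shares(
            ("spruce", "beech"), enterprise, 0, models=strong, costs=costs, econ=econ,
            scenario=scenarios["none"], price_series=None, n_reps=400, seed=5,
        )
        assert shares[0] == pytest.approx(0.9)
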