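"""Valuation: discounting, salvage penalties, market feedback, aggregation."""

import numpy as np
import pytest

from forestfolio import (
    CashFlow,
    CostTable,
    aggregate_realization,
    annuity,
    lev,
    market_multiplier,
    net_revenue,
    planting_cost,
    salvage_area_ratio,
)
from forestfolio.economics import (
    expected_final_harvest_area,
    gross_price_per_m3,
    harvest_cost_per_m3,
)


class TestDiscounting:
    @pytest.mark.parametrize(
        "flows,r,expected",
        [
            ([CashFlow(t=0, harvest_revenue=100.0)], 0.015, 100.0),
            ([CashFlow(t=10, harvest_revenue=100.0)], 0.015, 100.0 / 1.015**10),
            ([CashFlow(t=0, planting_cost=50.0), CashFlow(t=20, harvest_revenue=80.0)], 0.0, 30.0),
        ],
    )
    def test_lev_closed_form(self, flows, r, expected):
        assert lev(flows, r) == pytest.approx(expected, rel=1e-12)

    def test_lev_is_linear_in_cash_flow_components(self):
        base = [CashFlow(t=10, thinning_revenue=40.0), CashFlow(t=30, harvest_revenue=200.0)]
        scaled = [CashFlow(t=10, thinning_revenue=40.0), CashFlow(t=30, harvest_revenue=600.0)]
        r = 0.015
        delta = lev(scaled, r) - lev(base, r)
        assert delta == pytest.approx(2 * 200.0 / 1.015**30, rel=1e-12)

    @pytest.mark.parametrize("value,expected", [(1000.0, 15.0), (0.0, 0.0), (-2000.0, -30.0)])
    def test_annuity(self, value, expected):
        assert annuity(value, 0.015) == pytest.approx(expected)


class TestNetRevenue:
    def test_zero_volume_is_free(self):
        assert net_revenue("spruce", 35.0, 0.0) == (0.0, 0.0)

    def test_salvage_penalties_softwood(self):
        rev, cost = net_revenue("spruce", 35.0, 100.0)
        srev, scost = net_revenue("spruce", 35.0, 100.0, salvage=True)
        assert srev == pytest.approx(0.95 * rev)
        assert scost == pytest.approx(1.15 * cost)

    def test_salvage_penalties_deciduous(self):
        rev, _ = net_revenue("beech", 40.0, 100.0)
        srev, _ = net_revenue("beech", 40.0, 100.0, salvage=True)
        assert srev == pytest.approx(0.85 * rev)

    def test_capacity_shortage_surcharge(self):
        _, cost = net_revenue("pine", 30.0, 50.0)
        _, ccost = net_revenue("pine", 30.0, 50.0, capacity_shortage=True)
        assert ccost == pytest.approx(1.10 * cost)

    def test_species_net_revenue_ordering_at_reference_diameters(self):
        """The calibrated curves preserve the intended per-m3 ordering:
        Douglas-fir > spruce > pine among softwoods, oak > beech among
        deciduous species, at their typical mature diameters."""
        def net(sp, q):
            return float(gross_price_per_m3(sp, q) - harvest_cost_per_m3(sp, q))

        assert net("douglas_fir", 45.0) > net("spruce", 38.0) > net("pine", 32.0)
        assert net("oak", 45.0) > net("beech", 40.0)

    def test_price_rises_cost_falls_with_diameter(self):
        q = np.array([10.0, 20.0, 40.0, 60.0])
        assert np.all(np.diff(gross_price_per_m3("spruce", q)) > 0)
        assert np.all(np.diff(harvest_cost_per_m3("spruce", q)) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            net_revenue("spruce", 0.0, 10.0)
        with pytest.raises(ValueError):
            net_revenue("spruce", 30.0, -1.0)


class TestMarketFeedback:
    @pytest.mark.parametrize(
        "ratio,group,expected",
        [(0.0, "softwood", 1.0), (1.0, "softwood", 0.95), (1.0, "deciduous", 0.97)],
    )
    def test_linear_price_response(self, ratio, group, expected):
        assert float(market_multiplier(ratio, group)) == pytest.approx(expected)

    def test_floor(self):
        assert float(market_multiplier(50.0, "softwood")) == 0.0

    def test_groups_are_distinct_markets(self):
        """Softwood oversupply does not move deciduous prices and vice
        versa: the multiplier of one group only depends on its own ratio."""
        assert float(market_multiplier(3.0, "deciduous")) == pytest.approx(0.91)
        assert float(market_multiplier(0.0, "deciduous")) == 1.0


class TestPlantingCost:
    def test_full_natural_regeneration_is_free(self):
        ct = CostTable(nfi_regen_share={sp: 1.0 for sp in CostTable().planting_cost})
        assert planting_cost("beech", 120.0, "final", ct) == 0.0

    def test_documented_schedule_at_age_10(self):
        """With a regeneration share of 0.1 at age 10 the replant costs 90 %
        of full planting."""
        ct = CostTable(regen_cap=1.0)  # share = age/100 -> 0.1 at age 10
        full = ct.planting_cost["spruce"]
        assert planting_cost("spruce", 10.0, "salvage", ct) == pytest.approx(0.9 * full)

    def test_nfi_share_for_old_stands(self):
        ct = CostTable()
        expected = ct.planting_cost["oak"] * (1 - ct.nfi_regen_share["oak"])
        assert planting_cost("oak", 140.0, "final", ct) == pytest.approx(expected)

    def test_invalid_cause(self):
        with pytest.raises(ValueError):
            planting_cost("oak", 50.0, "storm", CostTable())


class TestAggregation:
    def test_single_unit_identity(self, rng):
        ann = rng.normal(size=(50, 1, 1))
        r = aggregate_realization(np.ones((1, 1)), ann, [1000.0])
        assert np.allclose(r, ann[:, 0, 0])

    def test_equal_area_weighted_mean(self):
        ann = np.stack([np.full((2, 1), 10.0), np.full((2, 1), 20.0)], axis=1)  # (2,2,1)
        r = aggregate_realization(np.ones((2, 1)), ann, [500.0, 500.0])
        assert np.allclose(r, 15.0)

    def test_permutation_invariance(self, rng):
        ann = rng.normal(size=(30, 2, 3))
        w = np.array([[0.2, 0.5, 0.3], [0.6, 0.1, 0.3]])
        perm = [2, 0, 1]
        r1 = aggregate_realization(w, ann, [800.0, 1200.0])
        r2 = aggregate_realization(w[:, perm], ann[:, :, perm], [800.0, 1200.0])
        assert np.allclose(r1, r2)

    def test_misaligned_dimensions(self, rng):
        with pytest.raises(ValueError):
            aggregate_realization(np.ones((2, 2)), rng.normal(size=(10, 2, 3)), [1.0, 1.0])


class TestSalvageRatio:
    def test_no_disturbance_is_zero(self):
        e = expected_final_harvest_area([1.0, 1.0], [100.0, 80.0])
        assert np.all(salvage_area_ratio(np.zeros(5), e) == 0)

    def test_everything_salvaged_at_rotation_100(self):
        """If the whole area (weight 1) is salvaged in one decade while the
        planned final-harvest area is area/10 rotations per decade, the
        ratio is 10."""
        e = expected_final_harvest_area([1.0], [100.0])
        assert float(salvage_area_ratio(1.0, e)) == pytest.approx(10.0)

    def test_zero_expected_area_undefined(self):
        with pytest.raises(ZeroDivisionError):
            salvage_area_ratio(1.0, 0.0)
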