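"""Generators: determinism, documented curves, and statistical structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestfolio import (
    ConfigurationError,
    generate_enterprise,
    generate_hazard_model,
    generate_price_series,
    generate_yield_table,
)
from forestfolio.synthetic import (
    SPECIES,
    CostTable,
    chapman_richards_volume,
    default_price_correlation,
)


class TestEnterprise:
    def test_seeded_determinism(self):
        a = generate_enterprise(24, 200.0, seed=1)
        b = generate_enterprise(24, 200.0, seed=1)
        assert a.to_frame().equals(b.to_frame())

    def test_total_area_bounds_for_default_range(self):
        ent = generate_enterprise(24, 200.0, seed=1)
        assert 24 * 5500 <= ent.total_area <= 24 * 19000
        assert all(5500 <= u.area <= 19000 for u in ent.units)

    def test_single_unit_identity(self):
        ent = generate_enterprise(1, 10.0, seed=7)
        assert ent.total_area == ent.units[0].area

    @pytest.mark.parametrize("n_units,side", [(0, 10.0), (-1, 10.0), (5, 0.0)])
    def test_invalid_arguments(self, n_units, side):
        with pytest.raises(ValueError):
            generate_enterprise(n_units, side, seed=0)

    def test_default_enterprise_site_heterogeneity(self):
        """The default 24-unit enterprise spans at least a 2-fold spread in
        per-species site index (pronounced site heterogeneity)."""
        ent = generate_enterprise(seed=0)
        for sp in SPECIES:
            si = np.array([u.site_index[sp] for u in ent.units])
            assert si.max() / si.min() >= 2.0

    def test_region_covers_core(self):
        ent = generate_enterprise(6, 250.0, seed=1)
        assert ent.region_area >= ent.region_side**2
        assert np.all(ent.centers >= 0) and np.all(ent.centers <= ent.region_side)

    def test_frame_round_trip(self):
        from forestfolio.synthetic import Enterprise

        ent = generate_enterprise(4, 100.0, seed=3)
        back = Enterprise.from_frame(ent.to_frame(), region_side=100.0)
        assert back.to_frame().round(9).equals(ent.to_frame().round(9))


class TestYieldTable:
    def test_higher_site_index_more_volume(self):
        lo = generate_yield_table("spruce", 28.0)
        hi = generate_yield_table("spruce", 36.0)
        assert np.all(hi.standing_volume[1:] > lo.standing_volume[1:])

    def test_age_zero_has_no_volume(self):
        tb = generate_yield_table("beech", 30.0)
        assert tb.standing_volume[0] == 0.0

    def test_standing_volume_matches_documented_curve(self):
        """Standing volume at age 80 equals the Chapman-Richards cumulative
        production minus all thinning removals up to that age (frozen from
        independent evaluation of the documented closed form)."""
        tb = generate_yield_table("spruce", 34.0, thin_fraction=0.30, thin_start_age=20)
        ages = np.arange(0, 90, 10)
        gross = chapman_richards_volume("spruce", 34.0, ages)
        thinned = 0.30 * np.diff(gross, prepend=0.0)
        thinned[ages < 20] = 0.0
        expected = gross[8] - thinned.sum()
        assert tb.standing_volume[8] == pytest.approx(expected, rel=1e-12)

    def test_qmd_nondecreasing_and_volumes_finite(self):
        for sp in SPECIES:
            tb = generate_yield_table(sp, 30.0)
            assert np.all(np.diff(tb.standing_qmd) >= 0)
            assert np.all(tb.thinning_volume >= 0)
            assert np.all(np.isfinite(tb.standing_volume))
            assert np.all(tb.standing_volume >= 0)

    def test_unknown_species_raises(self):
        with pytest.raises(ConfigurationError):
            generate_yield_table("larch", 30.0)

    def test_nonpositive_site_index_raises(self):
        with pytest.raises(ValueError):
            generate_yield_table("spruce", 0.0)


class TestHazardModel:
    def test_half_life_definition(self):
        m = generate_hazard_model("spruce", base_half_life=60.0, climate_shift=0.0)
        assert m.survival(60.0) == pytest.approx(0.5, abs=1e-12)

    def test_worse_climate_lowers_survival(self):
        base = generate_hazard_model("spruce", climate_shift=0.0)
        worse = generate_hazard_model("spruce", climate_shift=0.3)
        assert worse.survival(100.0) < base.survival(100.0)

    def test_mixture_multiplier_boundary(self):
        m = generate_hazard_model("spruce")
        assert m.mixture_multiplier(0.0) == 1.0
        assert 0.0 < m.mixture_multiplier(0.1) < 1.0
        oak = generate_hazard_model("oak")
        assert oak.mixture_multiplier(0.5) == 1.0  # not stabilized

    @given(shift=st.floats(-0.5, 1.5), half_life=st.floats(20.0, 200.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_survival_monotone_and_hazards_are_probabilities(self, shift, half_life):
        m = generate_hazard_model("pine", base_half_life=half_life, climate_shift=shift)
        ages = np.arange(0, 210, 10, dtype=float)
        s = m.survival(ages)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        h = m.decade_hazards(200)
        assert np.all((h >= 0) & (h <= 1))


class TestPriceSeries:
    def test_identity_correlation_recovered(self):
        corr = default_price_correlation()
        corr.iloc[:, :] = np.eye(len(SPECIES))
        ps = generate_price_series(1000, corr, seed=3)
        logs = np.column_stack([np.diff(np.log(ps.relative_price[sp])) for sp in SPECIES])
        sample = np.corrcoef(logs.T)
        off = sample[~np.eye(len(SPECIES), dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_target_correlation_within_tolerance(self):
        ps = generate_price_series(500, seed=2)
        corr = ps.correlation.to_numpy()
        logs = np.column_stack([np.diff(np.log(ps.relative_price[sp])) for sp in SPECIES])
        sample = np.corrcoef(logs.T)
        assert np.all(np.abs(sample - corr) <= 0.15)

    def test_mean_one_and_positive(self):
        ps = generate_price_series(200, seed=5)
        for series in ps.relative_price.values():
            assert np.all(series > 0)
            assert series.mean() == pytest.approx(1.0, abs=1e-12)

    def test_floating_average_smooths(self):
        ps = generate_price_series(400, seed=1)
        fa = ps.floating_average()
        for sp in SPECIES:
            assert fa[sp].var() < ps.relative_price[sp].var()

    def test_seeded_determinism(self):
        a = generate_price_series(100, seed=9)
        b = generate_price_series(100, seed=9)
        for sp in SPECIES:
            assert np.array_equal(a.relative_price[sp], b.relative_price[sp])

    def test_non_positive_definite_rejected(self):
        corr = default_price_correlation()
        corr.iloc[:, :] = 1.0 - 2.0 * np.eye(len(SPECIES)) * 0  # all ones, singular
        with pytest.raises(ValueError):
            generate_price_series(100, corr, seed=0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            generate_price_series(10, seed=0)


class TestCostTable:
    def test_regen_share_increases_with_age_then_nfi(self):
        ct = CostTable()
        shares = [ct.natural_regen_share("beech", a) for a in (0, 10, 50, 90)]
        assert shares == sorted(shares)
        assert ct.natural_regen_share("beech", 120) == ct.nfi_regen_share["beech"]
        assert all(0 <= s <= 1 for s in shares)

    def test_douglas_fir_first_establishment_is_full_planting(self):
        ct = CostTable()
        assert ct.initial_regen_share("douglas_fir") == 0.0
        assert ct.initial_regen_share("spruce") > 0.0

    def test_scaled_subset(self):
        ct = CostTable().scaled(0.25, {"beech", "oak"})
        base = CostTable()
        assert ct.planting_cost["beech"] == pytest.approx(0.25 * base.planting_cost["beech"])
        assert ct.planting_cost["spruce"] == base.planting_cost["spruce"]
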