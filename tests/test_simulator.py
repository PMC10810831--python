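"""Stand dynamics: hazards, trajectories, determinism, spatial correlation."""

from dataclasses import replace

import numpy as np
import pytest

from forestfolio import ExtremeEventScenario, generate_hazard_model
from forestfolio.simulate import (
    StandPrescription,
    period_hazard,
    rescale_extrapolated,
    simulate_annuity_matrix,
    simulate_stand,
    simulate_unit_standtype,
)
from forestfolio.synthetic import STAND_TYPES


def zero_hazard_models(models):
    return {sp: replace(m, half_life=1e12, mixture_delta=0.0) for sp, m in models.items()}


def certain_hazard_models(models):
    # a half-life far below one decade makes every period's hazard ~1
    return {sp: replace(m, half_life=1e-3, envelope_shift=float("inf")) for sp, m in models.items()}


class TestPeriodHazard:
    def test_constant_survival_means_no_mortality(self, models):
        m = replace(models["spruce"], half_life=1e12)
        assert period_hazard(m, 50.0) == pytest.approx(0.0, abs=1e-9)

    def test_exponential_hazard_is_memoryless(self, models):
        """A Weibull with shape 1 is exponential: the per-decade hazard does
        not depend on stand age."""
        m = replace(models["pine"], shape=1.0, half_life=80.0)
        hazards = [period_hazard(m, a) for a in (0.0, 40.0, 120.0)]
        assert max(hazards) - min(hazards) < 1e-12

    def test_admixture_stabilizes_spruce(self, models):
        mono = period_hazard(models["spruce"], 50.0)
        mixed = period_hazard(models["spruce"], 50.0, admix_share=0.1)
        assert mixed < mono

    def test_vanished_survival_means_certain_loss(self, models):
        m = replace(models["spruce"], half_life=1e-3)
        assert period_hazard(m, 400.0) == 1.0

    def test_negative_age_rejected(self, models):
        with pytest.raises(ValueError):
            period_hazard(models["spruce"], -1.0)


class TestExtrapolationRescale:
    def test_inside_envelope_unchanged(self, models):
        climate = np.array([0.0, 0.0])  # reference climate, score 0
        assert rescale_extrapolated(models["spruce"], climate) is models["spruce"]

    def test_outside_envelope_one_percent_survival(self, models):
        climate = np.array([2.0, -2.0])  # far beyond the spruce envelope
        m = rescale_extrapolated(models["spruce"], climate)
        assert m is not models["spruce"]
        assert float(m.survival(100.0, climate)) == pytest.approx(0.01, abs=1e-6)
        assert float(m.survival(0.0, climate)) == pytest.approx(1.0)

    def test_rescaled_survival_still_monotone(self, models):
        climate = np.array([2.0, -2.0])
        m = rescale_extrapolated(models["spruce"], climate)
        s = m.survival(np.arange(0, 210, 10, dtype=float), climate)
        assert np.all(np.diff(s) <= 1e-15)


class TestSingleStandTrajectory:
    def test_zero_hazard_harvests_exactly_at_rotation(self, enterprise, models, rng):
        pr = StandPrescription(species=("beech",), shares=(1.0,), rotation=100)
        traj = simulate_stand(pr, enterprise.units[0], rng=rng,
                              models=zero_hazard_models(models))
        finals = [r.t for r in traj.records if r.event == "final_harvest"]
        assert finals == [100, 200, 300, 400, 500]
        assert not any(r.event == "salvage_harvest" for r in traj.records)

    def test_certain_hazard_salvages_every_decade(self, enterprise, models, rng):
        pr = StandPrescription(species=("spruce",), shares=(1.0,), rotation=100)
        traj = simulate_stand(pr, enterprise.units[0], rng=rng,
                              models=certain_hazard_models(models))
        salvages = [r for r in traj.records if r.event == "salvage_harvest"]
        assert len(salvages) == 50
        assert all(r.age_at_event == 10 for r in salvages)

    def test_every_removal_is_followed_by_planting(self, enterprise, models, rng):
        pr = StandPrescription(species=("spruce", "beech"), shares=(0.9, 0.1), rotation=90)
        traj = simulate_stand(pr, enterprise.units[1], rng=rng, models=models)
        records = traj.records
        for i, rec in enumerate(records):
            if rec.event in ("final_harvest", "salvage_harvest"):
                assert records[i + 1].event == "planting"
                assert records[i + 1].t == rec.t
        assert records[0].event == "planting" and records[0].t == 0
        assert records[-1].t <= 500

    def test_tidy_export_has_one_row_per_species(self, enterprise, models, rng):
        pr = StandPrescription(species=("spruce", "beech"), shares=(0.9, 0.1), rotation=90)
        traj = simulate_stand(pr, enterprise.units[0], rng=rng, models=models)
        frame = traj.to_frame()
        assert set(frame["species"]) == {"spruce", "beech"}
        assert {"t", "event", "volume_m3_ha", "qmd_cm"} <= set(frame.columns)


class TestVectorizedEngine:
    def test_seeded_determinism(self, enterprise, models, scenarios):
        pr = StandPrescription(species=("spruce",), shares=(1.0,), rotation=90)
        kwargs = dict(scenario=scenarios["baseline"], models=models, n_reps=100, seed=11)
        a = simulate_unit_standtype(enterprise, 0, pr, **kwargs)
        b = simulate_unit_standtype(enterprise, 0, pr, **kwargs)
        assert np.array_equal(a, b)

    def test_mean_of_one_stand_is_that_stand(self, enterprise, models, scenarios):
        """With a single simulated stand the realization is the stand's own
        annuity, so raising the number of stands must reduce variance."""
        pr = StandPrescription(species=("spruce",), shares=(1.0,), rotation=90)
        few = simulate_unit_standtype(
            enterprise, 0, pr, scenario=scenarios["none"], models=models,
            n_reps=400, seed=3, stands_per_1000ha=1.0 / 20.0,  # 1 stand
        )
        many = simulate_unit_standtype(
            enterprise, 0, pr, scenario=scenarios["none"], models=models,
            n_reps=400, seed=3, stands_per_1000ha=1.0,  # ~15 stands
        )
        assert many.var() < few.var()

    def test_extreme_events_correlate_neighboring_units(self, enterprise, models, scenarios):
        """Shared event fields raise the cross-unit correlation of annuity
        realizations relative to the stand-level-only case."""
        pr = StandPrescription(species=("spruce",), shares=(1.0,), rotation=90)
        severe = ExtremeEventScenario("severe", 0.3, scenarios["baseline"].lam * 16,
                                      scenarios["baseline"].radius)
        corr = {}
        for name, sc in (("none", scenarios["none"]), ("events", severe)):
            r0 = simulate_unit_standtype(enterprise, 1, pr, scenario=sc, models=models,
                                         n_reps=2000, seed=5)
            r1 = simulate_unit_standtype(enterprise, 4, pr, scenario=sc, models=models,
                                         n_reps=2000, seed=5)
            corr[name] = np.corrcoef(r0, r1)[0, 1]
        assert corr["events"] > corr["none"]

    def test_conservation_every_cycle_ends_once(self, enterprise, models, scenarios):
        """Over the horizon, removal counts equal planting counts minus the
        stand alive at the end: each planted stand is removed by exactly one
        of final or salvage harvest or survives to the horizon."""
        prescriptions = [
            [StandPrescription(species=st, shares=(1.0,) if len(st) == 1 else (0.9, 0.1),
                               rotation=100) for st in STAND_TYPES[:3]]
            for _ in range(len(enterprise.units))
        ]
        sim = simulate_annuity_matrix(
            enterprise, prescriptions, scenario=scenarios["baseline"], models=models,
            n_reps=50, seed=2,
        )
        for row in sim.summaries:
            for summary in row:
                counts = summary.removal_counts
                assert np.all(counts >= 0)
                assert counts.sum() > 0
                # removals only at ages on the grid up to the rotation
                assert counts.shape[0] == summary.prescription.rotation // 10 + 1

    def test_annuity_matrix_deterministic(self, enterprise, models, scenarios):
        prescriptions = [
            [StandPrescription(species=("spruce",), shares=(1.0,), rotation=90)]
            for _ in range(len(enterprise.units))
        ]
        kwargs = dict(scenario=scenarios["baseline"], models=models, n_reps=60, seed=9)
        a = simulate_annuity_matrix(enterprise, prescriptions, **kwargs)
        b = simulate_annuity_matrix(enterprise, prescriptions, **kwargs)
        assert np.array_equal(a.annuities, b.annuities)
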