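"""Annual-cycle engine: drift, hazards, competing-risk transitions, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import strokesim as ss
from strokesim import engine, policy

from conftest import make_population

NO_ADHERENCE = {s: 0.0 for s in ss.STRATEGIES}


def zero_drift(registry):
    reg = registry
    for name in ("drift_hba1c", "drift_sbp", "drift_lipid", "drift_bmi"):
        reg = reg.with_value(name, 0.0)
    return reg


def zero_hazards(registry):
    reg = zero_drift(registry)
    for name in ("h_stroke_base", "h_mi_base", "h_mortality_base",
                 "h_poststroke_mortality"):
        reg = reg.with_value(name, 0.0)
    return reg


def reference_individual(**overrides):
    """Age-65 female at all hazard reference levels, untreated, no comorbidity."""
    defaults = dict(age=65.0, sex="female", hba1c=7.0, sbp=140.0, dbp=85.0,
                    lipid_ratio=4.0, bmi=27.0, glycemic_level=0, bp_level=0,
                    acei_arb=False, statin="none", aspirin=False,
                    anticoagulant="none")
    defaults.update(overrides)
    return make_population(1, **defaults).to_individuals()[0]


class TestDrift:
    def test_zero_drift_changes_only_age(self, registry):
        reg = zero_drift(registry)
        ind = reference_individual()
        out = engine.update_risk_factors(ind, reg)
        assert out.age == ind.age + 1
        assert (out.hba1c, out.sbp, out.lipid_ratio, out.bmi) == (
            ind.hba1c, ind.sbp, ind.lipid_ratio, ind.bmi)

    def test_linear_drift_accumulates_exactly(self, registry):
        s = 0.17
        reg = registry.with_value("drift_hba1c", s)
        ind = reference_individual()
        k = 7
        for _ in range(k):
            ind = engine.update_risk_factors(ind, reg)
        assert ind.hba1c == pytest.approx(7.0 + k * s)

    def test_weight_program_precedes_drift(self, spec, registry):
        """Year-0 weight-loss adoption cuts BMI by exactly 5% before any drift."""
        pop = make_population(10, bmi=30.0)
        cohort = pop.arrays()
        masks = policy.recommend_masks(cohort, {"weight"}, spec, 0)
        policy.apply_recommendations(
            cohort, masks, {"weight": 1.0},
            np.zeros((10, policy.N_POLICY_SLOTS)), spec, registry)
        assert cohort.bmi == pytest.approx(28.5)


class TestHazards:
    def test_reference_individual_gets_baseline_hazard(self, registry):
        hz = engine.annual_hazards(reference_individual(), registry)
        assert float(hz["stroke"]) == pytest.approx(registry.value("h_stroke_base"))
        assert float(hz["mi"]) == pytest.approx(registry.value("h_mi_base"))
        assert float(hz["death_stroke"]) == 0.0

    def test_sbp_excess_inverts_the_per_decrease_hazard_ratio(self, registry):
        hz_ref = engine.annual_hazards(reference_individual(), registry)
        hz_up = engine.annual_hazards(reference_individual(sbp=150.0), registry)
        expected = float(hz_ref["stroke"]) / registry.value("hr_sbp")
        assert float(hz_up["stroke"]) == pytest.approx(expected)

    def test_aspirin_multiplies_by_one_minus_rrr(self, registry):
        hz_ref = engine.annual_hazards(reference_individual(), registry)
        hz_asp = engine.annual_hazards(reference_individual(aspirin=True), registry)
        assert float(hz_asp["stroke"]) == pytest.approx(
            float(hz_ref["stroke"]) * (1 - registry.value("rrr_aspirin")))

    def test_current_smoking_multiplies_both_event_hazards(self, registry):
        ref = engine.annual_hazards(reference_individual(), registry)
        smk = engine.annual_hazards(reference_individual(smoker=True), registry)
        assert float(smk["stroke"]) == pytest.approx(
            float(ref["stroke"]) * registry.value("h_stroke_smoking_mult"))
        assert float(smk["mi"]) == pytest.approx(
            float(ref["mi"]) * registry.value("h_mi_smoking_mult"))

    def test_noac_protects_only_with_afib(self, registry):
        no_afib = engine.annual_hazards(
            reference_individual(anticoagulant="noac"), registry)
        ref = engine.annual_hazards(reference_individual(), registry)
        assert float(no_afib["stroke"]) == pytest.approx(float(ref["stroke"]))
        afib_noac = engine.annual_hazards(
            reference_individual(afib=True, anticoagulant="noac"), registry)
        afib_only = engine.annual_hazards(
            reference_individual(afib=True), registry)
        assert float(afib_noac["stroke"]) == pytest.approx(
            float(afib_only["stroke"]) * (1 - registry.value("rrr_noac")))

    @given(delta=hst.floats(0.0, 5.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_stroke_hazard_monotone_in_hba1c(self, delta):
        reg = ss.default_registry()
        lo = engine.annual_hazards(reference_individual(hba1c=7.0), reg)
        hi = engine.annual_hazards(reference_individual(hba1c=7.0 + delta), reg)
        assert float(hi["stroke"]) >= float(lo["stroke"])


class TestTransition:
    def test_null_hazards_leave_state_unchanged(self):
        state = np.zeros(1000, dtype=np.int64)
        hz = {k: np.zeros(1000) for k in
              ("stroke", "mi", "death_other", "death_stroke", "case_fatality")}
        rng = np.random.default_rng(0)
        events = engine.transition(state, hz, rng.uniform(size=1000),
                                   rng.uniform(size=1000), rng.uniform(size=1000))
        assert (state == 0).all()
        assert not any(v.any() for v in events.values())

    def test_probability_conservation(self):
        rng = np.random.default_rng(5)
        h = rng.uniform(0, 0.5, size=(200, 4))
        H = h.sum(axis=1)
        p_event = -np.expm1(-H)
        total = p_event * (h / H[:, None]).sum(axis=1) + np.exp(-H)
        assert total == pytest.approx(np.ones(200))

    def test_constant_hazard_matches_exponential_survival(self):
        """10 years at hazard 0.1: cumulative incidence ~ 1 - e^-1."""
        n, h, years = 100_000, 0.1, 10
        state = np.zeros(n, dtype=np.int64)
        hz = {"stroke": np.zeros(n), "mi": np.zeros(n),
              "death_other": np.full(n, h), "death_stroke": np.zeros(n),
              "case_fatality": np.zeros(n)}
        rng = np.random.default_rng(17)
        for _ in range(years):
            engine.transition(state, hz, rng.uniform(size=n),
                              rng.uniform(size=n), rng.uniform(size=n))
        p = 1 - np.exp(-h * years)
        se = np.sqrt(p * (1 - p) / n)
        assert abs((state > 0).mean() - p) < 2 * se

    def test_equal_hazards_split_causes_evenly(self):
        n = 100_000
        state = np.zeros(n, dtype=np.int64)
        hz = {"stroke": np.full(n, 0.2), "mi": np.full(n, 0.2),
              "death_other": np.zeros(n), "death_stroke": np.zeros(n),
              "case_fatality": np.zeros(n)}
        rng = np.random.default_rng(23)
        ev = engine.transition(state, hz, rng.uniform(size=n),
                               rng.uniform(size=n), rng.uniform(size=n))
        n_events = ev["stroke"].sum() + ev["mi"].sum()
        frac = ev["stroke"].sum() / n_events
        se = np.sqrt(0.25 / n_events)
        assert abs(frac - 0.5) < 2 * se

    def test_dead_states_are_absorbing(self):
        state = np.full(100, engine.S_DEAD_OTHER, dtype=np.int64)
        hz = {k: np.full(100, 5.0) for k in
              ("stroke", "mi", "death_other", "death_stroke")}
        hz["case_fatality"] = np.full(100, 1.0)
        rng = np.random.default_rng(2)
        events = engine.transition(state, hz, rng.uniform(size=100),
                                   rng.uniform(size=100), rng.uniform(size=100))
        assert (state == engine.S_DEAD_OTHER).all()
        assert not any(v.any() for v in events.values())

    def test_scalar_transition_wrapper(self, registry):
        ind = reference_individual()
        hz = engine.annual_hazards(ind, registry)
        new_state, events = engine.transition_individual(
            ind, hz, np.random.default_rng(0))
        assert new_state in ss.population.STATE_NAMES
        assert set(events) == {"stroke", "mi", "death_stroke", "death_other"}


class TestSimulateIndividual:
    def test_null_dynamics_runs_full_horizon(self, spec, registry):
        reg = zero_hazards(registry)
        ind = reference_individual(hba1c=6.0, sbp=120.0, dbp=70.0, bmi=24.0)
        records = engine.simulate_individual(ind, NO_ADHERENCE, spec, reg,
                                             horizon=10, seed=1)
        assert len(records) == 10
        assert all(r.state == "stroke_free" for r in records)
        assert not any(r.stroke_event or r.mi_event for r in records)

    def test_death_truncates_records(self, spec, registry):
        reg = zero_hazards(registry).with_value("h_mortality_base", 50.0)
        ind = reference_individual()
        records = engine.simulate_individual(ind, NO_ADHERENCE, spec, reg,
                                             horizon=10, seed=3)
        assert len(records) == 1
        assert records[0].state == "dead_other"
        assert records[0].death_cause == "other"

    def test_deterministic_given_seed(self, spec, registry):
        ind = reference_individual(afib=True)
        a = engine.simulate_individual(ind, NO_ADHERENCE, spec, registry,
                                       horizon=10, seed=11)
        b = engine.simulate_individual(ind, NO_ADHERENCE, spec, registry,
                                       horizon=10, seed=11)
        assert a == b

    def test_stroke_routes_through_acute_then_post(self, spec, registry):
        """A certain nonfatal stroke in year 0 leaves acute state, then the
        post-stroke state afterwards, with recurrence-free survival possible."""
        reg = zero_hazards(registry).with_value("h_stroke_base", 50.0)
        reg = reg.with_value("p_stroke_case_fatality", 0.0)
        reg = reg.with_value("h_stroke_recurrence_mult", 0.0)
        ind = reference_individual()
        records = engine.simulate_individual(ind, NO_ADHERENCE, spec, reg,
                                             horizon=3, seed=5)
        assert records[0].state == "acute_stroke" and records[0].stroke_event
        assert records[1].state == "post_stroke" and records[1].in_post
        assert records[2].state == "post_stroke"


class TestSimulateCohort:
    def test_common_random_numbers_pair_identical_policies(self, spec, registry):
        pop = ss.generate_population(ss.PopulationConfig(n=150), seed=4, spec=spec)
        costs = ss.CostSchedule.from_registry(registry)
        utils = ss.UtilitySchedule.from_registry(registry)
        u = engine.draw_uniforms(9, 0, 0, 150, 10)
        out1 = engine.simulate_cohort(pop.arrays(), NO_ADHERENCE, spec, registry,
                                      10, u, costs, utils)
        out2 = engine.simulate_cohort(pop.arrays(), NO_ADHERENCE, spec, registry,
                                      10, u, costs, utils)
        for k in out1:
            np.testing.assert_array_equal(out1[k], out2[k])

    def test_survival_curve_matches_exponential_oracle(self, spec, registry):
        """Constant total hazard H: fraction alive after t years ~ e^(-Ht)."""
        h = 0.05
        reg = zero_hazards(registry)
        reg = reg.with_value("h_mortality_base", h)
        reg = reg.with_value("h_mortality_age_slope", 0.0)
        reg = reg.with_value("h_mortality_t2d_mult", 1.0)
        n, t = 100_000, 5
        pop = make_population(n, sex="female", age=65.0, hba1c=7.0, sbp=140.0,
                              lipid_ratio=4.0, bmi=27.0, bp_level=0,
                              acei_arb=False, glycemic_level=0)
        costs = ss.CostSchedule.from_registry(reg)
        utils = ss.UtilitySchedule.from_registry(reg)
        cohort = pop.arrays()
        u = engine.draw_uniforms(21, 0, 0, n, t)
        engine.simulate_cohort(cohort, NO_ADHERENCE, spec, reg, t, u, costs, utils)
        alive = (cohort.state_code < engine.S_DEAD_STROKE).mean()
        expected = np.exp(-h * t)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(alive - expected) < 2 * se
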