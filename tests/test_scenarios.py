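"""Scenario catalog, paired runs, comparison, and sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

import strokesim as ss
from strokesim import scenarios as scen
from strokesim.config import ConfigError, ScenarioSpec
from strokesim.registry import RegistryError


@pytest.fixture(scope="module")
def setup(registry, spec):
    cfg = ss.PopulationConfig(n=250)
    pop = ss.generate_population(cfg, seed=13, spec=spec)
    imputed = ss.apply_missingness_and_impute(pop, cfg, M=2, seed=13, spec=spec)
    adherence = ss.calibrate_status_quo(pop, cfg, spec, registry, seed=13)
    return cfg, imputed, adherence


class TestScaleAdherence:
    def test_no_improvement_keeps_status_quo(self):
        assert scen.scale_adherence(0.3, 0.0) == 0.3

    def test_full_improvement_reaches_one(self):
        assert scen.scale_adherence(0.3, 1.0) == 1.0

    def test_half_improvement_closes_half_the_gap(self):
        assert scen.scale_adherence(0.5, 0.5) == 0.75

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            scen.scale_adherence(1.5, 0.5)


class TestCatalog:
    def test_eleven_scenarios_with_unique_names(self):
        catalog = scen.build_catalog()
        assert len(catalog) == 11
        names = [c.name for c in catalog]
        assert len(set(names)) == 11
        assert names[0] == scen.STATUS_QUO

    def test_default_combo_membership(self):
        catalog = {c.name: c for c in scen.build_catalog()}
        assert catalog["multiple_preventions_1"].enhanced_strategies == frozenset(
            {"bp", "statin", "aspirin", "smoking"})
        assert catalog["multiple_preventions_2"].enhanced_strategies == frozenset(
            {"bp", "statin", "aspirin", "smoking", "weight"})
        assert catalog["all_preventions"].enhanced_strategies == frozenset(
            ss.STRATEGIES)

    def test_empty_enhancement_equals_status_quo_adherence(self):
        sq = {s: 0.2 for s in ss.STRATEGIES}
        spec_ = ScenarioSpec(name="noop")
        assert spec_.adherence(sq) == sq

    def test_improvement_fraction_one_is_full_enhancement(self):
        sq = {s: 0.2 for s in ss.STRATEGIES}
        full = ScenarioSpec(name="a", enhanced_strategies=frozenset({"bp"}))
        partial = ScenarioSpec(name="b", enhanced_strategies=frozenset({"bp"}),
                               improvement_fraction=1.0)
        assert full.adherence(sq) == partial.adherence(sq)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioSpec(name="x", enhanced_strategies=frozenset({"yoga"}))

    def test_derive_combos_from_single_strategy_results(self):
        ref = ss.reference_basecase_table()
        results = {}
        name_of = dict(scen.SINGLE_SCENARIO_NAMES)
        for s, nm in name_of.items():
            row = ref[ref.scenario == nm].iloc[0]
            dc = row.incremental_cost_billions * 1e9
            dq = row.incremental_qalys_thousands * 1e3
            r = ss.icer(dc, dq)
            results[s] = ss.CEAResult(
                scenario=nm, strokes_averted=0, stroke_deaths_averted=0,
                mi_averted=0, delta_cost=dc, delta_qaly=dq, icer=r,
                nhb=0.0, label=ss.classify_cost_effectiveness(r))
        c1, c2 = scen.derive_combos(results)
        assert set(c1) == {"bp", "statin", "aspirin", "smoking"}
        assert set(c2) == {"bp", "statin", "aspirin", "smoking", "weight"}


class TestRun:
    def test_null_contrast_is_exactly_zero(self, setup, registry, spec):
        """A scenario whose adherence equals the status quo reproduces it
        bit-for-bit under common random numbers."""
        _, imputed, adherence = setup
        clone = ScenarioSpec(name="clone",
                             adherence_overrides=dict(adherence))
        catalog = [ScenarioSpec(name=scen.STATUS_QUO), clone]
        result = scen.run(imputed, catalog, registry, spec, adherence, R=3,
                          seed=5)
        res = scen.compare(result, "clone")
        assert res.delta_cost == 0.0 and res.delta_qaly == 0.0
        assert res.strokes_averted == 0.0 and res.nhb == 0.0
        assert res.ui["incremental_qalys"] == (0.0, 0.0)

    def test_doubling_weights_doubles_national_totals(self, registry, spec):
        cfg = ss.PopulationConfig(n=120)
        pop = ss.generate_population(cfg, seed=2, spec=spec)
        pop2 = ss.Population(pop.df.assign(weight=pop.df.weight * 2))
        catalog = [ScenarioSpec(name=scen.STATUS_QUO)]
        adh = {s: 0.0 for s in ss.STRATEGIES}
        r1 = scen.run(ss.ImputedPopulationSet([pop]), catalog, registry, spec,
                      adh, R=2, seed=3)
        r2 = scen.run(ss.ImputedPopulationSet([pop2]), catalog, registry, spec,
                      adh, R=2, seed=3)
        for col in ("strokes", "cost", "qaly"):
            np.testing.assert_allclose(r2.data[col], 2 * r1.data[col], rtol=1e-12)

    def test_reproducible_byte_for_byte(self, setup, registry, spec, tmp_path):
        _, imputed, adherence = setup
        catalog = scen.build_catalog()[:3]
        paths = []
        for i in (1, 2):
            res = scen.run(imputed, catalog, registry, spec, adherence, R=2,
                           seed=77)
            p = tmp_path / f"run{i}.csv"
            res.to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_enhanced_bp_lowers_pressure_and_strokes(self, registry, spec):
        """Full BP-escalation adherence must lower mean SBP and the stroke
        count relative to the status quo under a protective SBP hazard ratio."""
        cfg = ss.PopulationConfig(n=4000)
        pop = ss.generate_population(cfg, seed=21, spec=spec)
        imputed = ss.ImputedPopulationSet([pop])
        adh = {s: 0.0 for s in ss.STRATEGIES}
        catalog = [ScenarioSpec(name=scen.STATUS_QUO),
                   ScenarioSpec(name="bp_control",
                                enhanced_strategies=frozenset({"bp"}))]
        result = scen.run(imputed, catalog, registry, spec, adh, R=3, seed=9)
        res = scen.compare(result, "bp_control")
        assert res.strokes_averted > 0
        # direct mean-SBP check after a few simulated years
        from strokesim import engine
        costs = ss.CostSchedule.from_registry(registry)
        utils = ss.UtilitySchedule.from_registry(registry)
        u = engine.draw_uniforms(9, 0, 0, 4000, 5)
        sq_cohort, bp_cohort = pop.arrays(), pop.arrays()
        engine.simulate_cohort(sq_cohort, adh, spec, registry, 5, u, costs, utils)
        engine.simulate_cohort(bp_cohort, {**adh, "bp": 1.0}, spec, registry, 5,
                               u, costs, utils)
        assert bp_cohort.sbp.mean() < sq_cohort.sbp.mean()

    def test_paired_design_tightens_uncertainty_intervals(self, registry, spec):
        """Common random numbers must give narrower incremental-outcome
        intervals than independently seeded status-quo/scenario runs."""
        cfg = ss.PopulationConfig(n=300)
        pop = ss.generate_population(cfg, seed=31, spec=spec)
        imputed = ss.ImputedPopulationSet([pop])
        adh = {s: 0.0 for s in ss.STRATEGIES}
        catalog = [ScenarioSpec(name=scen.STATUS_QUO),
                   ScenarioSpec(name="bp_control",
                                enhanced_strategies=frozenset({"bp"}))]
        paired = scen.run(imputed, catalog, registry, spec, adh, R=12, seed=1)
        lo, hi = scen.compare(paired, "bp_control").ui["incremental_qalys"]
        width_paired = hi - lo
        # independent: subtract status-quo replicates simulated under another seed
        indep = scen.run(imputed, catalog, registry, spec, adh, R=12, seed=2)
        sq = indep.scenario(scen.STATUS_QUO)["qaly"].to_numpy()
        sc = paired.scenario("bp_control")["qaly"].to_numpy()
        lo2, hi2 = ss.uncertainty_interval(sc - sq)
        assert width_paired < (hi2 - lo2)

    def test_mismatched_designs_rejected(self, setup, registry, spec):
        _, imputed, adherence = setup
        catalog = [ScenarioSpec(name=scen.STATUS_QUO)]
        r1 = scen.run(imputed, catalog, registry, spec, adherence, R=2, seed=1)
        r2 = scen.run(imputed, [ScenarioSpec(name="other")], registry, spec,
                      adherence, R=3, seed=1)
        merged = scen.SimulationResult(
            data=pd.concat([r1.data, r2.data], ignore_index=True))
        with pytest.raises(ConfigError, match="mismatched"):
            scen.compare(merged, "other")

    def test_self_comparison_is_identically_zero(self, setup, registry, spec):
        _, imputed, adherence = setup
        catalog = [ScenarioSpec(name=scen.STATUS_QUO)]
        result = scen.run(imputed, catalog, registry, spec, adherence, R=2, seed=4)
        res = scen.compare(result, scen.STATUS_QUO)
        assert res.delta_cost == 0.0 and res.nhb == 0.0

    def test_results_table_shape_and_rounding(self, setup, registry, spec):
        _, imputed, adherence = setup
        catalog = scen.build_catalog()[:4]
        result = scen.run(imputed, catalog, registry, spec, adherence, R=2, seed=6)
        table = scen.results_table(scen.compare_all(result, catalog))
        assert list(table["scenario"]) == [c.name for c in catalog[1:]]
        assert {"incremental_cost_billions", "nhb_thousands",
                "icer", "classification"} <= set(table.columns)


class TestOwsa:
    def test_degenerate_bounds_reproduce_base_case(self, setup, registry, spec):
        _, imputed, adherence = setup
        catalog = [ScenarioSpec(name=scen.STATUS_QUO),
                   ScenarioSpec(name="bp_control",
                                enhanced_strategies=frozenset({"bp"}))]
        pinned = registry.with_value("hr_sbp", registry.value("hr_sbp"))
        # collapse the bounds to base
        import dataclasses
        p = pinned["hr_sbp"]
        pinned.params["hr_sbp"] = dataclasses.replace(p, low=p.base, high=p.base)
        base = scen.compare(
            scen.run(imputed, catalog, pinned, spec, adherence, R=2, seed=8),
            "bp_control")
        table = scen.run_owsa(imputed, catalog, pinned, spec, adherence, R=2,
                              seed=8, parameters=[])
        # no swingable parameters: empty table is the degenerate base case
        assert table.empty
        for bound in ("low", "high"):
            res = scen.compare(
                scen.run(imputed, catalog, pinned.at_bound("hr_sbp", bound),
                         spec, adherence, R=2, seed=8), "bp_control")
            assert res.delta_cost == base.delta_cost
            assert res.delta_qaly == base.delta_qaly

    def test_raising_medication_cost_does_not_lower_icer(self, setup, registry,
                                                         spec):
        _, imputed, adherence = setup
        catalog = [ScenarioSpec(name=scen.STATUS_QUO),
                   ScenarioSpec(name="noac_treatment",
                                enhanced_strategies=frozenset({"anticoagulant"}))]
        table = scen.run_owsa(imputed, catalog, registry, spec, adherence, R=2,
                              seed=12, parameters=["cost_noac"])
        lo = table[(table.bound == "low")].iloc[0]
        hi = table[(table.bound == "high")].iloc[0]
        assert hi.incremental_cost > lo.incremental_cost
        if lo.icer_value is not None and hi.icer_value is not None:
            assert hi.icer_value >= lo.icer_value

    def test_parameter_without_bounds_rejected(self, setup, registry, spec):
        _, imputed, adherence = setup
        with pytest.raises(RegistryError, match="bounds"):
            scen.run_owsa(imputed, [ScenarioSpec(name=scen.STATUS_QUO)],
                          registry, spec, adherence, R=1, seed=1,
                          parameters=["ref_sbp"])

    def test_insulin_price_variant_row_present(self, setup, registry, spec):
        _, imputed, adherence = setup
        catalog = [ScenarioSpec(name=scen.STATUS_QUO),
                   ScenarioSpec(name="hba1c_control",
                                enhanced_strategies=frozenset({"glycemic"}))]
        table = scen.run_owsa(imputed, catalog, registry, spec, adherence, R=2,
                              seed=3, parameters=[], include_insulin_variant=True)
        assert set(table.parameter) == {"insulin_price"}
        assert list(table.bound.unique()) == ["reduced"]
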