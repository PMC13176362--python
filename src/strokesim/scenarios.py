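"""Scenario catalog, simulation orchestration, and national aggregation.

The catalog holds the status quo plus ten enhanced-implementation scenarios:
one per prevention strategy, two guideline "combination" scenarios whose
membership is config-declared (defaulting to the strategies found
individually cost-saving or (highly) cost-effective), and full enhancement of
all seven.  Enhancement means raising a strategy's adherence to 1.0 (or
partially, closing fraction f of the gap).  Runs are organized as imputations
x replicates with common random numbers shared across scenarios, so every
incremental outcome is a paired contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import econ, engine
from .config import (DEFAULT_COMBO1, DEFAULT_COMBO2, STRATEGIES, ConfigError,
                     GuidelineSpec, ScenarioSpec)
from .population import ImputedPopulationSet
from .registry import ParameterRegistry, RegistryError

__all__ = [
    "SimulationResult",
    "scale_adherence",
    "build_catalog",
    "derive_combos",
    "run",
    "compare",
    "compare_all",
    "results_table",
    "run_owsa",
]

#: scenario names for the single-strategy enhancements, in Table order
SINGLE_SCENARIO_NAMES = {
    "glycemic": "hba1c_control",
    "bp": "bp_control",
    "statin": "statin_treatment",
    "aspirin": "aspirin_treatment",
    "smoking": "smoking_cessation",
    "weight": "weight_loss",
    "anticoagulant": "noac_treatment",
}
STATUS_QUO = "status_quo"


def scale_adherence(a_status_quo: float, f: float) -> float:
    """Partial implementation: close fraction ``f`` of the gap to full adherence."""
    if not (0 <= a_status_quo <= 1):
        raise ConfigError(f"adherence must be in [0, 1], got {a_status_quo}")
    if not (0 <= f <= 1):
        raise ConfigError(f"improvement fraction must be in [0, 1], got {f}")
    return a_status_quo + f * (1.0 - a_status_quo)


def build_catalog(combo1: tuple[str, ...] = DEFAULT_COMBO1,
                  combo2: tuple[str, ...] = DEFAULT_COMBO2,
                  horizon: int = 10, lam: float = 100_000.0,
                  highly_ce_cut: float = 50_000.0,
                  improvement_fraction: float | None = None
                  ) -> list[ScenarioSpec]:
    """Status quo + ten enhanced scenarios."""
    common = dict(horizon=horizon, lam=lam, highly_ce_cut=highly_ce_cut)
    catalog = [ScenarioSpec(name=STATUS_QUO, **common)]
    for s in STRATEGIES:
        catalog.append(ScenarioSpec(
            name=SINGLE_SCENARIO_NAMES[s], enhanced_strategies=frozenset({s}),
            improvement_fraction=improvement_fraction, **common))
    catalog.append(ScenarioSpec(
        name="multiple_preventions_1", enhanced_strategies=frozenset(combo1),
        improvement_fraction=improvement_fraction, **common))
    catalog.append(ScenarioSpec(
        name="multiple_preventions_2", enhanced_strategies=frozenset(combo2),
        improvement_fraction=improvement_fraction, **common))
    catalog.append(ScenarioSpec(
        name="all_preventions", enhanced_strategies=frozenset(STRATEGIES),
        improvement_fraction=improvement_fraction, **common))
    return catalog


def derive_combos(single_results: dict[str, econ.CEAResult],
                  highly_ce_cut: float = 50_000.0, lam: float = 100_000.0
                  ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Recompute combination membership from single-strategy results:
    combo 1 = cost-saving or ICER < the highly-cost-effective cut, combo 2 =
    cost-saving or ICER < the cost-effectiveness threshold."""
    c1, c2 = [], []
    for s in STRATEGIES:
        res = single_results.get(s)
        if res is None:
            continue
        r = res.icer
        saving = r.kind == "cost_saving"
        ratio = r.value if r.kind == "ratio" else np.inf
        if saving or ratio < highly_ce_cut:
            c1.append(s)
        if saving or ratio < lam:
            c2.append(s)
    return tuple(c1), tuple(c2)


@dataclass
class SimulationResult:
    """Weighted national totals per scenario x imputation x replicate."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def scenario(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["scenario"] == name]
        if sub.empty:
            raise ConfigError(f"no results for scenario {name!r}")
        return sub

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")


def run(populations: ImputedPopulationSet, catalog: list[ScenarioSpec],
        registry: ParameterRegistry, spec: GuidelineSpec,
        status_quo_adherence: dict[str, float], R: int, seed: int,
        discount_rate: float = 0.03, insulin: str = "standard"
        ) -> SimulationResult:
    """Simulate every catalog scenario over M imputations x R replicates.

    Replicate streams are keyed by (seed, imputation, replicate) and shared
    across scenarios (common random numbers), so a scenario whose effective
    adherence equals the status quo reproduces it exactly.  Deterministic in
    all arguments.
    """
    if R < 1:
        raise ConfigError(f"R must be >= 1, got {R}")
    names = [c.name for c in catalog]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate scenario names in catalog")
    costs = econ.CostSchedule.from_registry(registry, insulin=insulin)
    utils = econ.UtilitySchedule.from_registry(registry)
    adherence_by_scenario = {c.name: c.adherence(status_quo_adherence) for c in catalog}
    max_horizon = max(c.horizon for c in catalog)

    rows = []
    for m, pop in enumerate(populations):
        base = pop.arrays()
        w = base.weight
        for r in range(R):
            uniforms = engine.draw_uniforms(seed, m, r, base.n, max_horizon)
            for scen in catalog:
                cohort = base.copy()
                totals = engine.simulate_cohort(
                    cohort, adherence_by_scenario[scen.name], spec, registry,
                    scen.horizon, uniforms, costs, utils, discount_rate)
                rows.append({
                    "scenario": scen.name, "imputation": m, "replicate": r,
                    "strokes": float(w @ totals["strokes"]),
                    "stroke_deaths": float(w @ totals["stroke_deaths"]),
                    "mi_events": float(w @ totals["mi_events"]),
                    "cost": float(w @ totals["cost"]),
                    "qaly": float(w @ totals["qaly"]),
                })
    data = pd.DataFrame(rows)
    meta = {"seed": int(seed), "n": int(populations[0].df.shape[0]),
            "M": populations.M, "R": int(R),
            "registry_version": registry.version,
            "discount_rate": discount_rate, "insulin": insulin}
    return SimulationResult(data=data, meta=meta)


_DELTA_KEYS = ("strokes_averted", "stroke_deaths_averted", "mi_averted",
               "incremental_cost", "incremental_qalys", "nhb")


def compare(result: SimulationResult, scenario: str,
            status_quo: str = STATUS_QUO, lam: float = 100_000.0,
            highly_ce_cut: float = 50_000.0) -> econ.CEAResult:
    """Paired incremental outcomes of ``scenario`` vs the status quo.

    Point estimates average the per-(imputation, replicate) paired deltas;
    95% uncertainty intervals pool the replicate deltas across imputations.
    """
    keys = ["imputation", "replicate"]
    sc = result.scenario(scenario).set_index(keys).sort_index()
    sq = result.scenario(status_quo).set_index(keys).sort_index()
    if not sc.index.equals(sq.index):
        raise ConfigError(
            f"scenario {scenario!r} and {status_quo!r} have mismatched "
            "imputation/replicate designs")
    deltas = pd.DataFrame({
        "strokes_averted": sq["strokes"] - sc["strokes"],
        "stroke_deaths_averted": sq["stroke_deaths"] - sc["stroke_deaths"],
        "mi_averted": sq["mi_events"] - sc["mi_events"],
        "incremental_cost": sc["cost"] - sq["cost"],
        "incremental_qalys": sc["qaly"] - sq["qaly"],
    })
    deltas["nhb"] = deltas["incremental_qalys"] - deltas["incremental_cost"] / lam
    mean = deltas.mean()
    icer_res = econ.icer(float(mean["incremental_cost"]),
                         float(mean["incremental_qalys"]))
    ui = {}
    if len(deltas) >= 2:
        ui = {k: econ.uncertainty_interval(deltas[k].to_numpy())
              for k in _DELTA_KEYS}
    return econ.CEAResult(
        scenario=scenario,
        strokes_averted=float(mean["strokes_averted"]),
        stroke_deaths_averted=float(mean["stroke_deaths_averted"]),
        mi_averted=float(mean["mi_averted"]),
        delta_cost=float(mean["incremental_cost"]),
        delta_qaly=float(mean["incremental_qalys"]),
        icer=icer_res,
        nhb=econ.nhb(float(mean["incremental_qalys"]),
                     float(mean["incremental_cost"]), lam),
        label=econ.classify_cost_effectiveness(icer_res, highly_ce_cut, lam),
        ui=ui,
    )


def compare_all(result: SimulationResult, catalog: list[ScenarioSpec],
                lam: float = 100_000.0, highly_ce_cut: float = 50_000.0
                ) -> list[econ.CEAResult]:
    return [compare(result, c.name, lam=lam, highly_ce_cut=highly_ce_cut)
            for c in catalog if c.name != STATUS_QUO]


def results_table(results: list[econ.CEAResult]) -> pd.DataFrame:
    """Report table: events in thousands, costs in billions, NHB/QALYs rounded
    to the nearest thousand, ICER as a dollar figure or dominance label."""
    rows = []
    for res in results:
        rows.append({
            "scenario": res.scenario,
            "strokes_averted_thousands": round(res.strokes_averted / 1e3, 1),
            "stroke_deaths_averted_thousands": round(res.stroke_deaths_averted / 1e3, 1),
            "incremental_cost_billions": round(res.delta_cost / 1e9, 1),
            "incremental_qalys_thousands": round(res.delta_qaly / 1e3),
            "nhb_thousands": round(res.nhb / 1e3),
            "icer": str(res.icer),
            "classification": res.label,
            "strokes_averted_ui": res.ui.get("strokes_averted"),
            "incremental_cost_ui": res.ui.get("incremental_cost"),
            "incremental_qalys_ui": res.ui.get("incremental_qalys"),
            "nhb_ui": res.ui.get("nhb"),
        })
    return pd.DataFrame(rows)


def run_owsa(populations: ImputedPopulationSet, catalog: list[ScenarioSpec],
             registry: ParameterRegistry, spec: GuidelineSpec,
             status_quo_adherence: dict[str, float], R: int, seed: int,
             parameters: list[str], discount_rate: float = 0.03,
             lam: float = 100_000.0, highly_ce_cut: float = 50_000.0,
             include_insulin_variant: bool = False) -> pd.DataFrame:
    """One-way sensitivity analysis: re-run the full comparison with each
    named parameter at its lower and upper bound, all else at base.

    Optionally appends the reduced-insulin-price cost variant.  Returns one
    row per (parameter, bound, scenario).
    """
    for p in parameters:
        if not registry.has_bounds(p):
            raise RegistryError(f"parameter {p!r} has no low/high bounds for OWSA")
    rows = []

    def _one(label: str, bound: str, reg: ParameterRegistry, insulin: str) -> None:
        result = run(populations, catalog, reg, spec, status_quo_adherence,
                     R, seed, discount_rate, insulin=insulin)
        for res in compare_all(result, catalog, lam=lam,
                               highly_ce_cut=highly_ce_cut):
            row = {"parameter": label, "bound": bound, **res.to_row()}
            rows.append(row)

    for p in parameters:
        for bound in ("low", "high"):
            _one(p, bound, registry.at_bound(p, bound), "standard")
    if include_insulin_variant:
        _one("insulin_price", "reduced", registry, "reduced")
    return pd.DataFrame(rows)
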