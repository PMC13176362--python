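"""Health-economic calculus: cost and QALY accrual, discounting, ICER and NHB.

Costs are 2022 U.S. dollars from a health-system/payer perspective; utilities
are in [0, 1] with additive decrements floored at zero.  Discounting uses the
convention t = 0 for the first simulation year (the first year is
undiscounted).  The incremental cost-effectiveness ratio (ICER) carries a
dominance classification: an intervention that saves money and gains QALYs is
"cost saving" and one that costs more and loses QALYs is "dominated"; neither
has a meaningful ratio.  Net health benefit at willingness-to-pay threshold
lambda is NHB = dQALY - dCost / lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import ParameterRegistry

__all__ = [
    "CostSchedule",
    "UtilitySchedule",
    "ICERResult",
    "CEAResult",
    "discount",
    "cost_of_year",
    "utility_of_year",
    "accrue",
    "icer",
    "nhb",
    "uncertainty_interval",
    "classify_cost_effectiveness",
]


@dataclass(frozen=True)
class CostSchedule:
    """Annual and one-time costs (2022 USD)."""

    glycemic_rung: tuple[float, ...]  # rungs 0..4
    bp_per_rung: float
    statin_moderate: float
    statin_high: float
    aspirin: float
    noac: float
    warfarin: float
    stroke_acute: float
    poststroke_annual: float
    mi_event: float
    death: float
    smoking_program: float
    weight_program: float

    @classmethod
    def from_registry(cls, reg: ParameterRegistry, insulin: str = "standard",
                      bound: str | None = None) -> "CostSchedule":
        """Build from registry values; ``insulin='reduced'`` swaps in the
        post-2023 reduced insulin list prices."""
        v = reg.value if bound is None else (lambda name: reg.bound(name, bound))
        suffix = "_reduced" if insulin == "reduced" else ""
        if insulin not in ("standard", "reduced"):
            raise ValueError(f"insulin variant must be standard/reduced, got {insulin!r}")
        rungs = [v("cost_glycemic_r0"), v("cost_glycemic_r1"), v("cost_glycemic_r2"),
                 v(f"cost_glycemic_r3{suffix}"), v(f"cost_glycemic_r4{suffix}")]
        return cls(
            glycemic_rung=tuple(rungs),
            bp_per_rung=v("cost_bp_per_rung"),
            statin_moderate=v("cost_statin_moderate"),
            statin_high=v("cost_statin_high"),
            aspirin=v("cost_aspirin"),
            noac=v("cost_noac"),
            warfarin=v("cost_warfarin"),
            stroke_acute=v("cost_stroke_acute"),
            poststroke_annual=v("cost_poststroke_annual"),
            mi_event=v("cost_mi_event"),
            death=v("cost_death"),
            smoking_program=v("cost_smoking_program"),
            weight_program=v("cost_weight_program"),
        )


@dataclass(frozen=True)
class UtilitySchedule:
    """Baseline utility and additive decrements."""

    baseline: float
    acute_stroke: float
    poststroke: float
    post_mi: float
    insulin_basal: float
    insulin_intensive: float
    hypo_episode: float

    @classmethod
    def from_registry(cls, reg: ParameterRegistry) -> "UtilitySchedule":
        return cls(
            baseline=reg.value("u_baseline"),
            acute_stroke=reg.value("du_acute_stroke"),
            poststroke=reg.value("du_poststroke"),
            post_mi=reg.value("du_post_mi"),
            insulin_basal=reg.value("du_insulin_basal"),
            insulin_intensive=reg.value("du_insulin_intensive"),
            hypo_episode=reg.value("du_hypo_episode"),
        )


# ------------------------------------------------------------------ accrual
def discount(stream, rate: float) -> float:
    """Present value of a per-year stream; the first year is undiscounted."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    s = np.asarray(stream, dtype=float)
    t = np.arange(s.shape[-1])
    return float(np.sum(s * (1.0 + rate) ** -t, axis=-1))


def cost_of_year(*, alive_at_start, glycemic_level, bp_level, statin_code,
                 aspirin, anticoag_code, in_post, stroke_event, mi_event,
                 died, attended_smoking, attended_weight,
                 costs: CostSchedule) -> np.ndarray:
    """Total cost accrued this year per person (vectorized; scalars broadcast).

    Medication costs reflect the treatment state after this year's policy
    adoption; individuals dying within the year still accrue their medication
    and event costs plus the one-time death cost.  Individuals already dead at
    the start of the year accrue nothing.
    """
    alive = np.asarray(alive_at_start, dtype=bool)
    rung = np.asarray(glycemic_level)
    med = np.asarray(costs.glycemic_rung)[rung]
    med = med + costs.bp_per_rung * np.asarray(bp_level)
    med = med + np.asarray([0.0, costs.statin_moderate, costs.statin_high])[
        np.asarray(statin_code)]
    med = med + costs.aspirin * np.asarray(aspirin, dtype=float)
    med = med + np.asarray([0.0, costs.warfarin, costs.noac])[np.asarray(anticoag_code)]
    total = med
    total = total + costs.poststroke_annual * np.asarray(in_post, dtype=float)
    total = total + costs.stroke_acute * np.asarray(stroke_event, dtype=float)
    total = total + costs.mi_event * np.asarray(mi_event, dtype=float)
    total = total + costs.death * np.asarray(died, dtype=float)
    total = total + costs.smoking_program * np.asarray(attended_smoking, dtype=float)
    total = total + costs.weight_program * np.asarray(attended_weight, dtype=float)
    return np.where(alive, total, 0.0)


def utility_of_year(*, alive_at_start, died, in_post, stroke_event, mi_history,
                    glycemic_level, hypo_episodes,
                    utils: UtilitySchedule) -> np.ndarray:
    """Health utility experienced this year per person.

    The death year contributes zero utility.  A recurrent stroke in a
    post-stroke year applies the (larger) acute decrement, not both.
    """
    alive = np.asarray(alive_at_start, dtype=bool) & ~np.asarray(died, dtype=bool)
    stroke_event = np.asarray(stroke_event, dtype=bool)
    dec = np.where(stroke_event, utils.acute_stroke,
                   np.where(np.asarray(in_post, dtype=bool), utils.poststroke, 0.0))
    dec = dec + utils.post_mi * np.asarray(mi_history, dtype=float)
    rung = np.asarray(glycemic_level)
    dec = dec + np.where(rung == 4, utils.insulin_intensive,
                         np.where(rung == 3, utils.insulin_basal, 0.0))
    dec = dec + utils.hypo_episode * np.asarray(hypo_episodes, dtype=float)
    u = np.clip(utils.baseline - dec, 0.0, 1.0)
    return np.where(alive, u, 0.0)


def accrue(records, costs: CostSchedule, utils: UtilitySchedule,
           rate: float) -> tuple[float, float]:
    """Discounted (cost, QALY) totals for one individual's annual records.

    Recomputes year costs and utilities from the recorded states, events, and
    treatment levels through the same helpers the simulation engine uses.
    """
    if not records:
        return 0.0, 0.0
    def arr(name, dtype=float):
        return np.asarray([getattr(r, name) for r in records], dtype=dtype)

    died = arr("died_this_year", bool)
    cost = cost_of_year(
        alive_at_start=np.ones(len(records), dtype=bool),
        glycemic_level=arr("glycemic_level", int), bp_level=arr("bp_level", int),
        statin_code=arr("statin_code", int), aspirin=arr("aspirin", bool),
        anticoag_code=arr("anticoag_code", int), in_post=arr("in_post", bool),
        stroke_event=arr("stroke_event", bool), mi_event=arr("mi_event", bool),
        died=died, attended_smoking=arr("attended_smoking", bool),
        attended_weight=arr("attended_weight", bool), costs=costs)
    utility = utility_of_year(
        alive_at_start=np.ones(len(records), dtype=bool), died=died,
        in_post=arr("in_post", bool), stroke_event=arr("stroke_event", bool),
        mi_history=arr("mi_history", bool), glycemic_level=arr("glycemic_level", int),
        hypo_episodes=arr("hypo_episodes", int), utils=utils)
    return discount(cost, rate), discount(utility, rate)


# --------------------------------------------------------------------- CEA
@dataclass(frozen=True)
class ICERResult:
    """ICER with dominance classification.

    ``kind`` is one of ``cost_saving`` (less cost, more QALYs), ``dominated``
    (more cost, fewer QALYs), ``undefined`` (zero QALY difference), or
    ``ratio`` with ``value`` in $/QALY.
    """

    kind: str
    value: float | None = None

    def __str__(self) -> str:
        if self.kind == "cost_saving":
            return "Cost Saving"
        if self.kind in ("dominated", "undefined"):
            return "NA"
        return f"{self.value:,.0f}"


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Incremental cost-effectiveness ratio with dominance handling."""
    if delta_cost < 0 and delta_qaly > 0:
        return ICERResult("cost_saving")
    if delta_cost > 0 and delta_qaly < 0:
        return ICERResult("dominated")
    if delta_qaly == 0:
        return ICERResult("undefined")
    # remaining quadrants (same-sign deltas, or zero cost) give a ratio >= 0
    return ICERResult("ratio", value=delta_cost / delta_qaly if delta_cost else 0.0)


def nhb(delta_qaly: float, delta_cost: float, lam: float) -> float:
    """Net health benefit in QALYs at willingness-to-pay ``lam`` ($/QALY)."""
    if lam <= 0:
        raise ValueError(f"threshold must be > 0, got {lam}")
    return delta_qaly - delta_cost / lam


def uncertainty_interval(values) -> tuple[float, float]:
    """Empirical 95% uncertainty interval (2.5th/97.5th percentiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values for an interval")
    lo, hi = np.percentile(v, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


def classify_cost_effectiveness(result: ICERResult,
                                highly_cut: float = 50_000.0,
                                threshold: float = 100_000.0) -> str:
    """Map an ICER to the standard four-way label."""
    if result.kind == "cost_saving":
        return "cost-saving"
    if result.kind in ("dominated", "undefined"):
        return "not cost-effective"
    if result.value < highly_cut:
        return "highly cost-effective"
    if result.value < threshold:
        return "cost-effective"
    return "not cost-effective"


@dataclass
class CEAResult:
    """Incremental outcomes of one scenario vs the status quo."""

    scenario: str
    strokes_averted: float
    stroke_deaths_averted: float
    mi_averted: float
    delta_cost: float
    delta_qaly: float
    icer: ICERResult
    nhb: float
    label: str
    ui: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "strokes_averted": self.strokes_averted,
            "stroke_deaths_averted": self.stroke_deaths_averted,
            "mi_averted": self.mi_averted,
            "incremental_cost": self.delta_cost,
            "incremental_qalys": self.delta_qaly,
            "nhb": self.nhb,
            "icer": str(self.icer),
            "icer_value": self.icer.value,
            "classification": self.label,
        }
        for key, (lo, hi) in self.ui.items():
            row[f"{key}_lo"], row[f"{key}_hi"] = lo, hi
        return row
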