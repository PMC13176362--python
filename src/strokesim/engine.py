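"""Annual-cycle disease progression engine.

Each simulated year proceeds, in order: (1) treatment recommendations and
stochastic adherence, (2) risk-factor drift and aging, (3) competing-risk
event draw (first/recurrent ischemic stroke, myocardial infarction, death
from other causes, stroke-attributed death in post-stroke states), and
(4) cost/utility accrual.  Cause-specific annual hazards multiply a baseline
age-sex hazard by per-risk-factor hazard ratios (defined per *decrease* of
their unit, so the multiplier is ``hr ** ((ref - x) / unit)``) and by
treatment relative-risk reductions.  Hazards convert to a yearly event
probability via the competing-risk exponential form 1 - exp(-H), with the
cause drawn proportionally to its hazard share; a stroke event routes
through an acute case-fatality draw.  Dead states are absorbing.

Randomness is organized as common random numbers: for every (imputation,
replicate) a fixed array of per-individual, per-year, per-decision-slot
uniforms is drawn from a Philox stream keyed by (seed, imputation,
replicate).  Because slots are positional, scenarios consume identical
draws, so scenario contrasts are exactly paired.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import econ, policy
from .config import GuidelineSpec
from .population import STATE_CODES, STATE_NAMES, CohortArrays, Individual
from .registry import ParameterRegistry

__all__ = [
    "AnnualRecord",
    "draw_uniforms",
    "apply_drift",
    "update_risk_factors",
    "annual_hazards",
    "transition",
    "simulate_cohort",
    "simulate_individual",
    "N_SLOTS",
]

S_FREE = STATE_CODES["stroke_free"]
S_ACUTE = STATE_CODES["acute_stroke"]
S_POST = STATE_CODES["post_stroke"]
S_DEAD_STROKE = STATE_CODES["dead_stroke"]
S_DEAD_OTHER = STATE_CODES["dead_other"]

# uniform slot layout per individual-year (policy slots first)
SLOT_EVENT = policy.N_POLICY_SLOTS
SLOT_CAUSE = SLOT_EVENT + 1
SLOT_CASE_FATALITY = SLOT_EVENT + 2
SLOT_HYPO = SLOT_EVENT + 3
N_SLOTS = SLOT_HYPO + 1


def draw_uniforms(seed: int, imputation: int, replicate: int, n: int,
                  horizon: int) -> np.ndarray:
    """Common-random-number block of shape (n, horizon, N_SLOTS).

    Keyed by (seed, imputation, replicate); row i is individual i's private
    stream, identical across scenarios.
    """
    ss = np.random.SeedSequence(
        [int(seed) & 0xFFFFFFFFFFFFFFFF, int(imputation), int(replicate)])
    gen = np.random.Generator(np.random.Philox(ss))
    return gen.uniform(size=(n, horizon, N_SLOTS))


@dataclass(frozen=True)
class AnnualRecord:
    """One person-year of simulation output."""

    year: int
    state: str
    stroke_event: bool
    mi_event: bool
    death_cause: str | None  # None | "stroke" | "other"
    hypo_episodes: int
    age: float
    hba1c: float
    sbp: float
    dbp: float
    lipid_ratio: float
    bmi: float
    smoker: bool
    mi_history: bool
    glycemic_level: int
    bp_level: int
    statin_code: int
    aspirin: bool
    anticoag_code: int
    in_post: bool
    attended_smoking: bool
    attended_weight: bool
    cost: float
    utility: float

    @property
    def died_this_year(self) -> bool:
        return self.death_cause is not None


# --------------------------------------------------------------- risk drift
def apply_drift(cohort: CohortArrays, registry: ParameterRegistry) -> None:
    """Age one year and apply natural-history risk-factor drift, in place."""
    cohort.age += 1.0
    cohort.hba1c = np.clip(cohort.hba1c + registry.value("drift_hba1c"), 3.0, 20.0)
    cohort.sbp = np.clip(cohort.sbp + registry.value("drift_sbp"), 70.0, 260.0)
    cohort.dbp = np.clip(cohort.dbp + 0.5 * registry.value("drift_sbp"), 40.0, 150.0)
    cohort.lipid_ratio = np.clip(
        cohort.lipid_ratio + registry.value("drift_lipid"), 1.0, 20.0)
    cohort.bmi = np.clip(cohort.bmi + registry.value("drift_bmi"), 12.0, 80.0)


def update_risk_factors(individual: Individual, registry: ParameterRegistry,
                        year: int = 0) -> Individual:
    """Scalar drift step: returns a copy aged one year with drifted factors."""
    return dataclasses.replace(
        individual,
        age=individual.age + 1.0,
        hba1c=float(np.clip(individual.hba1c + registry.value("drift_hba1c"), 3.0, 20.0)),
        sbp=float(np.clip(individual.sbp + registry.value("drift_sbp"), 70.0, 260.0)),
        dbp=float(np.clip(individual.dbp + 0.5 * registry.value("drift_sbp"), 40.0, 150.0)),
        lipid_ratio=float(np.clip(individual.lipid_ratio + registry.value("drift_lipid"),
                                  1.0, 20.0)),
        bmi=float(np.clip(individual.bmi + registry.value("drift_bmi"), 12.0, 80.0)),
    )


# ------------------------------------------------------------------ hazards
def annual_hazards(cohort, registry: ParameterRegistry) -> dict[str, np.ndarray]:
    """Cause-specific annual hazards given current risk factors and treatments.

    Returns ``stroke``, ``mi``, ``death_other``, ``death_stroke`` hazards plus
    the acute-stroke ``case_fatality`` probability.  Works on a cohort of
    arrays or a single individual (0-d arrays).
    """
    v = registry.value
    age = np.asarray(cohort.age, dtype=float)
    male = np.asarray(cohort.male, dtype=bool)
    state = np.asarray(cohort.state_code)
    statin_on = np.asarray(cohort.statin_code) != policy.STATIN_NONE
    afib = np.asarray(cohort.afib, dtype=bool)
    ac = np.asarray(cohort.anticoag_code)

    def rf_mult(hr_name: str, value, ref: float, unit: float = 1.0):
        return v(hr_name) ** ((ref - np.asarray(value, dtype=float)) / unit)

    # first/recurrent ischemic stroke
    h_stroke = (
        v("h_stroke_base")
        * np.exp(v("h_stroke_age_slope") * (age - 65.0))
        * np.where(male, 1.0 / v("hr_stroke_male"), 1.0)
        * np.where((state == S_ACUTE) | (state == S_POST),
                   v("h_stroke_recurrence_mult"), 1.0)
        * np.where(afib, 1.0 / v("hr_afib_stroke"), 1.0)
        * rf_mult("hr_hba1c", cohort.hba1c, v("ref_hba1c"))
        * rf_mult("hr_sbp", cohort.sbp, v("ref_sbp"), unit=10.0)
        * rf_mult("hr_lipid", cohort.lipid_ratio, v("ref_lipid"))
        * rf_mult("hr_bmi", cohort.bmi, v("ref_bmi"))
        * np.where(np.asarray(cohort.smoker, dtype=bool),
                   v("h_stroke_smoking_mult"), 1.0)
        * (1.0 - v("rrr_aspirin") * np.asarray(cohort.aspirin, dtype=float))
        * (1.0 - v("rrr_noac") * ((ac == policy.AC_NOAC) & afib))
        * (1.0 - v("rrr_warfarin") * ((ac == policy.AC_WARFARIN) & afib))
        * (1.0 - v("rrr_statin_stroke") * statin_on)
    )
    # myocardial infarction
    h_mi = (
        v("h_mi_base")
        * np.exp(v("h_mi_age_slope") * (age - 65.0))
        * np.where(male, 1.0 / v("hr_mi_male"), 1.0)
        * np.where(np.asarray(cohort.mi_history, dtype=bool),
                   1.0 / v("hr_mi_history"), 1.0)
        * rf_mult("hr_hba1c_mi", cohort.hba1c, v("ref_hba1c"))
        * rf_mult("hr_sbp_mi", cohort.sbp, v("ref_sbp"), unit=10.0)
        * rf_mult("hr_lipid_mi", cohort.lipid_ratio, v("ref_lipid"))
        * np.where(np.asarray(cohort.smoker, dtype=bool),
                   v("h_mi_smoking_mult"), 1.0)
        * (1.0 - v("rrr_statin_mi") * statin_on)
    )
    # other-cause death: Gompertz life table x diabetes multiplier
    h_death = (
        v("h_mortality_base")
        * np.exp(v("h_mortality_age_slope") * (age - 65.0))
        * np.where(male, 1.0 / v("hr_mortality_male"), 1.0)
        * v("h_mortality_t2d_mult")
    )
    # stroke-attributed death hazard in acute/post-stroke states
    h_death_stroke = np.where((state == S_ACUTE) | (state == S_POST),
                              v("h_poststroke_mortality"), 0.0)
    shape = np.broadcast(age, male).shape
    out = {
        "stroke": np.broadcast_to(np.asarray(h_stroke, dtype=float), shape).copy(),
        "mi": np.broadcast_to(np.asarray(h_mi, dtype=float), shape).copy(),
        "death_other": np.broadcast_to(np.asarray(h_death, dtype=float), shape).copy(),
        "death_stroke": np.broadcast_to(np.asarray(h_death_stroke, dtype=float),
                                        shape).copy(),
        "case_fatality": np.broadcast_to(
            np.asarray(v("p_stroke_case_fatality"), dtype=float), shape).copy(),
    }
    return out


# --------------------------------------------------------------- transitions
def transition(state_code: np.ndarray, hazards: dict[str, np.ndarray],
               u_event: np.ndarray, u_cause: np.ndarray, u_cf: np.ndarray
               ) -> dict[str, np.ndarray]:
    """Competing-risk yearly transition, vectorized and in place on ``state_code``.

    At most one event per individual-year: with total hazard H the event
    probability is 1 - exp(-H) and the cause is drawn with probability
    h_i / H.  Stroke events are fatal with the acute case-fatality
    probability.  Returns event masks.
    """
    alive = state_code < S_DEAD_STROKE
    h_s, h_m = hazards["stroke"], hazards["mi"]
    h_do, h_ds = hazards["death_other"], hazards["death_stroke"]
    H = h_s + h_m + h_do + h_ds
    with np.errstate(invalid="ignore", divide="ignore"):
        p_event = -np.expm1(-H)
        frac_s = np.where(H > 0, h_s / H, 0.0)
        frac_m = np.where(H > 0, h_m / H, 0.0)
        frac_do = np.where(H > 0, h_do / H, 0.0)
    event = alive & (u_event < p_event)
    c1 = frac_s
    c2 = c1 + frac_m
    c3 = c2 + frac_do
    stroke = event & (u_cause < c1)
    mi = event & ~stroke & (u_cause < c2)
    death_other = event & (u_cause >= c2) & (u_cause < c3)
    death_stroke_chronic = event & (u_cause >= c3)

    stroke_fatal = stroke & (u_cf < hazards["case_fatality"])
    state_code[stroke & ~stroke_fatal] = S_ACUTE
    state_code[stroke_fatal | death_stroke_chronic] = S_DEAD_STROKE
    state_code[death_other] = S_DEAD_OTHER
    return {
        "stroke": stroke,
        "mi": mi,
        "death_stroke": stroke_fatal | death_stroke_chronic,
        "death_other": death_other,
    }


def transition_individual(individual: Individual, hazards: dict,
                          rng: np.random.Generator) -> tuple[str, dict]:
    """Scalar transition draw: returns (new state name, event flags)."""
    state = np.array([individual.state_code], dtype=np.int64)
    hz = {k: np.asarray([float(np.asarray(v))]) for k, v in hazards.items()}
    events = transition(state, hz, rng.uniform(size=1), rng.uniform(size=1),
                        rng.uniform(size=1))
    return STATE_NAMES[int(state[0])], {k: bool(v[0]) for k, v in events.items()}


# ------------------------------------------------------------- year stepping
def _hypo_episodes(cohort: CohortArrays, registry: ParameterRegistry,
                   u: np.ndarray, alive: np.ndarray) -> np.ndarray:
    """Severe hypoglycemia counts for individuals on insulin (Poisson via
    inverse CDF so the draw stays within the common-random-number block)."""
    episodes = np.zeros(cohort.n, dtype=np.int64)
    on_insulin = alive & (cohort.glycemic_level >= 3)
    if on_insulin.any():
        rate = np.where(cohort.glycemic_level[on_insulin] == 4,
                        registry.value("h_hypo_intensive"),
                        registry.value("h_hypo_basal"))
        episodes[on_insulin] = stats.poisson.ppf(
            u[on_insulin], rate).astype(np.int64)
    return episodes


def _step_year(cohort: CohortArrays, year: int, adherence: dict[str, float],
               spec: GuidelineSpec, registry: ParameterRegistry,
               uniforms_y: np.ndarray, costs: econ.CostSchedule,
               utils: econ.UtilitySchedule) -> dict[str, np.ndarray]:
    """One annual cycle in place; returns per-person accrual and event arrays."""
    alive_start = cohort.state_code < S_DEAD_STROKE
    # last year's acute strokes become chronic post-stroke
    cohort.state_code[cohort.state_code == S_ACUTE] = S_POST

    masks = policy.recommend_masks(cohort, set(adherence), spec, year)
    masks = {s: m & alive_start for s, m in masks.items()}
    adopted = policy.apply_recommendations(
        cohort, masks, adherence, uniforms_y[:, :policy.N_POLICY_SLOTS],
        spec, registry)
    attended_smoking = adopted.get("smoking", np.zeros(cohort.n, dtype=bool))
    attended_weight = adopted.get("weight", np.zeros(cohort.n, dtype=bool))

    apply_drift(cohort, registry)

    in_post = alive_start & (cohort.state_code == S_POST)
    hazards = annual_hazards(cohort, registry)
    events = transition(cohort.state_code, hazards, uniforms_y[:, SLOT_EVENT],
                        uniforms_y[:, SLOT_CAUSE], uniforms_y[:, SLOT_CASE_FATALITY])
    cohort.mi_history = cohort.mi_history | events["mi"]
    died = events["death_stroke"] | events["death_other"]

    hypo = _hypo_episodes(cohort, registry, uniforms_y[:, SLOT_HYPO], alive_start)
    cost = econ.cost_of_year(
        alive_at_start=alive_start, glycemic_level=cohort.glycemic_level,
        bp_level=cohort.bp_level, statin_code=cohort.statin_code,
        aspirin=cohort.aspirin, anticoag_code=cohort.anticoag_code,
        in_post=in_post, stroke_event=events["stroke"], mi_event=events["mi"],
        died=died, attended_smoking=attended_smoking,
        attended_weight=attended_weight, costs=costs)
    utility = econ.utility_of_year(
        alive_at_start=alive_start, died=died, in_post=in_post,
        stroke_event=events["stroke"], mi_history=cohort.mi_history,
        glycemic_level=cohort.glycemic_level, hypo_episodes=hypo, utils=utils)
    return {
        "cost": cost, "utility": utility, "stroke": events["stroke"],
        "mi": events["mi"], "death_stroke": events["death_stroke"],
        "death_other": events["death_other"], "hypo": hypo,
        "in_post": in_post, "attended_smoking": attended_smoking,
        "attended_weight": attended_weight, "alive_start": alive_start,
    }


def simulate_cohort(cohort: CohortArrays, adherence: dict[str, float],
                    spec: GuidelineSpec, registry: ParameterRegistry,
                    horizon: int, uniforms: np.ndarray,
                    costs: econ.CostSchedule, utils: econ.UtilitySchedule,
                    discount_rate: float = 0.03) -> dict[str, np.ndarray]:
    """Simulate a cohort in place over ``horizon`` years.

    Returns per-person discounted cost and QALY plus event counts.  All
    randomness comes from ``uniforms`` of shape (n, >= horizon, N_SLOTS).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    n = cohort.n
    out = {k: np.zeros(n) for k in ("cost", "qaly")}
    counts = {k: np.zeros(n, dtype=np.int64)
              for k in ("strokes", "stroke_deaths", "mi_events")}
    for y in range(horizon):
        disc = (1.0 + discount_rate) ** -y
        step = _step_year(cohort, y, adherence, spec, registry,
                         uniforms[:, y, :], costs, utils)
        out["cost"] += disc * step["cost"]
        out["qaly"] += disc * step["utility"]
        counts["strokes"] += step["stroke"]
        counts["stroke_deaths"] += step["death_stroke"]
        counts["mi_events"] += step["mi"]
        if not (cohort.state_code < S_DEAD_STROKE).any():
            break
    out.update({k: v.astype(float) for k, v in counts.items()})
    return out


def simulate_individual(individual: Individual, adherence: dict[str, float],
                        spec: GuidelineSpec, registry: ParameterRegistry,
                        horizon: int, seed: int,
                        costs: econ.CostSchedule | None = None,
                        utils: econ.UtilitySchedule | None = None,
                        discount_rate: float = 0.03) -> list[AnnualRecord]:
    """Simulate one individual, returning a record per simulated year.

    The simulation stops after the year in which death occurs (the death year
    is recorded) or at the horizon.  Deterministic in (individual, adherence,
    seed).
    """
    from .population import Population

    costs = costs or econ.CostSchedule.from_registry(registry)
    utils = utils or econ.UtilitySchedule.from_registry(registry)
    pop = Population.from_individuals([individual])
    cohort = pop.arrays()
    uniforms = draw_uniforms(seed, 0, int(individual.id), 1, horizon)
    records: list[AnnualRecord] = []
    for y in range(horizon):
        step = _step_year(cohort, y, adherence, spec, registry,
                         uniforms[:, y, :], costs, utils)
        death_cause = None
        if step["death_stroke"][0]:
            death_cause = "stroke"
        elif step["death_other"][0]:
            death_cause = "other"
        disc = (1.0 + discount_rate) ** -y
        records.append(AnnualRecord(
            year=y, state=STATE_NAMES[int(cohort.state_code[0])],
            stroke_event=bool(step["stroke"][0]), mi_event=bool(step["mi"][0]),
            death_cause=death_cause, hypo_episodes=int(step["hypo"][0]),
            age=float(cohort.age[0]), hba1c=float(cohort.hba1c[0]),
            sbp=float(cohort.sbp[0]), dbp=float(cohort.dbp[0]),
            lipid_ratio=float(cohort.lipid_ratio[0]), bmi=float(cohort.bmi[0]),
            smoker=bool(cohort.smoker[0]), mi_history=bool(cohort.mi_history[0]),
            glycemic_level=int(cohort.glycemic_level[0]),
            bp_level=int(cohort.bp_level[0]),
            statin_code=int(cohort.statin_code[0]),
            aspirin=bool(cohort.aspirin[0]),
            anticoag_code=int(cohort.anticoag_code[0]),
            in_post=bool(step["in_post"][0]),
            attended_smoking=bool(step["attended_smoking"][0]),
            attended_weight=bool(step["attended_weight"][0]),
            cost=float(disc * step["cost"][0]),
            utility=float(disc * step["utility"][0]),
        ))
        if cohort.state_code[0] >= S_DEAD_STROKE:
            break
    return records
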