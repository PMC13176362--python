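"""Guideline-recommendation logic and stochastic adherence.

Encodes the seven prevention strategies as escalation/initiation rules applied
at the start of every simulation year: antihyperglycemic and antihypertensive
treatment ladders, statin intensity, primary-prevention aspirin, one-time
smoking-cessation referral and weight-loss programs, and anticoagulation for
atrial fibrillation gated on the CHA2DS2-VASc score.

Two parallel surfaces are provided: scalar operations on a single individual
(``recommend``/``apply_adherence``) and vectorized mask operations on a cohort
of numpy arrays (``recommend_masks``/``apply_recommendations``) used by the
simulation engine; a unit test pins the two to each other.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .config import STRATEGIES, ConfigError, GuidelineSpec

if TYPE_CHECKING:  # pragma: no cover
    from .registry import ParameterRegistry

__all__ = [
    "Recommendation",
    "chads_vasc",
    "aspirin_eligible",
    "recommended_statin_intensity",
    "recommend",
    "recommend_masks",
    "apply_adherence",
    "apply_recommendations",
    "GLYCEMIC_MAX_RUNG",
    "BP_MAX_RUNG",
    "STATIN_NONE",
    "STATIN_MODERATE",
    "STATIN_HIGH",
    "AC_NONE",
    "AC_WARFARIN",
    "AC_NOAC",
]

# Treatment ladders: glycemic 0 lifestyle .. 4 intensive insulin;
# BP 0 none .. 6 three full-dose drugs.
GLYCEMIC_MAX_RUNG = 4
BP_MAX_RUNG = 6

STATIN_NONE, STATIN_MODERATE, STATIN_HIGH = 0, 1, 2
AC_NONE, AC_WARFARIN, AC_NOAC = 0, 1, 2

STATIN_CODES = {"none": STATIN_NONE, "moderate": STATIN_MODERATE, "high": STATIN_HIGH}
STATIN_NAMES = {v: k for k, v in STATIN_CODES.items()}
AC_CODES = {"none": AC_NONE, "warfarin": AC_WARFARIN, "noac": AC_NOAC}
AC_NAMES = {v: k for k, v in AC_CODES.items()}


@dataclass(frozen=True)
class Recommendation:
    """A single treatment recommendation for one individual-year."""

    strategy: str
    action: str  # escalate | initiate | switch
    detail: int | float | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.action not in ("escalate", "initiate", "switch"):
            raise ConfigError(f"unknown action {self.action!r}")


# --------------------------------------------------------------------- scores
def chads_vasc(ind, sbp_cut: float = 140.0):
    """CHA2DS2-VASc stroke-risk score (0..9).

    Components: congestive heart failure (1), hypertension (1; SBP >=
    ``sbp_cut`` or any antihypertensive treatment), age >= 75 (2), diabetes
    (1; everyone in this cohort), prior stroke (2), vascular disease / MI
    history (1), age 65-74 (1), female sex (1).  Works on a scalar individual
    or a cohort of arrays.
    """
    age = np.asarray(ind.age)
    hypertensive = (np.asarray(ind.sbp) >= sbp_cut) | (np.asarray(ind.bp_level) > 0)
    prior_stroke = np.asarray(ind.state_code) > 0  # any stroke state, incl. dead-of-stroke
    score = (
        np.asarray(ind.chf).astype(np.int64)
        + hypertensive.astype(np.int64)
        + 2 * (age >= 75)
        + 1  # diabetes, by cohort definition
        + 2 * prior_stroke.astype(np.int64)
        + np.asarray(ind.mi_history).astype(np.int64)
        + ((age >= 65) & (age < 75)).astype(np.int64)
        + (~np.asarray(ind.male)).astype(np.int64)
    )
    return int(score) if score.ndim == 0 else score


def aspirin_eligible(ind, spec: GuidelineSpec):
    """Primary-prevention aspirin eligibility.

    Age within the guideline window, at least one additional major ASCVD risk
    factor (family history of premature ASCVD, hypertension, dyslipidemia,
    smoking, or CKD/albuminuria), and no elevated bleeding risk.
    """
    age = np.asarray(ind.age)
    lo, hi = spec.aspirin_age_range
    in_age = (age >= lo) & (age <= hi)
    hypertensive = (np.asarray(ind.sbp) >= spec.bp_target[0]) | (np.asarray(ind.bp_level) > 0)
    risk = (
        np.asarray(ind.family_history_ascvd)
        | hypertensive
        | (np.asarray(ind.lipid_ratio) > spec.dyslipidemia_lipid_cut)
        | np.asarray(ind.smoker)
        | np.asarray(ind.ckd)
    )
    out = in_age & risk & ~np.asarray(ind.high_bleeding_risk)
    return bool(out) if out.ndim == 0 else out


def recommended_statin_intensity(ind, spec: GuidelineSpec):
    """Guideline statin intensity: moderate for all, high for ages 50-70 or
    multiple ASCVD risk factors, moderate (not high) at >= 75."""
    age = np.asarray(ind.age)
    hypertensive = (np.asarray(ind.sbp) >= spec.bp_target[0]) | (np.asarray(ind.bp_level) > 0)
    n_risk = (
        np.asarray(ind.smoker).astype(np.int64)
        + hypertensive.astype(np.int64)
        + (np.asarray(ind.lipid_ratio) > spec.dyslipidemia_lipid_cut).astype(np.int64)
        + np.asarray(ind.family_history_ascvd).astype(np.int64)
        + np.asarray(ind.ckd).astype(np.int64)
    )
    lo, hi = spec.statin_high_age_range
    high = (((age >= lo) & (age <= hi)) | (n_risk >= 2)) & (age < spec.statin_moderate_age)
    out = np.where(high, STATIN_HIGH, STATIN_MODERATE)
    return int(out) if out.ndim == 0 else out


# ------------------------------------------------------------ recommendations
def recommend_masks(cohort, active: frozenset[str] | set[str], spec: GuidelineSpec,
                    year: int) -> dict[str, np.ndarray]:
    """Boolean recommendation mask per active strategy, vectorized over a cohort.

    ``cohort`` is any object exposing the individual fields as equal-length
    arrays.  Masks ignore vital status; the caller restricts to the living.
    """
    unknown = set(active) - set(STRATEGIES)
    if unknown:
        raise ConfigError(f"unknown strategies in scenario: {sorted(unknown)}")
    masks: dict[str, np.ndarray] = {}
    if "glycemic" in active:
        target = spec.hba1c_target(cohort.age)
        masks["glycemic"] = (np.asarray(cohort.hba1c) >= target) & (
            np.asarray(cohort.glycemic_level) < GLYCEMIC_MAX_RUNG)
    if "bp" in active:
        above = (np.asarray(cohort.sbp) >= spec.bp_target[0]) | (
            np.asarray(cohort.dbp) >= spec.bp_target[1])
        masks["bp"] = above & (np.asarray(cohort.bp_level) < BP_MAX_RUNG)
    if "statin" in active:
        masks["statin"] = np.asarray(cohort.statin_code) != recommended_statin_intensity(
            cohort, spec)
    if "aspirin" in active:
        masks["aspirin"] = np.asarray(aspirin_eligible(cohort, spec)) & ~np.asarray(
            cohort.aspirin)
    if "smoking" in active:
        masks["smoking"] = np.asarray(cohort.smoker) & (year == 0)
    if "weight" in active:
        masks["weight"] = (np.asarray(cohort.bmi) > spec.weight_loss_bmi_floor) & (year == 0)
    if "anticoagulant" in active:
        masks["anticoagulant"] = (
            np.asarray(cohort.afib)
            & (chads_vasc(cohort, sbp_cut=spec.bp_target[0]) >= spec.chads_vasc_threshold)
            & (np.asarray(cohort.anticoag_code) == AC_NONE)
        )
    return masks


_ACTIONS = {
    "glycemic": "escalate",
    "bp": "escalate",
    "statin": "switch",
    "aspirin": "initiate",
    "smoking": "initiate",
    "weight": "initiate",
    "anticoagulant": "initiate",
}


def recommend(individual, active: frozenset[str] | set[str], spec: GuidelineSpec,
              year: int) -> list[Recommendation]:
    """Treatment recommendations for one individual-year, in strategy order."""
    recs = []
    for s in STRATEGIES:
        if s not in active:
            continue
        mask = recommend_masks(individual, {s}, spec, year)[s]
        if not bool(np.asarray(mask)):
            continue
        detail: int | float | None = None
        action = _ACTIONS[s]
        if s == "glycemic":
            detail = int(individual.glycemic_level) + 1
        elif s == "bp":
            detail = int(individual.bp_level) + 1
        elif s == "statin":
            detail = int(recommended_statin_intensity(individual, spec))
            action = "switch" if individual.statin_code != STATIN_NONE else "initiate"
        elif s == "weight":
            detail = spec.weight_loss_fraction
        elif s == "anticoagulant":
            detail = AC_NOAC
        recs.append(Recommendation(strategy=s, action=action, detail=detail))
    return recs


# ------------------------------------------------------------------ adherence
# Positional uniform slots consumed per individual-year; fixed layout keeps
# draws identical across scenarios (common random numbers).
ADHERENCE_SLOTS = {s: i for i, s in enumerate(STRATEGIES)}
SLOT_QUIT = len(STRATEGIES)  # smoking-cessation success draw
N_POLICY_SLOTS = SLOT_QUIT + 1


def apply_recommendations(cohort, masks: dict[str, np.ndarray],
                          adherence: dict[str, float], uniforms: np.ndarray,
                          spec: GuidelineSpec, registry: "ParameterRegistry",
                          ) -> dict[str, np.ndarray]:
    """Adopt recommendations in place on a cohort; return adopted masks.

    ``uniforms`` has shape (n, N_POLICY_SLOTS); each strategy consumes its own
    fixed column so that identical seeds give identical draws across
    scenarios.  Returns the per-strategy adopted masks (used for one-time
    program cost accounting).
    """
    adopted: dict[str, np.ndarray] = {}
    for s, mask in masks.items():
        a = float(adherence.get(s, 0.0))
        take = mask & (uniforms[:, ADHERENCE_SLOTS[s]] < a)
        adopted[s] = take
        if not take.any():
            continue
        if s == "glycemic":
            cohort.glycemic_level[take] = np.minimum(
                cohort.glycemic_level[take] + 1, GLYCEMIC_MAX_RUNG)
            cohort.hba1c[take] = np.maximum(
                cohort.hba1c[take] - registry.value("eff_hba1c_per_rung"), 4.0)
        elif s == "bp":
            cohort.bp_level[take] = np.minimum(cohort.bp_level[take] + 1, BP_MAX_RUNG)
            cohort.sbp[take] = np.maximum(
                cohort.sbp[take] - registry.value("eff_sbp_per_rung"), 85.0)
            cohort.dbp[take] = np.maximum(
                cohort.dbp[take] - registry.value("eff_dbp_per_rung"), 45.0)
            cohort.acei_arb[take] = True  # first-line agent is an ACEi/ARB
        elif s == "statin":
            cohort.statin_code[take] = recommended_statin_intensity(cohort, spec)[take]
        elif s == "aspirin":
            cohort.aspirin[take] = True
        elif s == "smoking":
            quit_ = take & (uniforms[:, SLOT_QUIT] < spec.quit_success)
            cohort.smoker[quit_] = False
        elif s == "weight":
            cohort.bmi[take] = cohort.bmi[take] * (1.0 - spec.weight_loss_fraction)
        elif s == "anticoagulant":
            cohort.anticoag_code[take] = AC_NOAC
    return adopted


def apply_adherence(individual, recs: list[Recommendation],
                    adherence: dict[str, float], rng: np.random.Generator,
                    spec: GuidelineSpec, registry: "ParameterRegistry"):
    """Scalar counterpart of :func:`apply_recommendations`.

    Each recommendation is adopted independently with its strategy's adherence
    probability; returns an updated copy of ``individual`` (a dataclass).
    """
    changes: dict = {}
    for rec in recs:
        if rng.uniform() >= float(adherence.get(rec.strategy, 0.0)):
            continue
        s = rec.strategy
        if s == "glycemic":
            changes["glycemic_level"] = min(individual.glycemic_level + 1, GLYCEMIC_MAX_RUNG)
            changes["hba1c"] = max(
                individual.hba1c - registry.value("eff_hba1c_per_rung"), 4.0)
        elif s == "bp":
            changes["bp_level"] = min(individual.bp_level + 1, BP_MAX_RUNG)
            changes["sbp"] = max(individual.sbp - registry.value("eff_sbp_per_rung"), 85.0)
            changes["dbp"] = max(individual.dbp - registry.value("eff_dbp_per_rung"), 45.0)
            changes["acei_arb"] = True
        elif s == "statin":
            changes["statin"] = STATIN_NAMES[int(rec.detail)]
        elif s == "aspirin":
            changes["aspirin"] = True
        elif s == "smoking":
            if rng.uniform() < spec.quit_success:
                changes["smoker"] = False
        elif s == "weight":
            changes["bmi"] = individual.bmi * (1.0 - spec.weight_loss_fraction)
        elif s == "anticoagulant":
            changes["anticoagulant"] = AC_NAMES[AC_NOAC]
    return dataclasses.replace(individual, **changes) if changes else individual
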