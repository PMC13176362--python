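"""Configuration objects: guideline rules, cohort generator settings, scenario specs.

All user-facing knobs are plain dataclasses validated on construction, loadable
from a single YAML file with nested sections (``population``, ``guidelines``,
``design``, ``adherence``, ``scenarios``).  Defaults describe the study
conditions: U.S. adults >= 45 years with type 2 diabetes and no stroke
history, with the nationally observed baseline achievement proportions of the
seven guideline-recommended prevention strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "STRATEGIES",
    "ConfigError",
    "Marginal",
    "GuidelineSpec",
    "PopulationConfig",
    "ScenarioSpec",
    "SimDesign",
    "AnalysisConfig",
    "load_config",
]

#: The seven prevention strategies, in reporting order.
STRATEGIES = ("glycemic", "bp", "statin", "aspirin", "smoking", "weight", "anticoagulant")


class ConfigError(ValueError):
    """Raised for invalid configuration input."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class Marginal:
    """A 1-D marginal distribution with truncation bounds.

    ``dist`` is ``normal`` (mean/sd on the natural scale) or ``lognormal``
    (mean/sd of log values).  Sampling clips to [lo, hi] by quantile
    truncation, not rejection, so the mapping from uniforms is monotone.
    """

    dist: str
    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        _require(self.dist in ("normal", "lognormal"), f"unknown marginal dist {self.dist!r}")
        _require(self.sd > 0, "marginal sd must be > 0")
        _require(self.lo < self.hi, "marginal bounds must satisfy lo < hi")


@dataclass(frozen=True)
class GuidelineSpec:
    """Operational definitions of the seven guideline recommendations."""

    hba1c_target_under65: float = 7.0
    hba1c_target_65plus: float = 7.5
    bp_target: tuple[float, float] = (140.0, 90.0)
    aspirin_age_range: tuple[float, float] = (50.0, 70.0)
    chads_vasc_threshold: int = 2
    quit_success: float = 0.12
    weight_loss_fraction: float = 0.05
    weight_loss_bmi_floor: float = 25.0
    # ancillary cuts used by the eligibility rules
    dyslipidemia_lipid_cut: float = 4.5
    statin_high_age_range: tuple[float, float] = (50.0, 70.0)
    statin_moderate_age: float = 75.0

    def __post_init__(self) -> None:
        _require(self.hba1c_target_under65 > 0 and self.hba1c_target_65plus > 0,
                 "HbA1c targets must be positive")
        _require(self.bp_target[0] > 0 and self.bp_target[1] > 0, "BP targets must be positive")
        _require(0 <= self.quit_success <= 1, "quit_success must be in [0, 1]")
        _require(0 <= self.weight_loss_fraction <= 1, "weight_loss_fraction must be in [0, 1]")
        _require(self.aspirin_age_range[0] <= self.aspirin_age_range[1],
                 "aspirin age range reversed")

    def hba1c_target(self, age):
        """Age-appropriate HbA1c target (vectorized over ``age``)."""
        return np.where(np.asarray(age) < 65, self.hba1c_target_under65, self.hba1c_target_65plus)


#: Baseline national proportions achieving each strategy (2015-2018, weighted).
DEFAULT_TARGET_PROPORTIONS = {
    "glycemic": 0.576,
    "bp": 0.707,
    "statin": 0.600,
    "aspirin": 0.079,
    "smoking": 0.811,
    "weight": 0.108,
    "anticoagulant": 0.524,
}

DEFAULT_MISSINGNESS = {"hba1c": 0.05, "sbp": 0.05, "dbp": 0.05, "lipid_ratio": 0.10, "bmi": 0.02}

_COPULA_FIELDS = ("age", "hba1c", "sbp", "lipid_ratio", "bmi")

# Modest positive dependence between age/pressure and adiposity/lipids/glycemia.
_DEFAULT_CORR = np.array(
    [
        # age   hba1c   sbp   lipid   bmi
        [1.00, -0.10, 0.30, -0.05, -0.15],
        [-0.10, 1.00, 0.10, 0.15, 0.15],
        [0.30, 0.10, 1.00, 0.10, 0.20],
        [-0.05, 0.15, 0.10, 1.00, 0.20],
        [-0.15, 0.15, 0.20, 0.20, 1.00],
    ]
)


def _default_marginals() -> dict[str, Marginal]:
    return {
        # underlying normal moment-matched so that after truncation to
        # [45, 100] the realized distribution has mean 65.1 and SD 9.8
        "age": Marginal("normal", 64.2422, 10.6857, lo=45.0, hi=100.0),
        "hba1c": Marginal("normal", 7.6, 1.6, lo=3.5, hi=19.0),
        "sbp": Marginal("normal", 131.0, 18.0, lo=75.0, hi=250.0),
        "lipid_ratio": Marginal("lognormal", np.log(4.0), 0.32, lo=1.2, hi=15.0),
        "bmi": Marginal("normal", 31.5, 6.5, lo=14.0, hi=75.0),
        "dbp": Marginal("normal", 72.0, 10.0, lo=40.0, hi=150.0),
    }


@dataclass
class PopulationConfig:
    """Settings of the survey-weighted synthetic cohort generator."""

    n: int = 1232
    total_weight: float = 3.7e6
    male_fraction: float = 0.558
    weight_cv: float = 0.5
    marginals: dict[str, Marginal] = field(default_factory=_default_marginals)
    correlation: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    target_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_PROPORTIONS))
    missingness_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    # comorbidity prevalences
    mi_history_prev: float = 0.12
    ckd_prev: float = 0.25
    family_history_prev: float = 0.15
    bleeding_risk_prev: float = 0.10
    chf_prev: float = 0.0
    #: atrial fibrillation prevalence by age band [45-54, 55-64, 65-74, 75+)
    afib_prev_by_age: tuple[float, ...] = (0.02, 0.04, 0.08, 0.15)
    #: fraction of individuals not meeting BP control who nonetheless take an ACEi/ARB
    acei_untreated_frac: float = 0.30
    #: glycemic ladder occupancy for achievers / non-achievers (rungs 0..4)
    glycemic_rung_probs_achiever: tuple[float, ...] = (0.15, 0.35, 0.35, 0.12, 0.03)
    glycemic_rung_probs_other: tuple[float, ...] = (0.10, 0.25, 0.35, 0.20, 0.10)

    def __post_init__(self) -> None:
        _require(self.n >= 0, f"cohort size must be >= 0, got {self.n}")
        _require(self.total_weight > 0, "total_weight must be > 0")
        for name, p in [
            ("male_fraction", self.male_fraction),
            ("mi_history_prev", self.mi_history_prev),
            ("ckd_prev", self.ckd_prev),
            ("family_history_prev", self.family_history_prev),
            ("bleeding_risk_prev", self.bleeding_risk_prev),
            ("chf_prev", self.chf_prev),
            ("acei_untreated_frac", self.acei_untreated_frac),
        ]:
            _require(0 <= p <= 1, f"{name} must be in [0, 1], got {p}")
        for s, p in self.target_proportions.items():
            _require(s in STRATEGIES, f"unknown strategy {s!r} in target_proportions")
            _require(0 <= p <= 1, f"target proportion for {s} must be in [0, 1], got {p}")
        for f_, p in self.missingness_rates.items():
            _require(0 <= p <= 1, f"missingness rate for {f_} must be in [0, 1]")
        for p in self.afib_prev_by_age:
            _require(0 <= p <= 1, "afib prevalences must be in [0, 1]")
        corr = np.asarray(self.correlation, dtype=float)
        k = len(_COPULA_FIELDS)
        _require(corr.shape == (k, k), f"correlation must be {k}x{k}")
        _require(np.allclose(corr, corr.T), "correlation must be symmetric")
        _require(np.all(np.linalg.eigvalsh(corr) > -1e-10),
                 "correlation must be positive semidefinite")
        self.correlation = corr
        for probs in (self.glycemic_rung_probs_achiever, self.glycemic_rung_probs_other):
            _require(len(probs) == 5 and abs(sum(probs) - 1) < 1e-9,
                     "glycemic rung probabilities must be 5 values summing to 1")

    @property
    def copula_fields(self) -> tuple[str, ...]:
        return _COPULA_FIELDS


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: which strategies are enhanced, and how far."""

    name: str
    enhanced_strategies: frozenset[str] = frozenset()
    adherence_overrides: dict[str, float] = field(default_factory=dict)
    improvement_fraction: float | None = None
    horizon: int = 10
    lam: float = 100_000.0
    highly_ce_cut: float = 50_000.0

    def __post_init__(self) -> None:
        for s in self.enhanced_strategies:
            _require(s in STRATEGIES, f"unknown strategy {s!r} in scenario {self.name!r}")
        for s, a in self.adherence_overrides.items():
            _require(s in STRATEGIES, f"unknown strategy {s!r} in adherence_overrides")
            _require(0 <= a <= 1, f"adherence for {s} must be in [0, 1]")
        if self.improvement_fraction is not None:
            _require(0 <= self.improvement_fraction <= 1,
                     "improvement_fraction must be in [0, 1]")
        _require(self.horizon >= 1, "horizon must be >= 1")
        _require(self.lam > 0, "cost-effectiveness threshold must be > 0")

    def adherence(self, status_quo: dict[str, float]) -> dict[str, float]:
        """Per-strategy adherence this scenario applies, given status-quo levels."""
        out = dict(status_quo)
        for s in STRATEGIES:
            if s in self.adherence_overrides:
                out[s] = self.adherence_overrides[s]
            elif s in self.enhanced_strategies:
                a = 1.0
                if self.improvement_fraction is not None:
                    from .scenarios import scale_adherence

                    a = scale_adherence(status_quo.get(s, 0.0), self.improvement_fraction)
                out[s] = a
        return out


@dataclass(frozen=True)
class SimDesign:
    """Replication design: imputations x replicates x horizon."""

    M: int = 10
    R: int = 50
    horizon: int = 10
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        _require(self.M >= 1, "M must be >= 1")
        _require(self.R >= 1, "R must be >= 1")
        _require(self.horizon >= 1, "horizon must be >= 1")
        _require(self.discount_rate >= 0, "discount rate must be >= 0")


#: Default membership of the combined scenarios (strategies found individually
#: cost-saving or highly cost-effective / cost-effective in the base case).
DEFAULT_COMBO1 = ("bp", "statin", "aspirin", "smoking")
DEFAULT_COMBO2 = ("bp", "statin", "aspirin", "smoking", "weight")


@dataclass
class AnalysisConfig:
    """Top-level bundle parsed from the YAML config file."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    guidelines: GuidelineSpec = field(default_factory=GuidelineSpec)
    design: SimDesign = field(default_factory=SimDesign)
    status_quo_adherence: dict[str, float] | None = None
    combo1: tuple[str, ...] = DEFAULT_COMBO1
    combo2: tuple[str, ...] = DEFAULT_COMBO2
    registry_path: str | None = None
    lam: float = 100_000.0
    highly_ce_cut: float = 50_000.0

    def __post_init__(self) -> None:
        for combo in (self.combo1, self.combo2):
            for s in combo:
                _require(s in STRATEGIES, f"unknown strategy {s!r} in combo membership")
        if self.status_quo_adherence is not None:
            for s, a in self.status_quo_adherence.items():
                _require(s in STRATEGIES, f"unknown strategy {s!r} in adherence")
                _require(0 <= a <= 1, f"adherence for {s} must be in [0, 1]")


def _parse_marginals(raw: dict) -> dict[str, Marginal]:
    out = _default_marginals()
    for name, rec in raw.items():
        _require(name in out, f"unknown marginal {name!r}")
        base = out[name]
        out[name] = Marginal(
            dist=rec.get("dist", base.dist),
            mean=float(rec.get("mean", base.mean)),
            sd=float(rec.get("sd", base.sd)),
            lo=float(rec.get("lo", base.lo)),
            hi=float(rec.get("hi", base.hi)),
        )
    return out


def _pop_from_dict(raw: dict) -> PopulationConfig:
    kwargs: dict = {}
    simple = [
        "n", "total_weight", "male_fraction", "weight_cv", "mi_history_prev", "ckd_prev",
        "family_history_prev", "bleeding_risk_prev", "chf_prev", "acei_untreated_frac",
    ]
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "marginals" in raw:
        kwargs["marginals"] = _parse_marginals(raw["marginals"])
    if "correlation" in raw:
        kwargs["correlation"] = np.asarray(raw["correlation"], dtype=float)
    if "target_proportions" in raw:
        tp = dict(DEFAULT_TARGET_PROPORTIONS)
        tp.update(raw["target_proportions"])
        kwargs["target_proportions"] = tp
    if "missingness_rates" in raw:
        kwargs["missingness_rates"] = {k: float(v) for k, v in raw["missingness_rates"].items()}
    if "afib_prev_by_age" in raw:
        kwargs["afib_prev_by_age"] = tuple(float(v) for v in raw["afib_prev_by_age"])
    return PopulationConfig(**kwargs)


def _guidelines_from_dict(raw: dict) -> GuidelineSpec:
    kwargs: dict = {}
    for key in (
        "hba1c_target_under65", "hba1c_target_65plus", "chads_vasc_threshold",
        "quit_success", "weight_loss_fraction", "weight_loss_bmi_floor",
        "dyslipidemia_lipid_cut", "statin_moderate_age",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("bp_target", "aspirin_age_range", "statin_high_age_range"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    return GuidelineSpec(**kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate a YAML analysis config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping at top level")
    known = {"population", "guidelines", "design", "adherence", "scenarios", "registry", "thresholds"}
    unknown = set(data) - known
    _require(not unknown, f"unknown config sections: {sorted(unknown)}")
    design_raw = data.get("design", {})
    scen_raw = data.get("scenarios", {})
    thr = data.get("thresholds", {})
    return AnalysisConfig(
        population=_pop_from_dict(data.get("population", {})),
        guidelines=_guidelines_from_dict(data.get("guidelines", {})),
        design=SimDesign(
            M=int(design_raw.get("imputations", 10)),
            R=int(design_raw.get("replicates", 50)),
            horizon=int(design_raw.get("horizon", 10)),
            discount_rate=float(design_raw.get("discount_rate", 0.03)),
        ),
        status_quo_adherence=data.get("adherence"),
        combo1=tuple(scen_raw.get("combo1", DEFAULT_COMBO1)),
        combo2=tuple(scen_raw.get("combo2", DEFAULT_COMBO2)),
        registry_path=data.get("registry"),
        lam=float(thr.get("cost_effective", 100_000.0)),
        highly_ce_cut=float(thr.get("highly_cost_effective", 50_000.0)),
    )
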