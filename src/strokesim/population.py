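"""Survey-weighted synthetic cohort generation, imputation, and calibration.

The generator emulates a national survey subsample of U.S. adults >= 45 years
with type 2 diabetes and no stroke history: correlated risk factors from a
Gaussian copula with configurable marginals, comorbidity prevalences, baseline
treatment states assigned jointly with strategy-achievement flags (so each
guideline criterion is meaningful at t = 0), and per-person survey weights
summing exactly to the national total represented.

Achievement of each of the seven prevention strategies is controlled by a
Bernoulli flag at the configured target proportion; the flagged individuals'
risk factors are drawn from the marginal truncated to the achieving side of
the criterion threshold, so the weighted achieved proportion converges to the
target at the usual root-n rate while the copula correlation structure is
preserved within each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import policy
from .config import STRATEGIES, ConfigError, GuidelineSpec, Marginal, PopulationConfig
from .registry import ParameterRegistry

__all__ = [
    "Individual",
    "CohortArrays",
    "Population",
    "ImputedPopulationSet",
    "InfeasibleTargetError",
    "generate_population",
    "apply_missingness_and_impute",
    "impute",
    "calibrate_adherence",
    "calibrate_status_quo",
    "strategy_achievement",
    "achieved_proportion",
]

STATE_NAMES = ("stroke_free", "acute_stroke", "post_stroke", "dead_stroke", "dead_other")
STATE_CODES = {s: i for i, s in enumerate(STATE_NAMES)}

#: continuous fields that may carry missing values / be imputed
CONTINUOUS_FIELDS = ("hba1c", "sbp", "dbp", "lipid_ratio", "bmi")


class InfeasibleTargetError(ValueError):
    """Calibration target lies outside the achievable range [f(0), f(1)]."""


def _entropy(seed: int) -> int:
    # SeedSequence wants a non-negative integer; fold arbitrary ints in.
    return int(seed) & 0xFFFFFFFFFFFFFFFF


@dataclass(frozen=True)
class Individual:
    """One simulated person at a point in time."""

    id: int
    age: float
    sex: str  # male | female
    weight: float
    hba1c: float
    sbp: float
    dbp: float
    lipid_ratio: float
    bmi: float
    smoker: bool
    mi_history: bool
    afib: bool
    ckd: bool
    family_history_ascvd: bool
    high_bleeding_risk: bool
    chf: bool = False
    glycemic_level: int = 0
    bp_level: int = 0
    acei_arb: bool = False
    statin: str = "none"  # none | moderate | high
    aspirin: bool = False
    anticoagulant: str = "none"  # none | warfarin | noac
    state: str = "stroke_free"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigError(f"sex must be male/female, got {self.sex!r}")
        if self.statin not in policy.STATIN_CODES:
            raise ConfigError(f"bad statin level {self.statin!r}")
        if self.anticoagulant not in policy.AC_CODES:
            raise ConfigError(f"bad anticoagulant {self.anticoagulant!r}")
        if self.state not in STATE_CODES:
            raise ConfigError(f"bad state {self.state!r}")
        if self.weight <= 0:
            raise ConfigError("survey weight must be > 0")
        if not (0 <= self.glycemic_level <= policy.GLYCEMIC_MAX_RUNG):
            raise ConfigError("glycemic_level outside ladder")
        if not (0 <= self.bp_level <= policy.BP_MAX_RUNG):
            raise ConfigError("bp_level outside ladder")

    # attribute views matching the vectorized cohort naming
    @property
    def male(self) -> bool:
        return self.sex == "male"

    @property
    def statin_code(self) -> int:
        return policy.STATIN_CODES[self.statin]

    @property
    def anticoag_code(self) -> int:
        return policy.AC_CODES[self.anticoagulant]

    @property
    def state_code(self) -> int:
        return STATE_CODES[self.state]


_ARRAY_SPEC = [
    ("id", np.int64), ("weight", float), ("age", float), ("male", bool),
    ("hba1c", float), ("sbp", float), ("dbp", float), ("lipid_ratio", float),
    ("bmi", float), ("smoker", bool), ("mi_history", bool), ("afib", bool),
    ("ckd", bool), ("family_history_ascvd", bool), ("high_bleeding_risk", bool),
    ("chf", bool), ("glycemic_level", np.int64), ("bp_level", np.int64),
    ("acei_arb", bool), ("statin_code", np.int64), ("aspirin", bool),
    ("anticoag_code", np.int64), ("state_code", np.int64),
]


@dataclass
class CohortArrays:
    """Struct-of-arrays view of a cohort, mutable, used by the engine."""

    id: np.ndarray
    weight: np.ndarray
    age: np.ndarray
    male: np.ndarray
    hba1c: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    lipid_ratio: np.ndarray
    bmi: np.ndarray
    smoker: np.ndarray
    mi_history: np.ndarray
    afib: np.ndarray
    ckd: np.ndarray
    family_history_ascvd: np.ndarray
    high_bleeding_risk: np.ndarray
    chf: np.ndarray
    glycemic_level: np.ndarray
    bp_level: np.ndarray
    acei_arb: np.ndarray
    statin_code: np.ndarray
    aspirin: np.ndarray
    anticoag_code: np.ndarray
    state_code: np.ndarray

    @property
    def n(self) -> int:
        return self.id.shape[0]

    def copy(self) -> "CohortArrays":
        return CohortArrays(**{f.name: getattr(self, f.name).copy()
                               for f in dc_fields(self)})


class Population:
    """A weighted cohort: a DataFrame with one row per individual.

    Columns follow the :class:`Individual` field names (sex/statin/
    anticoagulant/state as strings) plus per-strategy baseline achievement
    flags ``ach_<strategy>``.  Missing values in the continuous risk-factor
    columns are NaN (empty cells on disk).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_weight(self) -> float:
        return float(self.df["weight"].sum()) if len(self.df) else 0.0

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.df[list(CONTINUOUS_FIELDS)].isna().any().any())

    def arrays(self) -> CohortArrays:
        """Numeric struct-of-arrays copy (requires a complete population)."""
        if self.has_missing():
            raise ConfigError("cannot build simulation arrays from a population "
                              "with missing values; impute first")
        df = self.df
        kwargs = {}
        for name, dtype in _ARRAY_SPEC:
            if name == "male":
                kwargs[name] = (df["sex"] == "male").to_numpy()
            elif name == "statin_code":
                kwargs[name] = df["statin"].map(policy.STATIN_CODES).to_numpy(np.int64)
            elif name == "anticoag_code":
                kwargs[name] = df["anticoagulant"].map(policy.AC_CODES).to_numpy(np.int64)
            elif name == "state_code":
                kwargs[name] = df["state"].map(STATE_CODES).to_numpy(np.int64)
            else:
                # copy=True: the engine mutates these arrays in place and must
                # never write through into the backing DataFrame
                kwargs[name] = df[name].to_numpy(dtype, copy=True)
        return CohortArrays(**kwargs)

    def to_individuals(self) -> list[Individual]:
        cols = [f.name for f in dc_fields(Individual)]
        return [Individual(**{c: rec[c] for c in cols})
                for rec in self.df[cols].to_dict("records")]

    @classmethod
    def from_individuals(cls, individuals: list[Individual]) -> "Population":
        rows = [{f.name: getattr(ind, f.name) for f in dc_fields(Individual)}
                for ind in individuals]
        df = pd.DataFrame(rows)
        for s in STRATEGIES:
            df[f"ach_{s}"] = False
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Population":
        df = pd.read_csv(path)
        bool_cols = [c for c in df.columns
                     if c.startswith("ach_") or c in (
                         "smoker", "mi_history", "afib", "ckd", "family_history_ascvd",
                         "high_bleeding_risk", "chf", "acei_arb", "aspirin")]
        for c in bool_cols:
            if df[c].dtype == object:
                df[c] = df[c].map({"True": True, "False": False}).astype(bool)
            else:
                df[c] = df[c].astype(bool)
        return cls(df)


@dataclass
class ImputedPopulationSet:
    """M complete populations sharing ids, weights, and observed fields."""

    imputations: list[Population]

    def __post_init__(self) -> None:
        if len(self.imputations) < 1:
            raise ConfigError("need at least one imputation")
        ids0 = self.imputations[0].df["id"].to_numpy()
        w0 = self.imputations[0].weights
        for pop in self.imputations[1:]:
            if not np.array_equal(pop.df["id"].to_numpy(), ids0):
                raise ConfigError("imputations must share individual ids")
            if not np.array_equal(pop.weights, w0):
                raise ConfigError("imputations must share survey weights")

    @property
    def M(self) -> int:
        return len(self.imputations)

    def __iter__(self):
        return iter(self.imputations)

    def __getitem__(self, m: int) -> Population:
        return self.imputations[m]


# -------------------------------------------------------- marginal plumbing
def _trunc_cdf(m: Marginal, x):
    """CDF of the quantile-truncated marginal on [lo, hi]."""
    if m.dist == "normal":
        d = stats.norm(m.mean, m.sd)
    else:
        d = stats.lognorm(s=m.sd, scale=np.exp(m.mean))
    clo, chi = d.cdf(m.lo), d.cdf(m.hi)
    return np.clip((d.cdf(x) - clo) / (chi - clo), 0.0, 1.0)


def _trunc_ppf(m: Marginal, u):
    if m.dist == "normal":
        d = stats.norm(m.mean, m.sd)
    else:
        d = stats.lognorm(s=m.sd, scale=np.exp(m.mean))
    clo, chi = d.cdf(m.lo), d.cdf(m.hi)
    return d.ppf(clo + np.clip(u, 0.0, 1.0) * (chi - clo))


_EPS = 1e-9


def _flag_interval(m: Marginal, threshold, below: np.ndarray):
    """(lo, hi) uniform sub-interval for achievers (below threshold) vs not."""
    c = np.clip(_trunc_cdf(m, threshold), _EPS, 1.0 - _EPS)
    lo = np.where(below, 0.0, c)
    hi = np.where(below, c, 1.0)
    return lo, hi


def _map_with_flag(m: Marginal, u, threshold, below):
    lo, hi = _flag_interval(m, threshold, below)
    return _trunc_ppf(m, lo + u * (hi - lo))


def _invert_with_flag(m: Marginal, x, threshold, below):
    """Recover the copula uniform from an observed value and its flag."""
    lo, hi = _flag_interval(m, threshold, below)
    u = (_trunc_cdf(m, x) - lo) / (hi - lo)
    return np.clip(u, _EPS, 1.0 - _EPS)


def _afib_prob(age: np.ndarray, prevs: tuple[float, ...]) -> np.ndarray:
    band = np.clip(((np.asarray(age) - 45) // 10).astype(int), 0, len(prevs) - 1)
    return np.asarray(prevs, dtype=float)[band]


# ----------------------------------------------------------------- generator
def generate_population(config: PopulationConfig, seed: int,
                        spec: GuidelineSpec | None = None) -> Population:
    """Generate a synthetic survey-weighted cohort.

    Deterministic in (config, seed).  Weighted per-strategy achievement
    proportions converge to ``config.target_proportions`` as n grows.
    """
    spec = spec or GuidelineSpec()
    n = config.n
    cols = ([name for name, _ in _ARRAY_SPEC if name not in
             ("male", "statin_code", "anticoag_code", "state_code")]
            + ["sex", "statin", "anticoagulant", "state"]
            + [f"ach_{s}" for s in STRATEGIES])
    if n == 0:
        return Population(pd.DataFrame({c: [] for c in cols}))

    rng = np.random.default_rng(np.random.SeedSequence(_entropy(seed)))
    marg = config.marginals
    tp = config.target_proportions

    # correlated copula uniforms over (age, hba1c, sbp, lipid_ratio, bmi)
    L = np.linalg.cholesky(config.correlation + 1e-12 * np.eye(5))
    z = rng.standard_normal((n, 5)) @ L.T
    u = stats.norm.cdf(z)

    # independent achievement flags at the configured proportions
    uf = rng.uniform(size=(n, len(STRATEGIES)))
    flag = {s: uf[:, i] < tp[s] for i, s in enumerate(STRATEGIES)}

    age = _trunc_ppf(marg["age"], u[:, 0])
    hba1c = _map_with_flag(marg["hba1c"], u[:, 1], spec.hba1c_target(age),
                           flag["glycemic"])
    sbp = _map_with_flag(marg["sbp"], u[:, 2], spec.bp_target[0], flag["bp"])
    lipid = _trunc_ppf(marg["lipid_ratio"], u[:, 3])
    bmi = _map_with_flag(marg["bmi"], u[:, 4], spec.weight_loss_bmi_floor,
                         flag["weight"])
    # diastolic pressure: independent marginal, truncated below target for
    # BP achievers so the full criterion (SBP and DBP and ACEi/ARB) holds
    dbp = _map_with_flag(marg["dbp"], rng.uniform(size=n), spec.bp_target[1],
                         flag["bp"])

    male = rng.uniform(size=n) < config.male_fraction
    smoker = ~flag["smoking"]
    mi_history = rng.uniform(size=n) < config.mi_history_prev
    ckd = rng.uniform(size=n) < config.ckd_prev
    famhx = rng.uniform(size=n) < config.family_history_prev
    bleed = rng.uniform(size=n) < config.bleeding_risk_prev
    chf = rng.uniform(size=n) < config.chf_prev
    afib = rng.uniform(size=n) < _afib_prob(age, config.afib_prev_by_age)

    # BP treatment assigned jointly with control status
    bp_level = np.zeros(n, dtype=np.int64)
    bp_level[flag["bp"]] = rng.integers(1, 5, size=int(flag["bp"].sum()))
    uncontrolled = ~flag["bp"]
    treated_unc = uncontrolled & (rng.uniform(size=n) < 0.6)
    bp_level[treated_unc] = rng.integers(1, 5, size=int(treated_unc.sum()))
    acei_arb = flag["bp"] | (uncontrolled & (rng.uniform(size=n) < config.acei_untreated_frac))

    glycemic_level = np.where(
        flag["glycemic"],
        rng.choice(5, size=n, p=config.glycemic_rung_probs_achiever),
        rng.choice(5, size=n, p=config.glycemic_rung_probs_other),
    ).astype(np.int64)

    cohort = CohortArrays(
        id=np.arange(n, dtype=np.int64),
        weight=np.ones(n), age=age, male=male, hba1c=hba1c, sbp=sbp, dbp=dbp,
        lipid_ratio=lipid, bmi=bmi, smoker=smoker, mi_history=mi_history,
        afib=afib, ckd=ckd, family_history_ascvd=famhx, high_bleeding_risk=bleed,
        chf=chf, glycemic_level=glycemic_level, bp_level=bp_level,
        acei_arb=acei_arb, statin_code=np.zeros(n, dtype=np.int64),
        aspirin=np.zeros(n, dtype=bool), anticoag_code=np.zeros(n, dtype=np.int64),
        state_code=np.zeros(n, dtype=np.int64),
    )

    # statin intensity, aspirin and anticoagulation depend on the fields above
    rec_statin = policy.recommended_statin_intensity(cohort, spec)
    cohort.statin_code = np.where(flag["statin"], rec_statin, policy.STATIN_NONE)
    eligible_asp = policy.aspirin_eligible(cohort, spec)
    cohort.aspirin = eligible_asp & flag["aspirin"]
    high_risk = cohort.afib & (
        policy.chads_vasc(cohort, sbp_cut=spec.bp_target[0]) >= spec.chads_vasc_threshold)
    on_ac = high_risk & flag["anticoagulant"]
    warf = rng.uniform(size=n) < 0.5
    cohort.anticoag_code = np.where(on_ac, np.where(warf, policy.AC_WARFARIN,
                                                    policy.AC_NOAC), policy.AC_NONE)

    # survey weights: lognormal dispersion normalized to the national total
    if config.weight_cv > 0:
        sigma = np.sqrt(np.log1p(config.weight_cv**2))
        w = rng.lognormal(-sigma**2 / 2, sigma, size=n)
    else:
        w = np.ones(n)
    cohort.weight = w * (config.total_weight / w.sum())

    df = pd.DataFrame({
        "id": cohort.id, "age": cohort.age,
        "sex": np.where(cohort.male, "male", "female"),
        "weight": cohort.weight, "hba1c": cohort.hba1c, "sbp": cohort.sbp,
        "dbp": cohort.dbp, "lipid_ratio": cohort.lipid_ratio, "bmi": cohort.bmi,
        "smoker": cohort.smoker, "mi_history": cohort.mi_history,
        "afib": cohort.afib, "ckd": cohort.ckd,
        "family_history_ascvd": cohort.family_history_ascvd,
        "high_bleeding_risk": cohort.high_bleeding_risk, "chf": cohort.chf,
        "glycemic_level": cohort.glycemic_level, "bp_level": cohort.bp_level,
        "acei_arb": cohort.acei_arb,
        "statin": pd.Series(cohort.statin_code).map(policy.STATIN_NAMES),
        "aspirin": cohort.aspirin,
        "anticoagulant": pd.Series(cohort.anticoag_code).map(policy.AC_NAMES),
        "state": "stroke_free",
    })
    for s in STRATEGIES:
        num, _denom = strategy_achievement(cohort, s, spec)
        df[f"ach_{s}"] = num
    return Population(df)


# -------------------------------------------------------------- achievement
def strategy_achievement(cohort, strategy: str, spec: GuidelineSpec
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(numerator, denominator) masks for one strategy's achievement criterion.

    Aspirin and anticoagulation are measured among the eligible (aspirin
    criteria / high-risk atrial fibrillation); the other five over everyone.
    """
    n = np.asarray(cohort.age).shape[0] if np.asarray(cohort.age).ndim else 1
    denom = np.ones(n, dtype=bool)
    if strategy == "glycemic":
        num = np.asarray(cohort.hba1c) < spec.hba1c_target(cohort.age)
    elif strategy == "bp":
        num = ((np.asarray(cohort.sbp) < spec.bp_target[0])
               & (np.asarray(cohort.dbp) < spec.bp_target[1])
               & np.asarray(cohort.acei_arb))
    elif strategy == "statin":
        num = np.asarray(cohort.statin_code) == policy.recommended_statin_intensity(
            cohort, spec)
    elif strategy == "aspirin":
        denom = np.asarray(policy.aspirin_eligible(cohort, spec))
        num = np.asarray(cohort.aspirin) & denom
    elif strategy == "smoking":
        num = ~np.asarray(cohort.smoker)
    elif strategy == "weight":
        num = np.asarray(cohort.bmi) < spec.weight_loss_bmi_floor
    elif strategy == "anticoagulant":
        denom = np.asarray(cohort.afib) & (
            policy.chads_vasc(cohort, sbp_cut=spec.bp_target[0])
            >= spec.chads_vasc_threshold)
        num = (np.asarray(cohort.anticoag_code) != policy.AC_NONE) & denom
    else:
        raise ConfigError(f"unknown strategy {strategy!r}")
    num = np.broadcast_to(np.asarray(num), (n,)) & denom
    return num, denom


def achieved_proportion(cohort, strategy: str, spec: GuidelineSpec) -> float:
    """Survey-weighted fraction achieving the strategy (among its denominator)."""
    num, denom = strategy_achievement(cohort, strategy, spec)
    w = np.asarray(cohort.weight)
    wd = float(w[denom].sum())
    if wd == 0:
        return float("nan")
    return float(w[num].sum() / wd)


# ----------------------------------------------------------------- imputation
def _copula_z(pop: Population, config: PopulationConfig, spec: GuidelineSpec
              ) -> np.ndarray:
    """Latent copula z-scores for (age, hba1c, sbp, lipid_ratio, bmi); NaN
    where the value is missing."""
    df = pop.df
    marg = config.marginals
    age = df["age"].to_numpy(float)
    out = np.full((len(df), 5), np.nan)
    out[:, 0] = stats.norm.ppf(np.clip(_trunc_cdf(marg["age"], age), _EPS, 1 - _EPS))
    specs = [
        ("hba1c", 1, spec.hba1c_target(age), df["ach_glycemic"].to_numpy(bool)),
        ("sbp", 2, spec.bp_target[0], df["ach_bp"].to_numpy(bool)),
        ("lipid_ratio", 3, None, None),
        ("bmi", 4, spec.weight_loss_bmi_floor, df["ach_weight"].to_numpy(bool)),
    ]
    for name, j, thr, below in specs:
        x = df[name].to_numpy(float)
        obs = ~np.isnan(x)
        if thr is None:
            uu = np.clip(_trunc_cdf(marg[name], x[obs]), _EPS, 1 - _EPS)
        else:
            thr_arr = np.broadcast_to(np.asarray(thr, dtype=float), x.shape)
            uu = _invert_with_flag(marg[name], x[obs], thr_arr[obs], below[obs])
        out[obs, j] = stats.norm.ppf(uu)
    return out


def impute(pop: Population, config: PopulationConfig, M: int, seed: int,
           spec: GuidelineSpec | None = None) -> ImputedPopulationSet:
    """Draw M completions of a population with missing risk-factor values.

    Missing copula fields are redrawn from the conditional Gaussian given the
    observed fields' latent z-scores, then mapped through the same
    flag-truncated marginal used at generation, so imputations are samples
    from the generator's conditional model.  DBP (outside the copula) is
    redrawn from its flag-truncated marginal.
    """
    if M < 1:
        raise ConfigError(f"M must be >= 1, got {M}")
    spec = spec or GuidelineSpec()
    if not pop.has_missing():
        return ImputedPopulationSet([Population(pop.df.copy()) for _ in range(M)])

    rng = np.random.default_rng(np.random.SeedSequence(_entropy(seed)))
    marg = config.marginals
    corr = config.correlation
    z = _copula_z(pop, config, spec)
    df0 = pop.df
    age = df0["age"].to_numpy(float)
    thr_by_field = {
        "hba1c": (spec.hba1c_target(age), df0["ach_glycemic"].to_numpy(bool)),
        "sbp": (np.full(len(df0), spec.bp_target[0]), df0["ach_bp"].to_numpy(bool)),
        "lipid_ratio": (None, None),
        "bmi": (np.full(len(df0), spec.weight_loss_bmi_floor),
                df0["ach_weight"].to_numpy(bool)),
    }
    col_of = {"hba1c": 1, "sbp": 2, "lipid_ratio": 3, "bmi": 4}

    imputations = []
    for _m in range(M):
        df = df0.copy()
        # group rows by missing pattern over the four imputable copula fields
        miss = np.isnan(z[:, 1:5])
        if miss.any():
            patterns = {}
            for i in np.nonzero(miss.any(axis=1))[0]:
                patterns.setdefault(tuple(miss[i]), []).append(i)
            for pat, rows in patterns.items():
                rows = np.asarray(rows)
                mis_cols = np.array([j + 1 for j, m_ in enumerate(pat) if m_])
                obs_cols = np.array([j for j in range(5) if j not in mis_cols])
                s_oo = corr[np.ix_(obs_cols, obs_cols)]
                s_mo = corr[np.ix_(mis_cols, obs_cols)]
                s_mm = corr[np.ix_(mis_cols, mis_cols)]
                a = s_mo @ np.linalg.inv(s_oo)
                cond_cov = s_mm - a @ s_mo.T
                cond_mean = z[np.ix_(rows, obs_cols)] @ a.T
                L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(len(mis_cols)))
                draws = cond_mean + rng.standard_normal(
                    (len(rows), len(mis_cols))) @ L.T
                uu = stats.norm.cdf(draws)
                for k, j in enumerate(mis_cols):
                    name = [nm for nm, jj in col_of.items() if jj == j][0]
                    thr, below = thr_by_field[name]
                    if thr is None:
                        vals = _trunc_ppf(marg[name], uu[:, k])
                    else:
                        vals = _map_with_flag(marg[name], uu[:, k], thr[rows],
                                              below[rows])
                    df.loc[rows, name] = vals
        dbp = df0["dbp"].to_numpy(float)
        dmiss = np.nonzero(np.isnan(dbp))[0]
        if dmiss.size:
            below = df0["ach_bp"].to_numpy(bool)[dmiss]
            df.loc[dmiss, "dbp"] = _map_with_flag(
                marg["dbp"], rng.uniform(size=dmiss.size),
                np.full(dmiss.size, spec.bp_target[1]), below)
        imputations.append(Population(df))
    return ImputedPopulationSet(imputations)


def apply_missingness_and_impute(pop: Population, config: PopulationConfig,
                                 M: int, seed: int,
                                 spec: GuidelineSpec | None = None
                                 ) -> ImputedPopulationSet:
    """Mask fields missing-completely-at-random at the configured rates, then
    produce M conditional-model completions."""
    if M < 1:
        raise ConfigError(f"M must be >= 1, got {M}")
    rng = np.random.default_rng(np.random.SeedSequence([_entropy(seed), 0x5EED]))
    df = pop.df.copy()
    for fname, rate in config.missingness_rates.items():
        if fname not in CONTINUOUS_FIELDS:
            raise ConfigError(f"missingness only supported for {CONTINUOUS_FIELDS}, "
                              f"got {fname!r}")
        if rate > 0 and len(df):
            mask = rng.uniform(size=len(df)) < rate
            df.loc[mask, fname] = np.nan
    return impute(Population(df), config, M, seed, spec)


# ---------------------------------------------------------------- calibration
def calibrate_adherence(pop: Population, strategy: str, target: float,
                        spec: GuidelineSpec, registry: ParameterRegistry,
                        tol: float = 0.005, seed: int = 0) -> float:
    """Adherence probability reproducing a target achievement proportion.

    Simulates one status-quo year (recommend -> adopt with probability ``a``
    -> natural-history drift) and bisects on ``a``.  Fixed uniforms make the
    achieved proportion a nondecreasing step function of ``a``, so bisection
    is exact up to the step resolution.
    """
    from .engine import apply_drift  # deferred: engine imports this module

    if not (0 <= target <= 1):
        raise ConfigError(f"target proportion must be in [0, 1], got {target}")
    if tol <= 0:
        raise ConfigError("tol must be > 0")
    base = pop.arrays()
    rng = np.random.default_rng(np.random.SeedSequence([_entropy(seed), 0xCA11]))
    uniforms = rng.uniform(size=(base.n, policy.N_POLICY_SLOTS))

    def achieved(a: float) -> float:
        c = base.copy()
        masks = policy.recommend_masks(c, {strategy}, spec, year=0)
        policy.apply_recommendations(c, masks, {strategy: a}, uniforms, spec, registry)
        apply_drift(c, registry)
        return achieved_proportion(c, strategy, spec)

    f0, f1 = achieved(0.0), achieved(1.0)
    if abs(f0 - target) <= tol:
        return 0.0
    if abs(f1 - target) <= tol:
        return 1.0
    if not (f0 - tol <= target <= f1 + tol):
        raise InfeasibleTargetError(
            f"{strategy}: target {target:.3f} outside the feasible achieved range "
            f"[{f0:.3f}, {f1:.3f}]")
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = achieved(mid)
        if abs(fm - target) <= tol:
            return mid
        if fm < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return 0.5 * (lo + hi)


def calibrate_status_quo(pop: Population, config: PopulationConfig,
                         spec: GuidelineSpec, registry: ParameterRegistry,
                         tol: float = 0.005, seed: int = 0) -> dict[str, float]:
    """Status-quo adherence for all strategies from the configured targets.

    The weight strategy carries no status-quo program (natural BMI drift
    only), so its status-quo adherence is fixed at 0.  Each remaining
    strategy is calibrated to *maintain the cohort's own realized baseline
    proportion* through one annual cycle: the generated baseline already
    matches the national target up to sampling noise, so this offsets the
    genuine erosion from risk-factor drift without spending adherence on
    finite-sample noise.  Proportions the cycle cannot erode map to 0.
    """
    arrays = pop.arrays()
    out: dict[str, float] = {}
    for s in STRATEGIES:
        if s == "weight":
            out[s] = 0.0
            continue
        target = achieved_proportion(arrays, s, spec)
        try:
            out[s] = calibrate_adherence(pop, s, target, spec, registry,
                                         tol=tol, seed=seed)
        except InfeasibleTargetError:
            base = achieved_proportion(arrays, s, spec)
            out[s] = 0.0 if target <= base else 1.0
    return out
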