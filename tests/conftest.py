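import numpy as np
import pandas as pd
import pytest

from strokesim import GuidelineSpec, Population, PopulationConfig, default_registry
from strokesim.config import STRATEGIES


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def spec():
    return GuidelineSpec()


@pytest.fixture(scope="session")
def small_config():
    return PopulationConfig(n=400)


def make_population(n, *, weight=1.0, **overrides) -> Population:
    """Hand-built cohort of identical individuals; any column overridable
    with a scalar or an array."""
    base = {
        "id": np.arange(n), "age": 60.0, "sex": "female", "weight": weight,
        "hba1c": 6.5, "sbp": 120.0, "dbp": 70.0, "lipid_ratio": 3.5,
        "bmi": 24.0, "smoker": False, "mi_history": False, "afib": False,
        "ckd": False, "family_history_ascvd": False,
        "high_bleeding_risk": False, "chf": False, "glycemic_level": 1,
        "bp_level": 1, "acei_arb": True, "statin": "none", "aspirin": False,
        "anticoagulant": "none", "state": "stroke_free",
    }
    base.update(overrides)
    df = pd.DataFrame({k: (v if np.ndim(v) else np.repeat(v, n))
                       for k, v in base.items()})
    for s in STRATEGIES:
        df[f"ach_{s}"] = False
    return Population(df)
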