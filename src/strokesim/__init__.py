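"""strokesim: microsimulation cost-effectiveness analysis of primary stroke
prevention in U.S. adults >= 45 years with type 2 diabetes.

Pipeline: synthetic survey-weighted cohort generation -> annual-cycle
individual-level disease simulation (stroke, MI, death, hypoglycemia) ->
enhanced-implementation scenario comparison -> ICER / net-health-benefit
cost-effectiveness reporting.
"""

from importlib import resources

import pandas as pd

from .config import (AnalysisConfig, GuidelineSpec, PopulationConfig,
                     ScenarioSpec, SimDesign, STRATEGIES, load_config)
from .econ import (CEAResult, CostSchedule, ICERResult, UtilitySchedule,
                   classify_cost_effectiveness, discount, icer, nhb,
                   uncertainty_interval)
from .engine import (AnnualRecord, annual_hazards, simulate_cohort,
                     simulate_individual, transition, update_risk_factors)
from .population import (CohortArrays, ImputedPopulationSet, Individual,
                         Population, achieved_proportion,
                         apply_missingness_and_impute, calibrate_adherence,
                         calibrate_status_quo, generate_population)
from .registry import Parameter, ParameterRegistry, default_registry
from .scenarios import (SimulationResult, build_catalog, compare, compare_all,
                        results_table, run, run_owsa, scale_adherence)

__version__ = "0.1.0"


def reference_basecase_table() -> pd.DataFrame:
    """Published national 10-year base-case incremental outcomes (2022 USD)
    used as cross-check inputs for the cost-effectiveness calculus: events
    and QALYs in thousands, costs in billions of dollars."""
    ref = resources.files("strokesim.data").joinpath("us_basecase_table.csv")
    with resources.as_file(ref) as path:
        # keep_default_na: the ICER column uses the literal label "NA"
        return pd.read_csv(path, keep_default_na=False)
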