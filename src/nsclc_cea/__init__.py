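"""Markov cohort cost-effectiveness model of first-line immunotherapy
strategies for advanced non-small cell lung cancer across PD-L1 strata.

Typical use::

    from nsclc_cea import fixture_parameter_set, basecase

    ps = fixture_parameter_set(seed=1)          # synthetic curves + shipped costs
    result = basecase(ps, "ge50")               # frontier, labels, ICERs
    print(result.to_frame())
"""

from .errors import (CalibrationError, NonMonotoneError, NSCLCCEAError,
                     ParameterValidationError, SchemaError,
                     StrategyUnavailableError, ThresholdNotFoundError,
                     UndefinedICERError, UnknownParameterError)
from .frontier import (FrontierResult, compute_frontier, icer,
                       net_monetary_benefit)
from .markov import (CohortTrace, StrategyOutcome, accrue_costs, accrue_qalys,
                     discount_factor, evaluate_strategy, microsim_oracle,
                     run_cohort)
from .params import (DistributionSpec, EconomicParams, HazardRatioSpec,
                     ParameterSet, StrategyDefinition, Stratum, SurvivalCurve,
                     builtin_parameter_set, get_parameter, load_parameter_set,
                     published_basecase_file, read_survival_curve,
                     set_parameter, validate_parameter_set,
                     write_parameter_set, write_survival_curve)
from .pipeline import basecase, evaluate_all, reference_schedule
from .sensitivity import (CEACurve, PSADraw, TornadoEntry, ceac, one_way_dsa,
                          run_dsa, run_psa, sample_parameters,
                          scenario_hr_bounds, threshold_price, tornado)
from .survival import (TransitionSchedule, apply_hazard_ratio,
                       build_arm_schedule, calibrate_pd_death,
                       calibrate_reference, extrapolate_schedule,
                       pfs_to_transitions, prob_to_rate, rate_to_prob)
from .synthetic import (PiecewiseExpSpec, fixture_parameter_set,
                        make_cohort_curves, make_fixture_study,
                        make_survival_curve)

__version__ = "0.1.0"


def published_basecase_outcomes():
    """The published base-case (cost, LY, QALY) triples, as StrategyOutcome
    lists per stratum — inputs for frontier validation."""
    import pandas as pd

    df = pd.read_csv(published_basecase_file(), comment="#")
    out = {}
    for stratum, grp in df.groupby("stratum", sort=False):
        out[stratum] = [
            StrategyOutcome(strategy=r.strategy, cost=float(r.cost),
                            life_years=float(r.life_years), qalys=float(r.qalys))
            for r in grp.itertuples()
        ]
    return out, df
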