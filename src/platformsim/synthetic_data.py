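"""Synthetic inputs: expert-survey response tables and scaled test fixtures.

The pipeline consumes only the elicited (mean, SD) pairs, so the survey
generator draws respondent answers from the same distribution families the
analysis assumes (lognormal for costs, positive normal for times) around a
known ground truth; fitting the responses back with sample moments must
recover that truth within sampling error.  Respondent non-response and
disagreement structure are not modelled.

``make_fixture`` builds complete (scenarios, parameter table) inputs at three
scales: ``paper`` (the full default configuration), ``small`` (event
triggers, caps and entry offsets shrunk ~10x for fast stochastic tests) and
``tiny`` (a single 2-group trial with ~20 patients and single-digit event
triggers for unit tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .params import (
    ElicitedParameter,
    ParameterTable,
    default_parameter_table,
    estimate_moments,
    sample_parameter,
)
from .scenarios import ScenarioConfig, ScenarioSpec, default_scenarios, scale_config
from .trial_engine import AnalysisSchedule, ArmSpec, TrialDesign

#: Number of experts who completed the elicitation survey.
DEFAULT_N_RESPONDENTS = 16

SCALES = ("tiny", "small", "paper")


@dataclass(frozen=True)
class SurveyTruth:
    """Ground-truth elicited distribution per survey question."""

    parameters: tuple[ElicitedParameter, ...]
    n_respondents: int = DEFAULT_N_RESPONDENTS

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise InvalidParameterError("need at least 2 respondents")


def default_survey_truth(n_respondents: int = DEFAULT_N_RESPONDENTS) -> SurveyTruth:
    """Truth equal to the packaged elicited-parameter table."""
    return SurveyTruth(
        parameters=tuple(default_parameter_table()), n_respondents=n_respondents
    )


def generate_survey_responses(
    truth: SurveyTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one response table: one row per (parameter, respondent).

    Responses follow the truth's family with its (mean, SD): mean-anchored
    lognormal for costs, plain (untruncated) normal for times, so that the
    sample moments of the responses are unbiased for the truth.  The
    positivity constraint applied when *sampling* time parameters for the
    cost model is not part of the elicitation noise model; imposing it here
    would bias recovered means upward for high-CV time quantities.
    """
    rows = []
    for p in truth.parameters:
        if p.family == "normal":
            values = (
                np.full(truth.n_respondents, p.mean)
                if p.sd == 0.0
                else rng.normal(p.mean, p.sd, truth.n_respondents)
            )
        else:
            values = sample_parameter(
                p, rng, size=truth.n_respondents, lognormal_anchor="mean"
            )
        values = np.atleast_1d(np.asarray(values, dtype=float))
        for r, v in enumerate(values):
            rows.append(
                {
                    "name": p.name,
                    "design_type": p.design_type,
                    "respondent": r + 1,
                    "response": float(v),
                }
            )
    return pd.DataFrame(rows)


def fit_survey(responses: pd.DataFrame, template: SurveyTruth) -> ParameterTable:
    """Summarize responses back into a parameter table (sample mean/SD)."""
    table = ParameterTable()
    grouped = responses.groupby(["name", "design_type"])["response"]
    for p in template.parameters:
        mean, sd = estimate_moments(grouped.get_group((p.name, p.design_type)))
        table.add(
            ElicitedParameter(
                name=p.name,
                design_type=p.design_type,
                mean=mean,
                sd=sd,
                family=p.family,
                unit=p.unit,
                basis=p.basis,
            )
        )
    return table


def _tiny_scenarios(effect_case: str) -> list[ScenarioSpec]:
    schedule = AnalysisSchedule(
        futility_event_triggers=(3, 5, 7),
        futility_hr_thresholds=(1.0, 0.92, 0.89),
        final_death_trigger=8,
    )
    design = TrialDesign(
        design_type="two_group",
        n_sites=10,
        arms=(ArmSpec(label="arm01", cap=10, hr_ffs=0.75, hr_os=0.75),),
        accrual_per_site_year=10.0,
        control_weight_initial=1.0,
        control_median_ffs=12.0,
        control_median_os=24.0,
        schedule=schedule,
    )
    return [ScenarioSpec(id=3, trials=((design, 0.0),), effect_case=effect_case)]


def make_fixture(
    scale: str = "small",
    effect_case: str = "base",
    config: ScenarioConfig | None = None,
) -> tuple[list[ScenarioSpec], ParameterTable]:
    """Deterministic (scenario specs, parameter table) at a named scale."""
    if scale not in SCALES:
        raise InvalidParameterError(f"unknown scale {scale!r}")
    table = default_parameter_table()
    if scale == "tiny":
        return _tiny_scenarios(effect_case), table
    config = config or ScenarioConfig()
    if scale == "small":
        config = scale_config(config, 10.0)
    return default_scenarios(effect_case, config), table
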