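"""Top-down costing of one simulated trial realization.

Costs are decomposed into four components, each driven by the exposure
tallies the trial simulator produces and by one Monte-Carlo draw of every
elicited parameter:

* **setup** -- protocol development + trial approvals + database development
  + per-site setup x number of sites;
* **conduct** -- recruitment per patient x enrolled + monthly follow-up per
  patient-month + monthly site management per site-month + monthly database
  management per trial-month;
* **analysis** -- per intervention arm, interim cost per look performed plus
  the final-analysis cost when the final was run;
* **arm addition** (platform only) -- one sampled add-a-group cost per added
  arm; the matching sampled lead time delays that arm's activation in the
  trial simulator.

Setup time assembles the three setup activities as protocol development first,
then approvals and database development in parallel (configurable to fully
sequential).  Total duration is setup time plus the conduct span from trial
start to the last analysis.  Components conserve exactly: the total is their
sum, with no discounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, InvalidDesignError
from .params import (
    DEFAULT_LOGNORMAL_ANCHOR,
    LognormalAnchor,
    ParameterTable,
    sample_parameter,
)
from .trial_engine import MONTHS_PER_YEAR, TrialDesign, TrialOutcome

SETUP_COST_PARAMS = ("protocol_development", "trial_approvals", "database_development")
SETUP_TIME_PARAMS = (
    "protocol_development_time",
    "trial_approvals_time",
    "database_development_time",
)
CONDUCT_PARAMS = (
    "recruitment_per_patient",
    "monthly_followup_per_patient",
    "site_management_per_site_month",
    "database_management_per_month",
)
ANALYSIS_PARAMS = ("interim_analysis_per_group", "final_analysis_per_group")

SETUP_SCHEDULES = ("protocol_then_parallel", "sequential")


@dataclass(frozen=True)
class CostBreakdown:
    """Cost components (USD 2021) and times (years) for one realization."""

    setup_cost: float
    conduct_cost: float
    analysis_cost: float
    add_arm_cost: float
    total_cost: float
    setup_time: float
    total_duration: float

    def __post_init__(self) -> None:
        for name in ("setup_cost", "conduct_cost", "analysis_cost", "add_arm_cost"):
            if getattr(self, name) < 0:
                raise ConsistencyError(f"{name} must be non-negative")


def sample_shared_params(
    table: ParameterTable,
    rng: np.random.Generator,
    *,
    lognormal_anchor: LognormalAnchor = DEFAULT_LOGNORMAL_ANCHOR,
) -> dict[str, float]:
    """One draw of every shared (design-independent) quantity, in a fixed
    order so common random numbers line up across scenarios."""
    names = ("site_setup",) + CONDUCT_PARAMS + ANALYSIS_PARAMS
    return {
        name: float(
            sample_parameter(
                table.lookup(name, "shared"), rng, lognormal_anchor=lognormal_anchor
            )
        )
        for name in names
    }


def sample_design_params(
    table: ParameterTable,
    design_type: str,
    rng: np.random.Generator,
    *,
    lognormal_anchor: LognormalAnchor = DEFAULT_LOGNORMAL_ANCHOR,
) -> dict[str, float]:
    """One draw of every design-type-specific setup quantity."""
    out: dict[str, float] = {}
    for name in SETUP_COST_PARAMS + SETUP_TIME_PARAMS:
        out[name] = float(
            sample_parameter(
                table.resolve(name, design_type), rng,
                lognormal_anchor=lognormal_anchor,
            )
        )
    return out


def sample_add_arm(
    table: ParameterTable,
    n_added: int,
    rng: np.random.Generator,
    *,
    lognormal_anchor: LognormalAnchor = DEFAULT_LOGNORMAL_ANCHOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-added-arm sampled (cost USD, lead time months) draws."""
    if n_added < 0:
        raise InvalidDesignError("n_added must be >= 0")
    if n_added == 0:
        return np.empty(0), np.empty(0)
    costs = sample_parameter(
        table.lookup("add_group_cost", "platform"), rng, size=n_added,
        lognormal_anchor=lognormal_anchor,
    )
    delays = sample_parameter(
        table.lookup("add_group_time", "platform"), rng, size=n_added,
        lognormal_anchor=lognormal_anchor,
    )
    return np.asarray(costs, float), np.asarray(delays, float)


def setup_cost(design: TrialDesign, sampled: dict[str, float]) -> float:
    """Protocol + approvals + database + per-site setup x sites."""
    try:
        fixed = sum(sampled[name] for name in SETUP_COST_PARAMS)
        per_site = sampled["site_setup"]
    except KeyError as exc:
        raise ConsistencyError(f"missing sampled parameter {exc}") from None
    return fixed + design.n_sites * per_site


def setup_time(
    design: TrialDesign,
    sampled: dict[str, float],
    schedule: str = "protocol_then_parallel",
) -> float:
    """Setup duration in years.

    Under ``protocol_then_parallel`` the protocol is written first and the
    approvals and database activities then run in parallel; ``sequential``
    chains all three.
    """
    if schedule not in SETUP_SCHEDULES:
        raise ConsistencyError(f"unknown setup schedule {schedule!r}")
    p = sampled["protocol_development_time"]
    a = sampled["trial_approvals_time"]
    d = sampled["database_development_time"]
    months = p + a + d if schedule == "sequential" else p + max(a, d)
    return months / MONTHS_PER_YEAR


def conduct_cost(outcome: TrialOutcome, sampled: dict[str, float]) -> float:
    """Recruitment, follow-up, site management and database management."""
    if min(outcome.patient_months_followup, outcome.site_months,
           outcome.trial_months) < 0 or outcome.total_enrolled < 0:
        raise ConsistencyError("negative exposure tallies")
    return (
        sampled["recruitment_per_patient"] * outcome.total_enrolled
        + sampled["monthly_followup_per_patient"] * outcome.patient_months_followup
        + sampled["site_management_per_site_month"] * outcome.site_months
        + sampled["database_management_per_month"] * outcome.trial_months
    )


def analysis_cost(outcome: TrialOutcome, sampled: dict[str, float]) -> float:
    """Per-arm: interims performed x interim cost + final cost if run.

    Analyses are pairwise versus control, so only intervention arms are
    charged ("per group" reads as per intervention group per occasion).
    """
    interim = sampled["interim_analysis_per_group"]
    final = sampled["final_analysis_per_group"]
    return sum(
        a.n_interims_performed * interim + (final if a.final_performed else 0.0)
        for a in outcome.arm_outcomes
    )


def add_arm_cost(design: TrialDesign, add_costs: np.ndarray) -> float:
    """Summed sampled add-a-group costs; only platform designs may add."""
    if add_costs.size and design.design_type != "platform":
        raise InvalidDesignError("only platform designs can add arms")
    return float(np.sum(add_costs))


def assemble(
    outcome: TrialOutcome,
    *,
    setup_cost: float,
    conduct_cost: float,
    analysis_cost: float,
    add_arm_cost: float,
    setup_time: float,
) -> CostBreakdown:
    """Totals with exact conservation; duration = setup + conduct span."""
    return CostBreakdown(
        setup_cost=setup_cost,
        conduct_cost=conduct_cost,
        analysis_cost=analysis_cost,
        add_arm_cost=add_arm_cost,
        total_cost=setup_cost + conduct_cost + analysis_cost + add_arm_cost,
        setup_time=setup_time,
        total_duration=setup_time + outcome.duration_conduct,
    )


def cost_trial(
    design: TrialDesign,
    outcome: TrialOutcome,
    sampled: dict[str, float],
    add_costs: np.ndarray | None = None,
    *,
    setup_schedule: str = "protocol_then_parallel",
) -> CostBreakdown:
    """Full costing of one trial realization from one parameter draw."""
    add_costs = add_costs if add_costs is not None else np.empty(0)
    return assemble(
        outcome,
        setup_cost=setup_cost(design, sampled),
        conduct_cost=conduct_cost(outcome, sampled),
        analysis_cost=analysis_cost(outcome, sampled),
        add_arm_cost=add_arm_cost(design, add_costs),
        setup_time=setup_time(design, sampled, setup_schedule),
    )


def simulate_setup_times(
    table: ParameterTable,
    design_type: str,
    n: int,
    rng: np.random.Generator,
    *,
    schedule: str = "protocol_then_parallel",
) -> np.ndarray:
    """Monte-Carlo setup times (years) for one trial of a design type.

    Draws the three setup-time parameters ``n`` times (normals resampled to
    positivity) and assembles them under the given schedule.  Used for the
    single-trial setup comparisons; the full pipeline draws per trial.
    """
    draws = {
        name: np.asarray(
            sample_parameter(table.resolve(name, design_type), rng, size=n)
        )
        for name in SETUP_TIME_PARAMS
    }
    p = draws["protocol_development_time"]
    a = draws["trial_approvals_time"]
    d = draws["database_development_time"]
    months = p + a + d if schedule == "sequential" else p + np.maximum(a, d)
    return months / MONTHS_PER_YEAR
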