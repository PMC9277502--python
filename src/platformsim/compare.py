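"""Monte-Carlo driver and matched-iteration scenario comparison.

Each Monte-Carlo iteration simulates every trial of every scenario and costs
it; scenarios are compared per iteration (matched across scenarios by the
iteration index) by the relative difference ``100 x (comparator - reference) /
reference`` of their cumulative totals, summarized by median and IQR.

Seeding is hierarchical -- master seed -> iteration -> scenario -> trial ->
stream -- so iterations are matched across scenarios and adding a scenario
never perturbs another's draws.  Quantities elicited as shared across trial
designs (site setup and management, recruitment, follow-up, database
management, analysis costs) are drawn once per iteration and reused by every
trial in every scenario, i.e. common random numbers within an iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .costing import (
    cost_trial,
    sample_add_arm,
    sample_design_params,
    sample_shared_params,
)
from .errors import InsufficientDataError, InvalidParameterError, PairingError
from .params import DEFAULT_LOGNORMAL_ANCHOR, ParameterTable, default_parameter_table
from .scenarios import ScenarioSpec
from .trial_engine import simulate_trial

#: Scenario-level totals collected per iteration.
METRICS = ("total_cost", "cumulative_duration", "setup_cost", "setup_time",
           "sample_size")


@dataclass
class MonteCarloResult:
    """Per-iteration, per-scenario cumulative totals.

    ``data`` has one row per (iteration, scenario) with the columns in
    :data:`METRICS`; ``trial_data`` one row per (iteration, scenario, trial).
    """

    data: pd.DataFrame
    trial_data: pd.DataFrame
    n_iterations: int
    master_seed: int

    def scenario_values(self, scenario_id: int, metric: str) -> np.ndarray:
        sel = self.data[self.data["scenario"] == scenario_id].sort_values("iteration")
        return sel[metric].to_numpy()


@dataclass(frozen=True)
class ComparisonSummary:
    """Median/IQR of matched relative differences plus mean/SD."""

    metric: str
    median_pct: float
    iqr_pct: tuple[float, float]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        q1, q3 = self.iqr_pct
        if not (q1 <= self.median_pct <= q3):
            raise InvalidParameterError("quartiles must bracket the median")


def _trial_rng(master_seed: int, iteration: int, scenario_id: int, trial_idx: int,
               stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(master_seed), int(iteration), int(scenario_id), int(trial_idx),
             int(stream)]
        )
    )


def run_monte_carlo(
    scenario_specs: Sequence[ScenarioSpec],
    n_iter: int,
    master_seed: int,
    *,
    table: ParameterTable | None = None,
    lognormal_anchor: str = DEFAULT_LOGNORMAL_ANCHOR,
    setup_schedule: str = "protocol_then_parallel",
    engine: bool = True,
) -> MonteCarloResult:
    """Run matched Monte-Carlo iterations over a set of scenarios.

    With ``engine=False`` the trial simulator is skipped and only the
    setup-phase quantities (setup cost and time) are generated -- they do not
    depend on simulated trial conduct -- which is faster when only setup
    comparisons are needed; conduct-dependent metrics are then NaN.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    table = table if table is not None else default_parameter_table()
    rows = []
    trial_rows = []
    for it in range(int(n_iter)):
        shared_rng = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), it, 0, 0, 0])
        )
        shared = sample_shared_params(
            table, shared_rng, lognormal_anchor=lognormal_anchor
        )
        for spec in scenario_specs:
            totals = dict.fromkeys(METRICS, 0.0)
            for j, (design, offset) in enumerate(spec.trials):
                rng_params = _trial_rng(master_seed, it, spec.id, j + 1, 1)
                sampled = dict(shared)
                sampled.update(
                    sample_design_params(
                        table, design.design_type, rng_params,
                        lognormal_anchor=lognormal_anchor,
                    )
                )
                added = design.added_arms
                add_costs, add_delays = sample_add_arm(
                    table, len(added), rng_params, lognormal_anchor=lognormal_anchor
                )
                delays = {a.label: float(d) for a, d in zip(added, add_delays)}
                if engine:
                    rng_engine = _trial_rng(master_seed, it, spec.id, j + 1, 2)
                    outcome = simulate_trial(
                        design, rng_engine, arm_delays_months=delays
                    )
                    cb = cost_trial(
                        design, outcome, sampled, add_costs,
                        setup_schedule=setup_schedule,
                    )
                    totals["total_cost"] += cb.total_cost
                    totals["cumulative_duration"] += cb.total_duration
                    totals["sample_size"] += outcome.total_enrolled
                else:
                    from .costing import setup_cost as _sc, setup_time as _st

                    cb = None
                    totals["total_cost"] = np.nan
                    totals["cumulative_duration"] = np.nan
                    totals["sample_size"] = np.nan
                s_cost = cb.setup_cost if cb is not None else _sc(design, sampled)
                s_time = (
                    cb.setup_time if cb is not None
                    else _st(design, sampled, setup_schedule)
                )
                totals["setup_cost"] += s_cost
                totals["setup_time"] += s_time
                trial_rows.append(
                    {
                        "iteration": it,
                        "scenario": spec.id,
                        "trial": j + 1,
                        "design_type": design.design_type,
                        "start_offset": offset,
                        "setup_cost": s_cost,
                        "setup_time": s_time,
                        **(
                            {
                                "total_cost": cb.total_cost,
                                "conduct_cost": cb.conduct_cost,
                                "analysis_cost": cb.analysis_cost,
                                "add_arm_cost": cb.add_arm_cost,
                                "total_duration": cb.total_duration,
                                "sample_size": outcome.total_enrolled,
                            }
                            if cb is not None
                            else {}
                        ),
                    }
                )
            rows.append({"iteration": it, "scenario": spec.id, **totals})
    return MonteCarloResult(
        data=pd.DataFrame(rows),
        trial_data=pd.DataFrame(trial_rows),
        n_iterations=int(n_iter),
        master_seed=int(master_seed),
    )


def matched_relative_difference(
    reference: Sequence[float], comparator: Sequence[float]
) -> np.ndarray:
    """Per-iteration percent difference of comparator versus reference."""
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(comparator, dtype=float)
    if ref.shape != comp.shape:
        raise PairingError(
            f"length mismatch: reference {ref.shape} vs comparator {comp.shape}"
        )
    if np.any(ref == 0.0):
        raise PairingError("zero reference value: relative difference undefined")
    return 100.0 * (comp - ref) / ref


def summarize(values: Sequence[float], metric: str = "") -> ComparisonSummary:
    """Median, IQR (linear-interpolation quartiles), mean and SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return ComparisonSummary(
        metric=metric,
        median_pct=float(med),
        iqr_pct=(float(q1), float(q3)),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def compare_to_reference(
    result: MonteCarloResult,
    reference_id: int = 1,
    metrics: Sequence[str] = METRICS,
) -> pd.DataFrame:
    """Summaries of matched relative differences of every other scenario
    against the reference scenario, one row per (comparator, metric)."""
    scenario_ids = sorted(result.data["scenario"].unique())
    rows = []
    for sid in scenario_ids:
        if sid == reference_id:
            continue
        for metric in metrics:
            ref = result.scenario_values(reference_id, metric)
            comp = result.scenario_values(sid, metric)
            if np.isnan(ref).all() or np.isnan(comp).all():
                continue
            diff = matched_relative_difference(ref, comp)
            s = summarize(diff, metric)
            rows.append(
                {
                    "comparator": sid,
                    "reference": reference_id,
                    "metric": metric,
                    "median_pct": s.median_pct,
                    "q1_pct": s.iqr_pct[0],
                    "q3_pct": s.iqr_pct[1],
                    "mean_pct": s.mean,
                    "sd_pct": s.sd,
                }
            )
    return pd.DataFrame(rows)
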