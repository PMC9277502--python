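"""The three competing trial-portfolio scenarios and the effect-size cases.

All scenarios evaluate the same ten interventions at the same initiation
offsets (modelled on the entry history of a long-running multi-arm prostate
cancer platform):

* **Scenario 1** -- a single platform trial: five initial arms share a common
  control from time zero, five further arms join the platform at their entry
  offsets (after the sampled add-a-group lead time).
* **Scenario 2** -- one 6-group trial (control + the five initial arms)
  starting at offset zero, plus five independent 2-group trials at the later
  entry offsets.
* **Scenario 3** -- ten independent 2-group trials, five at offset zero and
  five at the later offsets.

Effect-size cases set every arm's FFS/OS hazard ratio: the target effect
(HR 0.75) as the base case, twice the target effect (HR 0.5625) as the best
case, and no effect (HR 1.00) as the pessimistic case.  Per-arm published
estimates can override these through the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidConfigError
from .trial_engine import AnalysisSchedule, ArmSpec, TrialDesign

N_INTERVENTIONS = 10

#: Entry offsets (years from portfolio start) for the ten interventions.
#: Arms 1-5 are available at the start; arms 6-10 approximate the public
#: entry history of the motivating platform trial.
DEFAULT_ENTRY_OFFSETS: tuple[float, ...] = (
    0.0, 0.0, 0.0, 0.0, 0.0, 6.0, 8.0, 8.5, 11.0, 12.0
)

DEFAULT_SITES = {"platform": 120, "multigroup": 80, "two_group": 50}

EFFECT_CASES = ("base", "best", "pessimistic")
CASE_HR = {"base": 0.75, "best": 0.5625, "pessimistic": 1.00}


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs shared by the three scenarios.

    ``hr_overrides`` maps ``(case, arm_index)`` (1-based) to an
    ``(hr_ffs, hr_os)`` pair, for plugging in published per-arm estimates.
    """

    entry_offsets: tuple[float, ...] = DEFAULT_ENTRY_OFFSETS
    sites: dict = field(default_factory=lambda: dict(DEFAULT_SITES))
    accrual_per_site_year: float = 500.0 / 120.0
    cap: int = 443
    control_median_ffs: float = 12.0
    control_median_os: float = 24.0
    control_weight_initial: float = 2.0
    schedule: AnalysisSchedule = field(default_factory=AnalysisSchedule)
    add_arm_lead_months: float = 3.0
    accrual_model: str = "deterministic"
    hr_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entry_offsets) != N_INTERVENTIONS:
            raise InvalidConfigError(
                f"scenarios evaluate exactly {N_INTERVENTIONS} interventions; "
                f"got {len(self.entry_offsets)} entry offsets"
            )
        if any(t < 0 for t in self.entry_offsets):
            raise InvalidConfigError("entry offsets must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario: trials with their portfolio start offsets (years)."""

    id: int
    trials: tuple[tuple[TrialDesign, float], ...]
    effect_case: str

    @property
    def n_interventions(self) -> int:
        return sum(len(d.arms) for d, _ in self.trials)

    @property
    def n_controls(self) -> int:
        return len(self.trials)


def effect_case_table(
    case: str, config: ScenarioConfig | None = None
) -> list[tuple[float, float]]:
    """Per-arm (hr_ffs, hr_os) for the ten interventions under a case."""
    if case not in EFFECT_CASES:
        raise InvalidConfigError(f"unknown effect case {case!r}")
    config = config or ScenarioConfig()
    default = CASE_HR[case]
    table = []
    for i in range(1, N_INTERVENTIONS + 1):
        hr_ffs, hr_os = config.hr_overrides.get((case, i), (default, default))
        if hr_ffs <= 0 or hr_os <= 0:
            raise InvalidConfigError(f"arm {i}: hazard ratios must be > 0")
        table.append((float(hr_ffs), float(hr_os)))
    return table


def _arm(i: int, entry: float, hrs: tuple[float, float], cap: int) -> ArmSpec:
    return ArmSpec(
        label=f"arm{i:02d}", entry_time=entry, hr_ffs=hrs[0], hr_os=hrs[1], cap=cap
    )


def build_scenario(
    scenario_id: int,
    effect_case: str = "base",
    config: ScenarioConfig | None = None,
) -> ScenarioSpec:
    """Construct one of the three competing scenarios."""
    if scenario_id not in (1, 2, 3):
        raise InvalidConfigError(f"scenario id must be 1, 2 or 3; got {scenario_id}")
    config = config or ScenarioConfig()
    hrs = effect_case_table(effect_case, config)
    offsets = config.entry_offsets

    def design(design_type: str, arms, control_weight: float) -> TrialDesign:
        return TrialDesign(
            design_type=design_type,
            n_sites=config.sites[design_type],
            arms=tuple(arms),
            accrual_per_site_year=config.accrual_per_site_year,
            control_weight_initial=control_weight,
            control_median_ffs=config.control_median_ffs,
            control_median_os=config.control_median_os,
            schedule=config.schedule,
            add_arm_lead_months=config.add_arm_lead_months,
            accrual_model=config.accrual_model,
        )

    if scenario_id == 1:
        arms = [
            _arm(i + 1, offsets[i], hrs[i], config.cap)
            for i in range(N_INTERVENTIONS)
        ]
        trials = ((design("platform", arms, config.control_weight_initial), 0.0),)
    elif scenario_id == 2:
        first = [_arm(i + 1, 0.0, hrs[i], config.cap) for i in range(5)]
        trials = [(design("multigroup", first, config.control_weight_initial), 0.0)]
        for i in range(5, N_INTERVENTIONS):
            arm = _arm(i + 1, 0.0, hrs[i], config.cap)
            trials.append((design("two_group", [arm], 1.0), offsets[i]))
        trials = tuple(trials)
    else:
        trials = tuple(
            (design("two_group", [_arm(i + 1, 0.0, hrs[i], config.cap)], 1.0),
             offsets[i])
            for i in range(N_INTERVENTIONS)
        )
    return ScenarioSpec(id=scenario_id, trials=trials, effect_case=effect_case)


def default_scenarios(
    effect_case: str = "base",
    config: ScenarioConfig | None = None,
    ids: tuple[int, ...] = (1, 2, 3),
) -> list[ScenarioSpec]:
    config = config or ScenarioConfig()
    return [build_scenario(i, effect_case, config) for i in ids]


def scale_config(config: ScenarioConfig, factor: float) -> ScenarioConfig:
    """Shrink event triggers, caps and entry offsets by ``factor`` (e.g. 10
    for a reduced test scale)."""
    sched = config.schedule
    new_sched = AnalysisSchedule(
        futility_event_triggers=tuple(
            max(3, int(round(t / factor))) for t in sched.futility_event_triggers
        ),
        futility_hr_thresholds=sched.futility_hr_thresholds,
        final_death_trigger=max(4, int(round(sched.final_death_trigger / factor))),
    )
    return replace(
        config,
        cap=max(5, int(round(config.cap / factor))),
        schedule=new_sched,
        entry_offsets=tuple(t / factor for t in config.entry_offsets),
    )
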