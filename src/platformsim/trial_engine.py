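"""Patient-level, event-driven simulator of multi-arm survival trials.

The simulator models trials in the style of a multi-arm, multi-stage design
with a shared control: intervention arms open at staggered calendar times,
patients arrive at a fixed aggregate accrual rate and are randomized among the
control and the currently open arms in proportion to allocation weights, and
each arm is evaluated against the control patients randomized while that arm
was open (its *concurrent controls*).

Analyses are event-driven.  An arm undergoes up to three interim futility
looks, each triggered when its concurrent-control failure-free-survival (FFS)
event count reaches a prespecified trigger; the look is a two-sample log-rank
test on FFS, and the arm stops for futility when the estimated hazard ratio
``exp((O - E) / V)`` is at or above the stage threshold.  Arms surviving all
interims get a final log-rank analysis on overall survival (OS), triggered
when concurrent-control deaths reach the final trigger.  Dropping an arm stops
randomization to it immediately, shrinking the overall sample size.

Latent event times are exponential: the control FFS and OS draws have medians
set by the design, intervention draws scale the hazard by the arm's hazard
ratio, and each patient's FFS time is the minimum of its FFS and OS draws so
failure-free survival always precedes death.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidDesignError, InvalidParameterError, UndefinedTestError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
MONTHS_PER_YEAR = 12.0


# ---------------------------------------------------------------------------
# design types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSpec:
    """One intervention arm.

    ``entry_time`` is in years from the trial's own start; arms entering after
    time zero (platform additions) begin randomizing only after the sampled
    add-a-group lead time has elapsed.  ``hr_ffs``/``hr_os`` are hazard ratios
    versus control for failure-free and overall survival.
    """

    label: str
    entry_time: float = 0.0
    hr_ffs: float = 0.75
    hr_os: float = 0.75
    cap: int = 443
    allocation_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.hr_ffs <= 0 or self.hr_os <= 0:
            raise InvalidDesignError(f"{self.label}: hazard ratios must be > 0")
        if self.cap <= 0:
            raise InvalidDesignError(f"{self.label}: cap must be positive")
        if self.allocation_weight <= 0:
            raise InvalidDesignError(f"{self.label}: allocation weight must be > 0")
        if self.entry_time < 0:
            raise InvalidDesignError(f"{self.label}: entry_time must be >= 0")


@dataclass(frozen=True)
class AnalysisSchedule:
    """Event-count triggers and futility thresholds.

    Interim ``k`` fires when the arm's concurrent-control FFS event count
    reaches ``futility_event_triggers[k]``; the final OS analysis fires at
    ``final_death_trigger`` concurrent-control deaths.
    """

    futility_event_triggers: tuple[int, ...] = (114, 215, 334)
    futility_hr_thresholds: tuple[float, ...] = (1.0, 0.92, 0.89)
    final_death_trigger: int = 400

    def __post_init__(self) -> None:
        trig = self.futility_event_triggers
        thr = self.futility_hr_thresholds
        if len(trig) != len(thr):
            raise InvalidDesignError("triggers and thresholds must have equal length")
        if any(b <= a for a, b in zip(trig, trig[1:])):
            raise InvalidDesignError("futility triggers must be strictly increasing")
        if any(b > a for a, b in zip(thr, thr[1:])):
            raise InvalidDesignError("futility thresholds must be non-increasing")
        if self.final_death_trigger <= 0:
            raise InvalidDesignError("final death trigger must be positive")

    @property
    def n_interims(self) -> int:
        return len(self.futility_event_triggers)


@dataclass(frozen=True)
class TrialDesign:
    """A trial: sites, accrual, arms, control event-time model, schedule."""

    design_type: Literal["two_group", "multigroup", "platform"]
    n_sites: int
    arms: tuple[ArmSpec, ...]
    accrual_per_site_year: float = 500.0 / 120.0
    control_weight_initial: float = 1.0
    control_median_ffs: float = 12.0   # months
    control_median_os: float = 24.0    # months
    schedule: AnalysisSchedule = field(default_factory=AnalysisSchedule)
    add_arm_lead_months: float = 3.0
    accrual_model: Literal["deterministic", "poisson"] = "deterministic"

    def __post_init__(self) -> None:
        if self.design_type not in ("two_group", "multigroup", "platform"):
            raise InvalidDesignError(f"unknown design_type {self.design_type!r}")
        if not self.arms:
            raise InvalidDesignError("design must have at least one arm")
        if self.n_sites <= 0 or self.accrual_per_site_year <= 0:
            raise InvalidDesignError("sites and accrual must be positive")
        if self.control_median_ffs > self.control_median_os:
            raise InvalidDesignError("control median FFS must not exceed median OS")
        if self.control_median_ffs <= 0:
            raise InvalidDesignError("control medians must be positive")
        if self.design_type != "platform" and any(a.entry_time > 0 for a in self.arms):
            raise InvalidDesignError("staggered arm entry requires a platform design")

    @property
    def accrual_per_year(self) -> float:
        return self.n_sites * self.accrual_per_site_year

    @property
    def initial_arms(self) -> tuple[ArmSpec, ...]:
        return tuple(a for a in self.arms if a.entry_time == 0.0)

    @property
    def added_arms(self) -> tuple[ArmSpec, ...]:
        return tuple(a for a in self.arms if a.entry_time > 0.0)


@dataclass
class ArmOutcome:
    label: str
    n_enrolled: int
    stop_reason: str              # futility_stage_<k> or final_analysis
    stop_time: float              # years from trial start
    n_interims_performed: int
    final_performed: bool
    activation_time: float
    window_end: float             # when randomization to the arm ceased
    hr_estimates: list[float] = field(default_factory=list)


@dataclass
class TrialOutcome:
    """Aggregate result of one simulated trial (conduct phase only).

    Times are years from the trial's own start; the setup phase is prepended
    by the costing layer.  ``patient_months_followup`` counts each patient
    from enrollment to the earlier of death and the terminal analysis of its
    arm (trial end for controls).
    """

    start_time: float
    end_time: float
    total_enrolled: int
    control_enrolled: int
    patient_months_followup: float
    site_months: float
    trial_months: float
    arm_outcomes: list[ArmOutcome]
    analyses: list[dict]
    warnings: list[str]

    @property
    def duration_conduct(self) -> float:
        return self.end_time - self.start_time


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def draw_event_times(
    n: int, control_median: float, hr: float, rng: np.random.Generator
) -> np.ndarray:
    """Exponential latent event times (months) with hazard ``ln2/median * hr``.

    The distribution's median is ``control_median / hr``.
    """
    if control_median <= 0 or hr <= 0:
        raise InvalidParameterError("median and hazard ratio must be positive")
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    scale = control_median / (LN2 * hr)
    return rng.exponential(scale, int(n))


def logrank(
    time: Sequence[float], event: Sequence[bool], group: Sequence[bool]
) -> tuple[float, float]:
    """Two-sample log-rank test with hypergeometric variance.

    ``group`` is True for the intervention.  Returns ``(chi_square,
    hr_estimate)`` where ``hr_estimate = exp((O1 - E1) / V)`` from the
    intervention's observed and expected event counts and the hypergeometric
    variance accumulated over distinct event times.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    g = np.asarray(group, dtype=bool)
    if t.size == 0 or not d.any():
        raise UndefinedTestError("log-rank test needs at least one event")

    order = np.argsort(t, kind="stable")
    t, d, g = t[order], d[order], g[order]
    n_total = t.size
    n1_total = int(g.sum())

    # risk sets just before each distinct time
    uniq, first = np.unique(t, return_index=True)
    cum_d = np.concatenate(([0.0], np.cumsum(d)))
    cum_d1 = np.concatenate(([0.0], np.cumsum(d & g)))
    cum_g = np.concatenate(([0.0], np.cumsum(g)))
    last = np.concatenate((first[1:], [n_total]))

    at_risk = n_total - first
    at_risk_1 = n1_total - cum_g[first]
    d_i = cum_d[last] - cum_d[first]
    d1_i = cum_d1[last] - cum_d1[first]

    has_event = d_i > 0
    n_i = at_risk[has_event].astype(float)
    n1_i = at_risk_1[has_event].astype(float)
    dd = d_i[has_event]

    o1 = float(d1_i.sum())
    e1 = float(np.sum(dd * n1_i / n_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = dd * (n1_i / n_i) * (1.0 - n1_i / n_i) * (n_i - dd) / (n_i - 1.0)
    v = float(np.sum(np.where(n_i > 1.0, v_terms, 0.0)))
    if v <= 0.0:
        raise UndefinedTestError("zero log-rank variance (no at-risk overlap)")

    score = o1 - e1
    chi_square = score * score / v
    hr_estimate = math.exp(score / v)
    return chi_square, hr_estimate


def interim_decision(
    hr_estimate: float, stage: int, schedule: AnalysisSchedule
) -> str:
    """``"stop_futility"`` iff the estimated HR is at or above the stage
    threshold (ties stop), else ``"continue"``.  ``stage`` is 1-based."""
    if not 1 <= stage <= schedule.n_interims:
        raise InvalidDesignError(f"stage {stage} outside schedule")
    threshold = schedule.futility_hr_thresholds[stage - 1]
    return "stop_futility" if hr_estimate >= threshold else "continue"


def concurrent_control_count(
    control_enroll: Sequence[float],
    control_event_cal: Sequence[float],
    window_start: float,
    window_end: float,
    t: float,
    ) -> int:
    """Events by calendar time ``t`` among controls enrolled in the window.

    ``window_end`` is the time randomization to the arm ceased (may be
    ``inf`` while the arm is still open).
    """
    enroll = np.asarray(control_enroll, dtype=float)
    ev = np.asarray(control_event_cal, dtype=float)
    sel = (enroll >= window_start) & (enroll <= min(window_end, t))
    return int(np.count_nonzero(ev[sel] <= t))


# ---------------------------------------------------------------------------
# simulation internals
# ---------------------------------------------------------------------------

class _Ledger:
    """Columnar store of one group's patients, append-ordered by enrollment."""

    __slots__ = ("enroll", "ffs", "os", "n")

    def __init__(self) -> None:
        cap = 256
        self.enroll = np.empty(cap)
        self.ffs = np.empty(cap)   # calendar FFS event time
        self.os = np.empty(cap)    # calendar death time
        self.n = 0

    def _grow(self, need: int) -> None:
        cap = self.enroll.size
        if self.n + need <= cap:
            return
        new = max(cap * 2, self.n + need)
        for name in ("enroll", "ffs", "os"):
            arr = getattr(self, name)
            out = np.empty(new)
            out[: self.n] = arr[: self.n]
            setattr(self, name, out)

    def append(self, enroll: np.ndarray, ffs: np.ndarray, os_: np.ndarray) -> None:
        m = enroll.size
        if m == 0:
            return
        self._grow(m)
        self.enroll[self.n : self.n + m] = enroll
        self.ffs[self.n : self.n + m] = ffs
        self.os[self.n : self.n + m] = os_
        self.n += m

    def truncate_after(self, t: float) -> float:
        """Drop patients enrolled after ``t``; return earliest dropped
        enrollment time (inf if none)."""
        k = int(np.searchsorted(self.enroll[: self.n], t, side="right"))
        first_dropped = self.enroll[k] if k < self.n else math.inf
        self.n = k
        return float(first_dropped)

    def view(self, upto: int | None = None):
        m = self.n if upto is None else upto
        return self.enroll[:m], self.ffs[:m], self.os[:m]


class _ArmState:
    __slots__ = (
        "spec", "activation", "ledger", "status", "window_end",
        "stop_reason", "stop_time", "interims_done", "final_done",
        "hr_estimates", "is_initial",
    )

    def __init__(self, spec: ArmSpec, activation: float) -> None:
        self.spec = spec
        self.activation = activation
        self.ledger = _Ledger()
        self.status = "pending" if activation > 0 else "open"
        self.window_end: float | None = None
        self.stop_reason: str | None = None
        self.stop_time: float | None = None
        self.interims_done = 0
        self.final_done = False
        self.hr_estimates: list[float] = []
        self.is_initial = spec.entry_time == 0.0

    @property
    def closed(self) -> bool:
        return self.status in ("stopped", "done")

    @property
    def randomizing(self) -> bool:
        return self.status == "open"


def _window_control_mask(ctrl: _Ledger, arm: _ArmState) -> np.ndarray:
    enroll = ctrl.enroll[: ctrl.n]
    hi = arm.window_end if arm.window_end is not None else math.inf
    return (enroll >= arm.activation) & (enroll <= hi)


def simulate_trial(
    design: TrialDesign,
    rng: np.random.Generator,
    *,
    arm_delays_months: dict[str, float] | None = None,
    chunk: int = 512,
) -> TrialOutcome:
    """Run one trial realization.

    ``arm_delays_months`` maps added-arm labels to sampled add-a-group lead
    times; arms not listed use the design's default lead time.  All
    randomness flows through ``rng``, so a fixed seed reproduces the outcome
    bit-exactly.
    """
    if not design.arms:
        raise InvalidDesignError("design with no arms")
    delays = arm_delays_months or {}
    sched = design.schedule
    rate = design.accrual_per_year
    dt = 1.0 / rate
    eps = dt * 1e-9

    # per-year hazards for the latent exponential draws
    h_ffs0 = MONTHS_PER_YEAR * LN2 / design.control_median_ffs
    h_os0 = MONTHS_PER_YEAR * LN2 / design.control_median_os

    arms: list[_ArmState] = []
    for spec in design.arms:
        act = spec.entry_time
        if spec.entry_time > 0.0:
            act += delays.get(spec.label, design.add_arm_lead_months) / MONTHS_PER_YEAR
        arms.append(_ArmState(spec, act))
    for a in arms:
        a.status = "pending" if a.activation > 0.0 else "open"

    ctrl = _Ledger()
    initial_caps = [a.spec.cap for a in arms if a.is_initial]
    ctrl_phase_cap = (
        int(round(design.control_weight_initial * max(initial_caps)))
        if initial_caps and design.control_weight_initial > 1.0
        else None
    )
    warnings: list[str] = []
    analyses: list[dict] = []
    next_arrival = dt
    t_frontier = 0.0

    # ---------------- helpers ----------------

    def control_weight() -> float:
        if design.control_weight_initial <= 1.0:
            return design.control_weight_initial
        any_initial_open = any(a.is_initial and a.randomizing for a in arms)
        if any_initial_open and (ctrl_phase_cap is None or ctrl.n < ctrl_phase_cap):
            return design.control_weight_initial
        return 1.0

    def pending_analysis(a: _ArmState):
        """(time, kind) of the arm's next analysis, or (None, kind) if its
        trigger is not yet (or never) reached."""
        if a.closed:
            return None, None
        if a.interims_done < sched.n_interims:
            kind = ("interim", a.interims_done + 1)
            trigger = sched.futility_event_triggers[a.interims_done]
            ev = ctrl.ffs[: ctrl.n]
        else:
            kind = ("final", None)
            trigger = sched.final_death_trigger
            ev = ctrl.os[: ctrl.n]
        evt = ev[_window_control_mask(ctrl, a)]
        if evt.size < trigger:
            return None, kind
        t_a = float(np.partition(evt, trigger - 1)[trigger - 1])
        return t_a, kind

    def analysis_dataset(a: _ArmState, t_a: float, endpoint: str):
        enroll_c, ffs_c, os_c = ctrl.view()
        mask = _window_control_mask(ctrl, a) & (enroll_c <= t_a)
        enroll_i, ffs_i, os_i = a.ledger.view()
        imask = enroll_i <= t_a
        ev_c = (ffs_c if endpoint == "ffs" else os_c)[mask]
        ev_i = (ffs_i if endpoint == "ffs" else os_i)[imask]
        en_c = enroll_c[mask]
        en_i = enroll_i[imask]
        time = np.concatenate((np.minimum(ev_c, t_a) - en_c,
                               np.minimum(ev_i, t_a) - en_i))
        event = np.concatenate((ev_c <= t_a, ev_i <= t_a))
        group = np.concatenate((np.zeros(en_c.size, bool), np.ones(en_i.size, bool)))
        return time, event, group

    def do_analysis(a: _ArmState, t_a: float, kind, forced: bool = False) -> bool:
        """Perform the analysis; return True if the arm was still randomizing
        at ``t_a`` and closed (enrollment must then be rolled back)."""
        what, stage = kind
        endpoint = "ffs" if what == "interim" else "os"
        try:
            chi2, hr = logrank(*analysis_dataset(a, t_a, endpoint))
        except UndefinedTestError:
            if not forced:
                raise
            chi2, hr = math.nan, math.nan
        a.hr_estimates.append(hr)
        analyses.append(
            {"arm": a.spec.label, "kind": what, "stage": stage, "time": t_a,
             "chi_square": chi2, "hr_estimate": hr, "forced": forced}
        )
        # a cap recorded after t_a is causally invalid once the arm closes
        # here: randomization truly ceased at t_a
        was_randomizing = a.window_end is None or a.window_end > t_a
        if what == "interim":
            a.interims_done += 1
            if interim_decision(hr, stage, sched) == "stop_futility":
                a.status = "stopped"
                a.stop_reason = f"futility_stage_{stage}"
                a.stop_time = t_a
                if was_randomizing:
                    a.window_end = t_a
                return was_randomizing
            return False
        a.final_done = True
        a.status = "done"
        a.stop_reason = "final_analysis"
        a.stop_time = t_a
        if was_randomizing:
            a.window_end = t_a
        return was_randomizing

    def rollback(t_a: float) -> None:
        nonlocal next_arrival, t_frontier
        dropped = [ctrl.truncate_after(t_a)]
        for a in arms:
            dropped.append(a.ledger.truncate_after(t_a))
        first = min(dropped)
        if math.isfinite(first):
            next_arrival = first
        # recompute arm enrollment statuses from the truncated data
        for a in arms:
            if a.closed:
                continue
            if a.activation > t_a + eps:
                a.status = "pending"
                a.window_end = None
            elif a.ledger.n >= a.spec.cap:
                a.status = "capped"
                a.window_end = float(a.ledger.enroll[a.spec.cap - 1])
            else:
                a.status = "open"
                a.window_end = None
        t_frontier = t_a

    def analysis_sweep(limit_to_frontier: bool) -> None:
        while True:
            best_t, best_arm, best_kind = math.inf, None, None
            for a in arms:
                t_a, kind = pending_analysis(a)
                if t_a is None:
                    continue
                if limit_to_frontier and t_a > t_frontier + eps:
                    continue
                if t_a < best_t:
                    best_t, best_arm, best_kind = t_a, a, kind
            if best_arm is None:
                return
            if do_analysis(best_arm, best_t, best_kind):
                rollback(best_t)

    def enroll_block(times: np.ndarray) -> None:
        nonlocal next_arrival, t_frontier
        open_arms = [a for a in arms if a.randomizing]
        w = np.array([control_weight()] + [a.spec.allocation_weight for a in open_arms])
        cum = np.cumsum(w / w.sum())
        gidx = np.searchsorted(cum, rng.random(times.size), side="right")
        gidx[gidx >= w.size] = w.size - 1  # guard fp edge

        # truncate the block at the first cap-filling or weight-changing event
        cut = times.size - 1
        for j, a in enumerate(open_arms, start=1):
            remaining = a.spec.cap - a.ledger.n
            pos = np.flatnonzero(gidx == j)
            if pos.size >= remaining:
                cut = min(cut, int(pos[remaining - 1]))
        if (
            ctrl_phase_cap is not None
            and control_weight() > 1.0
        ):
            pos = np.flatnonzero(gidx == 0)
            remaining = ctrl_phase_cap - ctrl.n
            if pos.size >= remaining:
                cut = min(cut, int(pos[remaining - 1]))
        m = cut + 1
        times = times[:m]
        gidx = gidx[:m]

        hf = np.array([h_ffs0] + [h_ffs0 * a.spec.hr_ffs for a in open_arms])
        ho = np.array([h_os0] + [h_os0 * a.spec.hr_os for a in open_arms])
        e_ffs = rng.exponential(1.0, m)
        e_os = rng.exponential(1.0, m)
        os_lat = e_os / ho[gidx]
        ffs_lat = np.minimum(e_ffs / hf[gidx], os_lat)
        ffs_cal = times + ffs_lat
        os_cal = times + os_lat

        sel = gidx == 0
        ctrl.append(times[sel], ffs_cal[sel], os_cal[sel])
        for j, a in enumerate(open_arms, start=1):
            sel = gidx == j
            a.ledger.append(times[sel], ffs_cal[sel], os_cal[sel])
            if a.ledger.n >= a.spec.cap:
                a.status = "capped"
                a.window_end = float(a.ledger.enroll[a.spec.cap - 1])
        t_frontier = float(times[-1])
        next_arrival = t_frontier + dt

    # ---------------- main loop ----------------
    # Enroll while any arm is open (or pending activation), processing every
    # analysis whose trigger time has been passed; once enrollment is
    # exhausted, process remaining analyses in time order.  An analysis that
    # closes a still-randomizing arm rolls enrollment back to its time and
    # may reopen enrollment, so the two activities interleave in one loop.

    while True:
        open_arms = [a for a in arms if a.randomizing]
        pending = [a for a in arms if a.status == "pending"]
        if open_arms or pending:
            if not open_arms:
                t0 = min(a.activation for a in pending)
                for a in pending:
                    if a.activation <= t0 + eps:
                        a.status = "open"
                next_arrival = max(next_arrival, t0 + dt)
                t_frontier = max(t_frontier, t0)
                continue
            next_act = min((a.activation for a in pending), default=math.inf)
            if next_act <= next_arrival + eps:
                for a in pending:
                    if a.activation <= next_act + eps:
                        a.status = "open"
                continue
            if math.isfinite(next_act):
                k = int(math.ceil((next_act - next_arrival) / dt - 1e-9))
                k = max(1, min(chunk, k))
            else:
                k = chunk
            if design.accrual_model == "poisson":
                gaps = rng.exponential(dt, k)
                times = next_arrival + np.concatenate(([0.0], np.cumsum(gaps[:-1])))
                if math.isfinite(next_act):
                    times = times[times < next_act - eps]
                if times.size == 0:
                    for a in pending:
                        if a.activation <= next_act + eps:
                            a.status = "open"
                    continue
            else:
                times = next_arrival + dt * np.arange(k)
            enroll_block(times)
            analysis_sweep(limit_to_frontier=True)
            continue

        # no enrollment possible: next pending analysis, in time order
        best_t, best_arm, best_kind = math.inf, None, None
        unreachable: list[_ArmState] = []
        for a in arms:
            if a.closed:
                continue
            t_a, kind = pending_analysis(a)
            if t_a is None:
                unreachable.append(a)
            elif t_a < best_t:
                best_t, best_arm, best_kind = t_a, a, kind
        if best_arm is not None:
            if do_analysis(best_arm, best_t, best_kind):
                rollback(best_t)
            continue
        if not unreachable:
            break
        # Windows are final and the trigger count can never be reached:
        # force the final analysis at the last event time that could still
        # have contributed (the last concurrent-control death).
        for a in unreachable:
            mask = _window_control_mask(ctrl, a)
            ev = ctrl.os[: ctrl.n][mask]
            t_last = float(ev.max()) if ev.size else 0.0
            if a.ledger.n and not ev.size:
                t_last = float(a.ledger.os[: a.ledger.n].max())
            t_last = max(t_last, a.window_end or 0.0)
            msg = (
                f"arm {a.spec.label}: event trigger unreachable with "
                f"{int(mask.sum())} concurrent controls; forcing final "
                f"analysis at t={t_last:.3f}y"
            )
            warnings.append(msg)
            logger.warning(msg)
            do_analysis(a, t_last, ("final", None), forced=True)

    # ---------------- assemble outcome ----------------

    end_time = max((a.stop_time for a in arms if a.stop_time is not None), default=0.0)
    arm_outcomes = []
    patient_months = 0.0
    total_enrolled = ctrl.n
    for a in arms:
        stop = a.stop_time if a.stop_time is not None else end_time
        enroll, _, os_cal = a.ledger.view()
        patient_months += float(np.sum(np.minimum(os_cal, stop) - enroll)) * MONTHS_PER_YEAR
        total_enrolled += a.ledger.n
        arm_outcomes.append(
            ArmOutcome(
                label=a.spec.label,
                n_enrolled=a.ledger.n,
                stop_reason=a.stop_reason or "final_analysis",
                stop_time=stop,
                n_interims_performed=a.interims_done,
                final_performed=a.final_done,
                activation_time=a.activation,
                window_end=a.window_end if a.window_end is not None else stop,
                hr_estimates=a.hr_estimates,
            )
        )
    enroll_c, _, os_c = ctrl.view()
    patient_months += float(np.sum(np.minimum(os_c, end_time) - enroll_c)) * MONTHS_PER_YEAR

    return TrialOutcome(
        start_time=0.0,
        end_time=end_time,
        total_enrolled=int(total_enrolled),
        control_enrolled=int(ctrl.n),
        patient_months_followup=patient_months,
        site_months=design.n_sites * end_time * MONTHS_PER_YEAR,
        trial_months=end_time * MONTHS_PER_YEAR,
        arm_outcomes=arm_outcomes,
        analyses=analyses,
        warnings=warnings,
    )
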