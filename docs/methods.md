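# Methods

`platformsim` estimates the cost and time required to evaluate ten medical
interventions under three competing trial-portfolio designs: a single
platform trial with a shared control (scenario 1), one 6-group trial followed
by five independent 2-group trials (scenario 2), and ten independent 2-group
trials (scenario 3).  Every quantity is produced by Monte-Carlo simulation:
an event-driven patient-level trial simulator generates each trial's
duration, enrollment and exposure tallies, a top-down costing model converts
those tallies into US-dollar (2021) costs using expert-elicited unit costs,
and scenarios are compared by matched-iteration relative differences.

## Trial simulation model

**Survival model.**  Latent event times are exponential.  Control
overall-survival (OS) times have a configurable median (default 24 months);
control failure-free-survival (FFS) draws have their own median (default 12
months), and each patient's FFS time is the minimum of the FFS and OS draws,
which guarantees that failure precedes or coincides with death.  An
intervention arm multiplies both hazards by its hazard ratios (HR).  The
default medians are deliberately simple stand-ins: the exponential law is the
minimal model consistent with hazard-ratio effect specifications, and a
2-year control OS median puts the platform trial's simulated length on the
right decade-scale.  Real advanced-cancer survival is not exponential and
real event registration lags clinic visits; neither feature is modelled.

**Accrual and allocation.**  Patients arrive at a deterministic aggregate
rate of `n_sites x accrual_per_site_year` (default 500/120 per site-year, so
a 120-site platform recruits 500 patients per year, an 80-site multigroup
trial 333 per year, a 50-site 2-group trial 208 per year).  Deterministic
(equally spaced) arrivals are the default because the design fixes recruitment
rates; a Poisson arrival process is available via `accrual_model="poisson"`.
Each arrival is randomized among the control and the currently open arms with
probability proportional to allocation weights.  Designs with five initial
arms use 2:1:1:1:1:1 (control weight 2) until either every initial arm has
closed or the control has reached twice the 443-patient arm cap (886),
after which the control weight drops to 1; 2-group trials and later platform
arms randomize 1:1.  Arms stop receiving patients at their cap (443), at a
futility stop, or at their final analysis; enrollment pauses entirely when no
arm is open.  Platform arms entering after time zero begin randomizing after
a sampled add-a-group lead time (elicited mean 3.00 months, SD 1.73).

**Event-driven analyses.**  Each arm is compared against its *concurrent
controls* -- control patients randomized while that arm was open.  Up to
three interim futility looks occur at 114, 215 and 334 concurrent-control
FFS events; each look is a two-sample log-rank test on FFS, with the HR
estimated as `exp((O - E)/V)` from the log-rank table (a proportional-hazards
fit would be near-identical and slower).  The arm stops for futility when the
estimate is at or above the stage threshold (1.0, 0.92, 0.89); a tie stops,
reading the thresholds as inclusive futility bounds.  Arms surviving all
interims receive a final log-rank analysis on OS at 400 concurrent-control
deaths.  There are no efficacy stops.  Because randomization is multinomial,
an arm's concurrent-control count is random with mean about 443 in the 1:1
phases, so a window can end with fewer than 400 controls, making the final
trigger unreachable; the simulator then forces the final analysis at the
last concurrent-control death and logs a warning.  This is a known
self-inconsistency of the specified design (a 400-death trigger against a
~443-patient control) and materially lengthens the affected realizations;
see "Known limitations".

The simulator is exact about causality: analyses are processed in calendar
order, and an analysis that closes a still-randomizing arm rolls enrollment
back to the analysis time so that no patient is ever allocated under weights
that the decision would have changed.

## Top-down costing model

Each trial realization is costed from one Monte-Carlo draw of every elicited
parameter:

* setup cost = protocol development + trial approvals + database development
  + per-site setup x sites;
* setup time = protocol development, then approvals and database development
  in parallel (`setup_schedule="protocol_then_parallel"`, the default; a
  fully `sequential` schedule is available).  The parallel tail reproduces
  the elicited single-trial setup-time scale better than a fully sequential
  chain;
* conduct cost = recruitment/patient x enrolled + follow-up/patient-month x
  patient-months + site management/site-month x site-months + database
  management/month x trial-months.  Patient-months run from enrollment to the
  earlier of death and the terminal analysis of the patient's arm (trial end
  for controls); all sites are counted as active from trial start to the last
  analysis;
* analysis cost = per intervention arm, interims performed x interim cost,
  plus the final-analysis cost when the final was run (analyses are pairwise
  against control, so the control is not charged separately);
* arm-addition cost (platform only) = one sampled add-a-group cost per added
  arm.

Totals conserve exactly (total = sum of the four components); no discounting
is applied.  A trial's duration is its setup time plus the conduct span, and
a scenario's cumulative cost/duration is the sum over its trials even where
trials overlap in calendar time.

## Elicited parameters and distributions

Costs vary lognormally and times normally, with times constrained positive
by rejection resampling (clamping would put a point mass at zero).  The
lognormal is parameterized by a method-of-moments inversion:
`sigma^2 = ln(1 + (sd/mean)^2)`.  The *anchoring* of the elicited mean is
genuinely ambiguous and exposed as `lognormal_anchor`:

* `"mean"` -- location `ln(mean) - sigma^2/2`, so the arithmetic mean of the
  draws equals the elicited mean;
* `"median"` (default) -- location `ln(mean)`, placing the elicited value at
  the median, so heavy-tailed cost draws have an arithmetic mean above it.

The median anchor is the default because it reproduces the single-trial
setup-cost scale and the cumulative setup-cost comparisons this model is
calibrated against; the mean anchor lands substantially lower on both.
Nothing else in the pipeline depends on the choice.

## Monte-Carlo comparison

Scenarios are compared per iteration: each iteration simulates every trial of
every scenario, sums per-scenario totals, and records the matched relative
difference `100 x (comparator - reference)/reference`, summarized by median
and IQR (linear-interpolation quartiles).  Seeding is hierarchical
(master seed -> iteration -> scenario -> trial -> stream), so iterations are
matched across scenarios, results are bit-reproducible, and adding a scenario
to a run never perturbs another's draws.  Unit costs elicited as shared
across designs (site setup/management, recruitment, follow-up, database
management, analysis costs) are drawn once per iteration and reused by every
trial in every scenario -- common random numbers that sharpen the paired
comparison.  Design-specific setup quantities are drawn independently per
trial.

Default run sizes: 5000 iterations for headline comparisons (the acceptance
script); the test suite uses 1000 iterations for the full-scale headline
check and the `small` fixture scale (triggers, caps and entry offsets shrunk
~10x) elsewhere, which keeps the default suite to a couple of minutes on one
CPU while leaving median estimates well inside the tolerance bands used.

## Synthetic survey data

The survey generator draws respondent answers around a known ground truth
using the analysis-side families: mean-anchored lognormal for costs and
*untruncated* normal for times, because the elicitation noise model is
normal and the positivity constraint belongs to the cost-model sampling
stage; truncating responses would bias recovered means upward for high-CV
time quantities.  Sample moments of generated responses are therefore
unbiased for the truth, and fitting them back with `estimate_moments`
(sample mean, SD with denominator n-1) recovers the elicited table within
sampling error.  Expert disagreement structure, anchoring bias and
non-response are not modelled: the pipeline consumes only (mean, SD).

## Numerical choices

* Calendar time is kept in years; months convert at exactly 12 months/year.
* Event-trigger times are order statistics of concurrent-control event
  times, computed exactly (no grid).
* Log-rank ties are handled by grouping distinct event times with the
  hypergeometric variance correction `(n - d)/(n - 1)`.
* Zero log-rank variance (no at-risk overlap) raises an error rather than
  returning 0/0.
* A degenerate elicited SD of 0 yields a point mass at the mean.
* Quartiles use linear interpolation (numpy's default).

## Known limitations

* The baseline survival law, the exact platform entry dates, and the
  original study's lognormal anchoring are not derivable from its main text;
  the defaults here are documented stand-ins, and the cumulative-duration
  and total-cost comparisons for scenario 2 in particular are sensitive to
  the baseline event-rate assumption (faster control event accrual brings
  the 6-group trial's event-triggered finals earlier, shrinking its share of
  scenario 2's burden).
* The 400-death final trigger against a ~443-patient concurrent control is
  self-inconsistent under multinomial randomization (see above); the forced
  final at the last control death is a conservative fallback that markedly
  lengthens the affected realizations.
* Site counts are fixed per design; there is no site-level heterogeneity,
  no patient dropout, no competition for a finite patient pool, and no
  efficacy stopping.
* Costs are nominal 2021 US dollars with no discounting, overheads or
  staffing decomposition.
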