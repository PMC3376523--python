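# Methods

## Scope and model

The package evaluates two delivery modes of the same short course — a
face-to-face workshop and a web-delivered equivalent — from three
stakeholder perspectives sharing one cost model. The analysis is
single-period: no discounting, inflation adjustment, amortization of
the web platform across repeated cohorts, or course-development (sunk)
costs. Fees are treated as the provider's savings, wages as the
opportunity cost of time, and stated willingness to pay (WTP) as the
monetary proxy for participant benefit.

### Cost model

Costs are itemized as per-class **fixed** (venue, presentation
equipment, the facilitator contract, ICT support, administration) or
per-participant **variable** (catering, stationery, DVDs). Money is
`Decimal` AUD throughout — never binary floating point — carried exactly
and rounded to cents half-up only at operation boundaries; printed
tables render with two decimals.

The wage policy has three parameters: the base rate (default $45/h, an
early-career allied-health award rate), the employer on-cost multiplier
(default 1.17, i.e. 17% on-costs, applied only in health-service
perspectives), and the penalty loading (default 1.5, time-and-a-half,
applied when participation occupies leisure time/weekends).

Hours are perspective-specific and deliberately configured as two
independent sets, because the two analyses use different bases:

* CEA in-work hours: 8 (face-to-face) and 9.6 (web = 8 + 1.6 extra
  hours observed for web learners);
* CBA participant totals: 12 and 14.4 (total time on task, implied by
  the participant time costs of $540 and $648 at $45/h).

The web totals imply 2.4 extra hours while the contact figure is 1.6;
the two are *not* reconciled — they are separate defaults a user can
change, since self-reported total time and contact time measure
different things.

Participant out-of-pocket constants: broadband download $20, satellite
download $25 (a substitute item, back-derived from the $5 gap between
the satellite and primary web totals), car transport $20. All
configurable.

### Break-even (provider)

Fixed costs replicate per class: total fixed cost at `q` enrollments is
`FC·⌈q/capacity⌉` (zero classes at zero enrollments), so the net
position `q·(S − VC) − FC·⌈q/capacity⌉` is a sawtooth and profitability
forms segments of the integer enrollment domain. Two solver conventions
are exposed because published break-even tables mix them:

* **integer scan** (default): exhaustive scan of `q = 1..max`
  (default 60), maximal runs of non-negative net; exact. A net of
  exactly zero counts as breaking even (e.g. face-to-face at an $800
  fee: 3060/765 = 4 exactly).
* **rounded ratio** (legacy): `FC/(S − VC)` rounded half-up, ignoring
  capacity steps. This reproduces headline single numbers quoted from
  the ratio (e.g. 14 for the face-to-face primary, where the exact scan
  gives 15). Half-up is a determinism choice; no default scenario lands
  on exactly .5.

Enrollments are integers; no fractional/continuous break-even is
offered. One-way sweeps cover facilitator hours, facilitator rate
(which rebuild FC as `hours × rate + other fixed`), class capacity,
fee, and a joint FC+VC scale factor.

### Cost-effectiveness (health service)

`QASE = completers × mean grade` (grade a fraction in [0, 1];
non-completers score zero). Scenario cost assembly:

* enrollment fee × enrolled, if the service pays the fee;
* participant wages with on-costs, whenever training displaces paid
  work — **both** the working-hours and unpaid-study-leave timings (the
  published cost rows are only reproducible under this attribution, so
  it is taken as given rather than re-derived);
* an equal backfill wage term when replacement staff are engaged —
  coherent only for working-hours timing (validated).

Transport and downloads are participant-borne and excluded. The ICER is
`ΔCost/ΔQASE` with dominance handling: equal costs report ratio 0 and
prefer the higher-QASE arm; equal QASE at unequal cost reports the
cheaper arm as dominant with no finite ratio. The sensitivity table
appends two variants derived from the first (primary) scenario: equal
attrition (web completers forced to the face-to-face count) and an
alternative face-to-face fee inflated by a configurable factor (default
2.1, giving $525 from $250; the factor is a configuration constant, not
derived). Exact-cent values are asserted only for the face-to-face arm;
the web arm's 9.6 in-work hours reproduce published service costs to
their own rounding ($10,108.80 vs a printed 10,108).

### Cost-benefit (participant)

Expenses are assembled from components (downloads or transport, fee,
time at the base wage without on-costs, penalty-loaded for leisure
timing); sensitivity rows always recompute from scaled components,
never by scaling totals — the published sensitivity table contains
internally inconsistent cells that only a component-wise recomputation
avoids. Benefit is the per-context mean WTP; the context feeding the
net-benefit comparison is configurable and defaults to context 3
(professional-development recognition), since no single context is
canonically designated. Missing WTP fields are dropped per context, not
imputed. Spearman validity uses average-rank tie handling; the p-value
is asymptotic by default for n > 8 and an exact pairing-permutation
enumeration for small samples (`p_method="exact"`, capped at n ≤ 10
where 10! pairings are still enumerable; the automatic switch is at
n ≤ 8 to keep default calls fast).

## Synthetic cohorts

The generator emulates the trial that motivates the defaults: arms of
68 (face-to-face) and 67 (web) enrollees; completion probabilities
49/68 and 44/67; grade means 81.6 and 83.2 with SDs 9.5 and 9.9;
per-context WTP means/SDs taken from the published summaries; target
WTP–satisfaction Spearman correlations 0.46/0.43/0.53/0.45; per-field
WTP missingness 0.42 and 0.24 (matching the published respondent counts
among completers). Survey fields exist only for completers.

Modeling choices:

* **Grades** are normal draws *censored* to [0, 100] (values beyond a
  bound score the bound), giving an atom at full marks as bounded exam
  scores have. At these parameters the censoring bias on the mean is
  below 0.2 percentage points, whereas discarding-and-redrawing
  out-of-range values would bias the mean down by 0.6–1.0 points and
  defeat parameter recovery.
* **WTP** is log-normal, moment-matched to the stated mean/SD (SDs
  exceed means in some cells, ruling out a normal model for a
  non-negative quantity). A zero SD degenerates to a constant; a
  non-positive mean with positive SD is an impossible moment match and
  raises.
* **Satisfaction** is a shared latent standard normal discretized into
  equiprobable ordinal levels (default 5). Each context's WTP loads on
  the latent through a Gaussian copula; the loading is calibrated
  analytically — the population Spearman between a continuous margin
  and the discretized latent is computed from a bivariate-normal CDF
  integral and inverted by Brent root finding — so the *realized* rank
  correlation hits the target despite discretization ties. The
  calibration is cached per (target, levels) pair.
* No behavioral attrition model (completion is independent Bernoulli)
  and no per-participant time draws: hours enter the analyses as
  scenario constants because no dispersion for time on task is
  published.

What passing tests on synthetic cohorts show: the estimators recover
the generating parameters and the pipeline is closed end to end. What
they do not show: the generator cannot validate assumptions real trial
data might violate — correlated attrition, non-log-normal WTP tails,
satisfaction scale-use heterogeneity.

## Numerical and testing choices

* Parameter-recovery assertions use n = 20,000 per arm for single-run
  checks, placing the tolerance bands (completion ±0.03, grade ±0.5 pp,
  WTP means ±5%) at three or more standard errors; the Spearman check
  follows its stated condition of n = 2,000 (±0.05). A 100-seed sweep
  at n = 2,000 per arm asserts per-seed pipeline closure (finite,
  schema-valid statistics) and Monte-Carlo unbiasedness of the averaged
  statistics at the same tolerances.
* The segment scanner is verified against an independent naive
  rational-arithmetic re-scan (class-by-class fill, `Fraction` cost
  accounting) on randomized scenarios, alongside monotonicity
  properties (raising the fee never shrinks a profitability segment;
  raising FC or VC never grows one).
* The pipeline writes no timestamps; a fixed configuration regenerates
  byte-identical output, and changing the seed alters only
  cohort-derived tables, never the break-even tables.
* Degenerate inputs are mapped to markers, not exceptions: empty WTP
  cells, single-observation SDs, zero rank variance in the validity
  check, and non-break-even scenarios all return explicit empty/None
  results.

## Known limitations

* The two published hour bases (1.6 vs 2.4 extra web hours) are kept as
  independent defaults; results are sensitive to which a user adopts.
* The payer attribution under unpaid study leave follows the published
  cost rows rather than first principles; users disagreeing can zero
  the wage term via the leisure timing.
* The alternative-fee inflation factor (2.1) and the WTP benefit
  context (3) are conventions, not estimates.
* Class capacity is assumed binding and identical across modes by
  default; web capacity is arguably softer in practice.
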