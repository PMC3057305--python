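# Methods

`trialcea` re-implements, as a tested pipeline, the economic evaluation of
a three-arm randomized trial for adults with depressive symptoms:
internet-based cognitive behavioural therapy (CBT, 8 weekly lessons),
internet-based problem-solving therapy (PST, 5 weekly lessons) and a
waiting list (WL), with outcomes at weeks 0, 5, 8 and 12. The original
participant-level records were never deposited; the package therefore
couples the analysis code to a synthetic-trial generator that reproduces
the statistical structure the analysis assumes, and separately verifies
every piece of arithmetic the trial report prints from its own summary
numbers.

## Outcomes

**QALYs.** EQ-5D utilities (Dutch tariff, taken as given — the package
does not map dimension profiles to utilities) are measured at weeks 0, 5,
8, 12. QALYs are computed per interval and summed, so faster early
response earns more QALYs than the same endpoint reached late:

    QALY_i = (u_start + u_end)/2 × weeks_i / 52.18        (trapezoid)

with interval widths 5, 3 and 4 weeks and a year of 365.25/7 ≈ 52.18
weeks. The interval rule is configurable (`qaly_rule =
trapezoid | right_endpoint`); the trapezoid is the standard
area-under-the-curve convention and is symmetric in the endpoints. With
utilities in [0, 1] each interval QALY is bounded by its width in years
and the total is exactly the sum of the three parts.

**Reliable and clinically significant change.** Depression severity is the
CES-D (0–60; 16 and higher denotes clinically significant symptoms, which
is also the trial's inclusion rule). Following Jacobson and Truax, the
reliable change index is

    RCI = (pre − post) / (SD_baseline × √(2(1 − r)))

with SD_baseline = 7.5. The test–retest reliability `r` is not reported
for this trial; the default 0.87 is in the range commonly reported for the
CES-D and is an explicit assumption, configurable everywhere it enters.
At the defaults the minimum reliable improvement is 1.96 × 3.824 ≈ 7.5
score points. A participant is *recovered* when the week-12 score is
strictly below 16 (consistent with "16 and higher" defining caseness) and
shows *clinically significant change* only when both reliably improved and
recovered. Supporting tests are the Pearson chi-square without continuity
correction (the change table is 3×2, where Yates' correction is
undefined) and classical one-way ANOVA. The ANOVA reports the textbook
degrees of freedom (k−1, n−k) and echoes the total n; trial reports
sometimes subscript F with n−1 instead, and the implementation does not
force agreement with that convention.

## Costs

Societal perspective, Euros at 2007 prices, no discounting (12-week
horizon). Three categories, summed exactly into the total:

* **Direct medical** — per-arm intervention cost (€501 CBT, €338 PST, €0
  WL, added once to the 12-week aggregate), health-service contacts at
  standard unit cost prices, and medication priced per standard daily
  dose per month (the published price list is not printed; the default
  €11/month is calibrated so mean medication costs land at the reported
  €15–18 per 12 weeks given ~54% medication use).
* **Direct nonmedical** — per visit: `km × 0.17 + patient_hours × 8.83 +
  2.64 × 1{km > 0}`. The one-parking-hour surcharge for any travelling
  visit is reverse-engineered: it reproduces all 13 printed per-visit
  nonmedical values within €0.05 (max error €0.02), and visits without
  travel match exactly. It is a modelling inference, not stated in the
  source text.
* **Indirect** — friction-cost productivity losses:
  `work_loss_days × day_rate + days_worked_ill × inefficiency × day_rate +
  domestic_hours × 8.83`. The original analysis used age- and
  gender-specific friction costs from the national costing manual, which
  are not printed; the package uses a flat configurable day rate
  (default €115/day). Over 12 weeks friction and human-capital costing
  coincide.

Money is handled in exact cents internally; rounding to whole Euros
happens only in report output. One published inconsistency is kept
visible rather than patched: the indirect-cost saving of CBT versus WL is
printed as €201 while the printed means subtract to €199 (1900 − 1701);
the PST figure (1900 − 1642 = 258) is exact. The package reproduces the
subtraction exactly and treats the printed value with a ±€2 tolerance.

## Missing data

Follow-up attrition is severe (the trial lost ~44% of cost data by week
12). The main analysis imputes by **expectation–maximization** under a
multivariate normal over the analysis variables: baseline CES-D and
utility (always observed), the six follow-up outcome scores, and the nine
per-period cost-category totals. Choices:

* *Within-arm imputation.* A single joint normal without arm terms would
  pull treated participants toward the pooled mean and attenuate arm
  contrasts; fitting each arm separately preserves them.
* *Period cost totals, not service counts.* The source text says missing
  cost data were EM-imputed without saying at which level; imputing the
  nine period×category totals keeps the model low-dimensional and the
  category additivity exact.
* *Convergence* when the relative change in the observed-data
  log-likelihood falls below 1e-6, at most 500 iterations (neither is
  stated in the source; on default-size cohorts EM converges in ~10
  iterations). The log-likelihood trace is returned and asserted
  non-decreasing in the tests. Estimability requires every column pair
  jointly observed at least twice; violations raise an error naming the
  pair.
* *Clipping.* Imputed cells are clipped to admissible ranges (CES-D
  [0, 60], utility [−1, 1], costs ≥ 0) because a linear model is unaware
  of such bounds. Observed cells are never modified.

The **sensitivity analysis** imputes each missing cell from an ordinary
least-squares fit on complete cases, regressing on whichever of the other
columns are observed in that row (one fit per missing pattern, falling
back to the column mean with a warning when complete cases are scarcer
than predictors plus two). It is deterministic by default; stochastic
residual draws can be enabled and are then governed by the seed.

A known consequence of *both* conditional-mean methods: imputed values
carry no residual variance, so threshold-based classifications (recovered,
reliably improved) computed on imputed CES-D scores are biased toward the
null — an imputed participant sitting at the conditional mean rarely
crosses both thresholds. This attenuation is visible in the synthetic
runs as lower post-imputation improvement percentages than the
complete-data cohort produces, and it would equally have affected the
original single-imputation analysis.

## Economic evaluation

For each contrast (CBT−WL, PST−WL, PST−CBT) and each effect measure
(total QALYs; the 0/1 clinically-significant-change indicator):

* **ICER** = (C₁−C₀)/(E₁−E₀) from arm means; a numerically zero effect
  difference flags the ratio undefined rather than raising, with ΔC and
  ΔE always reported separately.
* **Bootstrap**: B = 5000 replicates; each resamples participants with
  replacement *within* each arm (preserving randomization arms), keeping
  every participant's (cost, effect) pair intact, and records the pair of
  mean differences. Reproducible for a given seed: the same seed yields
  the same resample indices (NumPy PCG64 `default_rng`).
* **Summary**: median and 2.5th/97.5th percentiles of the replicate
  ratios, linear-interpolation percentile rule (the median of ratios
  1..100 is 50.5). Means of ratio distributions are unstable and are
  deliberately not reported, though all draws are stored so any summary
  can be recomputed. Replicates with ΔE exactly 0 (possible for the
  binary effect) are excluded from the ratio percentiles and counted
  separately.
* **CE plane**: quadrant shares from the signs of (ΔE, ΔC); boundary
  rule: ΔE = 0 is counted on the west side and reported separately,
  ΔC = 0 counts as "not cheaper", so the four shares always sum to 1.
* **CEAC** via net monetary benefit: acceptability at ceiling λ is the
  fraction of replicates with λ·ΔE − ΔC > 0, ties not acceptable. Unlike
  an ICER-threshold rule, NMB orders draws correctly in all four
  quadrants; CEAC(0) = P(ΔC < 0) and CEAC(λ→∞) = P(ΔE > 0), both
  asserted in tests. Default λ grid: 0 to 50,000 € in steps of 500.

## The synthetic cohort generator

The generator defines the conditions everything is tested under. It
emulates: exact arm sizes 88/88/87; baseline CES-D as a truncated normal
whose *truncated* moments equal the reported 31.7/7.5 (the report's
moments describe the included population, so the underlying parameters
are solved numerically rather than plugging 31.7/7.5 into the truncated
law, which would shrink the SD by ~5%); baseline utility with mean
0.61/SD 0.22, clipped to [0, 1] and negatively coupled to severity;
follow-up trajectories with regression to the mean (coefficient 0.7),
AR(1)-correlated residuals across waves (ρ = 0.6 — the source gives no
correlation structure, so this is a free knob, not a claim), and shared
residuals linking utility to depression changes; zero-inflated service-use
counts with occurrence probabilities matching the published baseline
service-use table; log-normal productivity losses; and monotone MAR
dropout whose per-wave marginal (default 20/32/44%) is solved exactly and
whose individual risk rises with baseline severity — matching the
ignorability assumption EM relies on, so imputation-recovery tests are
fair.

Arm effects (additive CES-D and utility shifts at weeks 5/8/12, and a
follow-up care-consumption multiplier) are calibrated once so that
large-sample complete-data arm summaries land near the published ones:
improvement percentages ≈ 30/29/14 vs reported 28.4/26.1/14.9; mean
12-week QALYs ≈ 0.150/0.152/0.145 vs 0.16/0.16/0.15; mean total costs
≈ 2533/2407/2300 € vs 2814/2705/2558 € with the same ordering and
SD > mean right-skew in indirect costs.

What the generator does **not** emulate: the intervention content and any
dose–response structure; non-ignorable (MNAR) dropout; the exact joint
distribution of service-use counts (services are drawn independently);
seasonal or calendar effects. Consequently, passing tests show the
*pipeline* is correct and recovers known synthetic truth under MAR — they
cannot certify the original trial's bootstrap medians or quadrant
probabilities, which depend on the undeposited raw data and are
explicitly out of reach.

A second, deliberately minimal generator (`synthetic_arm_data`: gamma
costs with configured mean, Bernoulli or normal effects) provides exact
known truth for parameter-recovery checks of the bootstrap chain, e.g.
incremental cost €147 with incremental improvement probability 0.112
(the published PST−WL deltas), whose median ICER must bracket
147/0.112 ≈ €1313 across seeds within Monte-Carlo error.

## Reproducibility and problem sizes

One master seed drives everything: sub-seeds for generation, dropout,
bootstrap and summary stages are derived through NumPy's `SeedSequence`,
and identical (config, seed) produces byte-identical output files. The
default analyses use the trial's own sizes (263 participants, B = 5000
bootstrap replicates); the test suite uses the same sizes where a check
depends on them (e.g. 20 seeds × B = 5000 for recovery) and smaller
cohorts elsewhere, and the whole suite runs in well under a minute.

## Known limitations

* Single imputation (EM or regression) understates post-imputation
  uncertainty relative to multiple imputation with pooling, and biases
  threshold classifications toward the null (above); this mirrors the
  original analysis rather than improving on it.
* The friction day rate is flat, not age/gender-specific.
* Utilities are accepted as given; negative tariff values are admissible
  on input but the generator produces [0, 1].
* The CES-D reliability 0.87 is an assumption; the RCSC flags move with
  it, and the package exposes it as a first-class parameter.
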