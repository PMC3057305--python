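# trialcea

Trial-based cost-utility and cost-effectiveness analysis for a three-arm
randomized trial of internet-based treatments for depression — with a
seeded synthetic-trial generator standing in for the undeposited
participant-level data.

## The problem

A Dutch randomized trial compared internet-based cognitive behavioural
therapy (CBT, n = 88), internet-based problem-solving therapy (PST,
n = 88) and a waiting list (WL, n = 87) for adults with clinically
significant depressive symptoms (CES-D ≥ 16), with follow-ups at 5, 8 and
12 weeks. Beyond clinical effect, the economic question is what each
treatment buys society per Euro: health-service use, patient travel and
time, and lost productivity all carry costs, while benefits are measured
both generically (quality-adjusted life-years from EQ-5D utilities) and
clinically (reliable and clinically significant change on the CES-D).

This package is for health-economics and biostatistics practitioners who
want that style of trial-based evaluation as reusable, tested code: the
costing rules, the Jacobson–Truax classification, EM imputation of
missing follow-up data, and the bootstrap machinery for incremental
cost-effectiveness ratios, cost-effectiveness planes and acceptability
curves.

## The core quantities

For a contrast of arms 1 (intervention) and 0 (comparator),

    ICER = (C₁ − C₀) / (E₁ − E₀)

where C is the mean 12-week societal cost per participant and E the mean
effect — total QALYs (cost-utility) or the probability of clinically
significant change (cost-effectiveness). QALYs are the area under the
utility trajectory, per interval: QALY_i = ((u_start + u_end)/2) ×
weeks_i / 52.18. Clinically significant change requires both a reliable
change index (pre − post)/(SD√(2(1−r))) above 1.96 and a week-12 score
below the cutoff of 16.

Uncertainty is nonparametric: participants are resampled with replacement
within each arm (B = 5000), each replicate yields a (ΔC, ΔE) pair, and
the ICER is summarised by the median and the 2.5th/97.5th percentiles of
the replicate ratios. The same draws give the CE-plane quadrant
probabilities and the acceptability curve P(λ·ΔE − ΔC > 0) over
willingness-to-pay ceilings λ.

The raw trial data were never deposited, so a synthetic cohort generator
(`trialcea.synthetic`) reproduces the structure the analysis assumes —
truncated-normal baseline severity, right-skewed costs, treatment
effects calibrated to the published arm summaries, and monotone
missing-at-random dropout reaching ~44% lost cost data at week 12. See
`docs/methods.md` for every assumption and default.

## Worked example

```python
from trialcea import pipeline

cfg = pipeline.RunConfig(synthetic={}, B=5000, seed=1,
                         output_dir="results/demo")
res = pipeline.run_analysis(cfg)
print(res.outcome_summary.round(3)[["n", "qaly_mean", "pct_improved"]])
icer = res.contrasts[("CBT-WL", "qaly")].icer
print(f"CBT-WL: dC={icer.dC:.0f} EUR, dE={icer.dE:.4f} QALYs, "
      f"median ICER {icer.median_icer:,.0f} EUR/QALY")
```

prints (synthetic cohort, master seed 1):

```
      n  qaly_mean  pct_improved
arm
CBT  88      0.157        23.864
PST  88      0.148         7.955
WL   87      0.138         6.897
CBT-WL: dC=483 EUR, dE=0.0184 QALYs, median ICER 26,049 EUR/QALY
```

Read: on this simulated cohort, CBT costs €483 more than waiting over 12
weeks and gains 0.018 QALYs per participant, so the central bootstrap
estimate is ≈ €26k per QALY gained; the per-arm table shows mean QALYs
and the percentage with clinically significant change after EM
imputation (note how conditional-mean imputation pulls the improvement
percentages below the complete-data rates — see `docs/methods.md`).

The same analysis is available from the shell:

```
cea simulate --config cfg.yaml -o cohort.csv   # synthesize a cohort
cea run --config cfg.yaml                      # impute, cost, bootstrap
cea verify                                     # recompute printed arithmetic
```

and as numbered drivers under `analysis/` (simulate → impute → outcomes
and costs → economic evaluation → arithmetic verification), each writing
its tables under `results/`.

`cea verify` recomputes the arithmetic the trial report prints from its
own summary inputs, for example:

```
ok  chi2_rcsc_statistic             computed=5.0963 expected=5.1000 tol=0.01
ok  pct_rcsc_CBT                    computed=28.4091 expected=28.4000 tol=0.05
ok  delta_total_CBT_WL              computed=256.0000 expected=256.0000 tol=1.0
ok  table1_nonmedical_max_abs_error computed=0.0200 expected=0.0000 tol=0.05
all 12 checks passed
```

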