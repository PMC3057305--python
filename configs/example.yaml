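# Full analysis on a freshly generated synthetic cohort.
# Usage: cea run --config configs/example.yaml [--seed N]
#        cea simulate --config configs/example.yaml -o cohort.csv
synthetic: {}          # default three-arm trial (88/88/87, ~44% dropout)
# cohort_path: cohort.csv      # analyse an existing cohort file instead
# unit_costs_path: costs.csv   # override the built-in 2007 unit-cost table
output_dir: results/example
B: 5000                # bootstrap replicates per contrast
seed: 1                # master seed; all stages derive from it
lambda_max: 50000      # willingness-to-pay grid ceiling (EUR)
lambda_step: 500
reliability: 0.87      # CES-D test-retest reliability for the RCI
cutoff: 16             # CES-D recovery cutoff
z: 1.96                # reliable-change criterion
qaly_rule: trapezoid   # or right_endpoint
imputation: em         # main analysis; 'regression' = sensitivity analysis
friction_day_rate: 115.0
medication_price: 11.0
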