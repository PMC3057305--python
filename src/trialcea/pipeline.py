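"""End-to-end analysis pipeline and reported-arithmetic verification.

``run_analysis`` reproduces the full economic evaluation on a cohort file
(or a freshly generated synthetic cohort): impute missing follow-up data
(EM for the main analysis, regression for the sensitivity analysis),
compute QALYs and clinically-significant-change flags, aggregate societal
costs, and bootstrap the three contrasts (CBT-WL, PST-WL, PST-CBT) under
both effect measures, writing CSV outputs and a machine-readable run
manifest. Identical (config, seed) gives byte-identical outputs.

``verify_reported_arithmetic`` recomputes the arithmetic that the trial
publication prints from its own summary numbers (the chi-square test on
the clinically-significant-change counts, arm percentages, incremental
costs, and the per-visit nonmedical cost reconstruction) and reports each
check with its tolerance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import costing, econ, imputation, outcomes, reference, schema, synthetic

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "run_analysis",
    "verify_reported_arithmetic",
    "derive_seeds",
]

#: Columns imputed in the analysis matrix (baseline columns are complete
#: by design and enter only as predictors).
FOLLOWUP_OUTCOME_COLS = (
    [schema.cesd_col(w) for w in (5, 8, 12)]
    + [schema.util_col(w) for w in (5, 8, 12)]
)
PERIOD_COST_COLS = [f"{cat}_{p}" for p in ("p1", "p2", "p3")
                    for cat in ("dm", "dnm", "ind")]
BASELINE_COLS = [schema.cesd_col(0), schema.util_col(0)]


def derive_seeds(master: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    cohort_path: str | None = None
    unit_costs_path: str | None = None
    output_dir: str = "results/run"
    B: int = 5000
    seed: int = 0
    lambda_max: float = 50_000.0
    lambda_step: float = 500.0
    reliability: float = outcomes.DEFAULT_RELIABILITY
    cutoff: float = float(reference.CESD_CUTOFF)
    z: float = 1.96
    qaly_rule: str = "trapezoid"
    imputation: str = "em"
    friction_day_rate: float = 115.0
    medication_price: float = 11.0
    synthetic: dict | None = None   # TrialConfig overrides; None = need file

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.imputation not in {"em", "regression"}:
            raise ValueError("imputation must be 'em' or 'regression'")
        if self.qaly_rule not in {"trapezoid", "right_endpoint"}:
            raise ValueError("qaly_rule must be 'trapezoid' or "
                             "'right_endpoint'")
        if self.cohort_path is None and self.synthetic is None:
            raise ValueError("need either cohort_path or a synthetic block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def trial_config(self, seed: int) -> synthetic.TrialConfig:
        """Build the synthetic-generation config, applying overrides."""
        over = dict(self.synthetic or {})
        kwargs: dict = {"seed": seed}
        if "n_per_arm" in over:
            kwargs["n_per_arm"] = {k: int(v)
                                   for k, v in over.pop("n_per_arm").items()}
        if "dropout_wave_probs" in over:
            kwargs["dropout"] = synthetic.DropoutModel(
                wave_probs=tuple(over.pop("dropout_wave_probs")))
        if over:
            raise ValueError(f"unknown synthetic overrides: {sorted(over)}")
        return synthetic.TrialConfig(**kwargs)


@dataclass
class AnalysisResult:
    """In-memory bundle of one run's outputs."""

    cohort: pd.DataFrame
    imputed: pd.DataFrame
    costs: pd.DataFrame
    cost_summary: pd.DataFrame
    outcome_summary: pd.DataFrame
    contrasts: dict
    manifest: dict


def build_analysis_matrix(cohort: pd.DataFrame,
                          unit_costs: costing.UnitCostTable,
                          friction: costing.FrictionParams) -> pd.DataFrame:
    """Assemble the per-participant matrix the imputation operates on.

    Columns: baseline CES-D and utility (complete), follow-up CES-D and
    utilities, and per-period cost-category totals (NaN where the period
    was not returned). Missing cost data are imputed at the period-total
    level, not at the level of individual service counts.
    """
    pcosts = costing.period_costs(cohort, unit_costs, friction)
    base = cohort[["id", "arm"] + BASELINE_COLS + FOLLOWUP_OUTCOME_COLS]
    return base.merge(pcosts.drop(columns="arm"), on="id")


def imputation_ranges() -> dict[str, tuple[float, float]]:
    ranges: dict[str, tuple[float, float]] = {}
    for w in schema.WEEKS:
        ranges[schema.cesd_col(w)] = schema.RANGES["cesd"]
        ranges[schema.util_col(w)] = schema.RANGES["utility"]
    for col in PERIOD_COST_COLS:
        ranges[col] = (0.0, np.inf)
    return ranges


def impute_analysis_matrix(matrix: pd.DataFrame, method: str = "em",
                           seed: int | None = None) -> pd.DataFrame:
    """Complete the analysis matrix within each arm by EM or regression."""
    cols = BASELINE_COLS + FOLLOWUP_OUTCOME_COLS + PERIOD_COST_COLS
    return imputation.impute_by_arm(
        matrix, cols, imputation_ranges(), method=method, seed=seed)


def cumulative_costs(imputed: pd.DataFrame,
                     unit_costs: costing.UnitCostTable) -> pd.DataFrame:
    """12-week cost breakdown from imputed period totals plus intervention."""
    out = imputed[["id", "arm"]].copy()
    dm = sum(imputed[f"dm_{p}"] for p in ("p1", "p2", "p3"))
    dm = dm + imputed["arm"].map(unit_costs.intervention_cost).astype(float)
    out["direct_medical"] = dm.round(2)
    out["direct_nonmedical"] = sum(
        imputed[f"dnm_{p}"] for p in ("p1", "p2", "p3")).round(2)
    out["indirect"] = sum(
        imputed[f"ind_{p}"] for p in ("p1", "p2", "p3")).round(2)
    out["total"] = (out["direct_medical"] + out["direct_nonmedical"]
                    + out["indirect"]).round(2)
    return out


def run_analysis(config: RunConfig,
                 write: bool = True) -> AnalysisResult:
    """Execute the full evaluation described by ``config``."""
    seeds = derive_seeds(config.seed, 4)
    gen_seed, miss_seed, boot_seed, summary_seed = seeds

    # --- stage 1: cohort -------------------------------------------------
    if config.cohort_path is not None:
        cohort = synthetic.read_cohort(config.cohort_path)
    else:
        tc = config.trial_config(gen_seed)
        cohort = synthetic.generate_cohort(tc)
        cohort = synthetic.apply_missingness(cohort, tc.dropout,
                                             seed=miss_seed)

    unit_costs = (costing.UnitCostTable.default()
                  if config.unit_costs_path is None
                  else costing.UnitCostTable.from_csv(config.unit_costs_path))
    unit_costs = dataclasses.replace(
        unit_costs, medication_price=config.medication_price)
    friction = costing.FrictionParams(day_rate=config.friction_day_rate)

    # --- stage 2: imputation --------------------------------------------
    matrix = build_analysis_matrix(cohort, unit_costs, friction)
    n_missing = int(matrix[FOLLOWUP_OUTCOME_COLS + PERIOD_COST_COLS]
                    .isna().sum().sum())
    imputed = impute_analysis_matrix(matrix, method=config.imputation,
                                     seed=summary_seed)

    # --- stage 3: outcomes and costs ------------------------------------
    costs = cumulative_costs(imputed, unit_costs)
    cost_summary = costing.arm_cost_summary(costs)
    outcome_summary = outcomes.arm_outcome_summary(
        imputed, rule=config.qaly_rule, seed=summary_seed,
        cutoff=config.cutoff, z=config.z, reliability=config.reliability)

    qalys = outcomes.cohort_qalys(imputed, rule=config.qaly_rule)
    rcsc = outcomes.cohort_rcsc(imputed, cutoff=config.cutoff, z=config.z,
                                reliability=config.reliability)
    ce = costs[["id", "arm", "total"]].merge(
        qalys[["id", "qaly_total"]], on="id").merge(
        rcsc[["id", "clinically_significant"]], on="id")
    ce["clinically_significant"] = ce["clinically_significant"].astype(float)

    # --- stage 4: three contrasts x two effect measures ------------------
    grid = econ.default_lambda_grid(config.lambda_max, config.lambda_step)
    contrast_seeds = derive_seeds(boot_seed, 6)
    results = {}
    for i, (contrast, effect) in enumerate(
            (c, e) for c in econ.CONTRASTS for e in ("qaly", "rcsc")):
        results[(contrast, effect)] = econ.evaluate_contrast(
            ce, contrast, effect_kind=effect, B=config.B,
            lambda_grid=grid, seed=contrast_seeds[i])

    manifest = {
        "config": config.to_dict(),
        "derived_seeds": {"generation": gen_seed, "missingness": miss_seed,
                          "bootstrap": boot_seed, "summary": summary_seed},
        "n_participants": int(len(cohort)),
        "n_missing_cells": n_missing,
        "imputation_method": config.imputation,
    }

    result = AnalysisResult(
        cohort=cohort, imputed=imputed, costs=costs,
        cost_summary=cost_summary, outcome_summary=outcome_summary,
        contrasts=results, manifest=manifest)
    if write:
        _write_outputs(result, config)
    return result


def _fmt_money(x: float) -> str:
    return f"{x:.2f}"


def _write_outputs(result: AnalysisResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic.write_cohort(result.cohort, out / "cohort.csv")
    result.imputed.to_csv(out / "imputed_matrix.csv", index=False)
    result.costs.to_csv(out / "participant_costs.csv", index=False,
                        float_format="%.2f")
    result.cost_summary.round(2).to_csv(out / "cost_summary.csv")
    diffs = result.cost_summary.attrs.get("differences")
    if diffs:
        pd.DataFrame(diffs).round(2).to_csv(out / "cost_differences.csv",
                                            index=False)
    result.outcome_summary.round(4).to_csv(out / "outcome_summary.csv")
    for (contrast, effect), res in result.contrasts.items():
        tag = f"{contrast}_{effect}"
        pd.DataFrame({"dE": res.draws.dE, "dC": res.draws.dC}).to_csv(
            out / f"plane_{tag}.csv", index=False)
        pd.DataFrame({"lambda": res.ceac.lambdas,
                      "probability": res.ceac.probability}).to_csv(
            out / f"ceac_{tag}.csv", index=False, float_format="%.4f")
        icer = res.icer
        lines = [
            f"contrast: {contrast}  effect: {effect}",
            f"dC (EUR): {_fmt_money(icer.dC)}",
            f"dE: {icer.dE:.6f}",
            ("point ICER: undefined (dE ~ 0)" if icer.undefined
             else f"point ICER: {_fmt_money(icer.point_icer)}"),
            f"median ICER: {_fmt_money(icer.median_icer)}",
            f"95% CI: [{_fmt_money(icer.ci_lower)}, "
            f"{_fmt_money(icer.ci_upper)}]",
            "quadrants (NE/SE/NW/SW): "
            + "/".join(f"{icer.quadrants[q]:.4f}"
                       for q in ("NE", "SE", "NW", "SW")),
            f"draws with dE == 0: {icer.n_zero_effect}",
        ]
        (out / f"icer_{tag}.txt").write_text("\n".join(lines) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# verification of the published arithmetic

def verify_reported_arithmetic() -> dict[str, dict]:
    """Recompute the published summary arithmetic from printed inputs.

    Every check uses only numbers printed in the trial report (counts,
    cost-table means, unit costs) and the package's own operations; the
    returned mapping gives computed value, expected value, tolerance and
    pass flag per check.
    """
    checks: dict[str, dict] = {}

    def add(name, computed, expected, tol):
        checks[name] = {
            "computed": float(computed), "expected": float(expected),
            "tolerance": float(tol),
            "passed": bool(abs(computed - expected) <= tol)}

    # chi-square on clinically-significant-change counts
    table = [[k, n - k] for k, n in (reference.RCSC_COUNTS[a]
                                     for a in reference.ARMS)]
    chi2 = outcomes.pearson_chi2(table)
    add("chi2_rcsc_statistic", chi2.statistic, reference.RCSC_CHI2, 0.01)
    add("chi2_rcsc_df", chi2.df, reference.RCSC_CHI2_DF, 0)
    add("chi2_rcsc_p", chi2.p, reference.RCSC_CHI2_P, 0.005)

    # arm percentages of clinically significant change
    for arm, expected in (("CBT", 28.4), ("PST", 26.1), ("WL", 14.9)):
        k, n = reference.RCSC_COUNTS[arm]
        add(f"pct_rcsc_{arm}", 100.0 * k / n, expected, 0.05)

    # incremental costs from the printed cost-table means
    t = reference.COST_TABLE
    add("delta_total_CBT_WL", t["CBT"]["total"][0] - t["WL"]["total"][0],
        256.0, 1.0)
    add("delta_total_PST_WL", t["PST"]["total"][0] - t["WL"]["total"][0],
        147.0, 1.0)
    add("delta_indirect_CBT_WL",
        t["WL"]["indirect"][0] - t["CBT"]["indirect"][0], 201.0, 2.0)
    add("delta_indirect_PST_WL",
        t["WL"]["indirect"][0] - t["PST"]["indirect"][0], 258.0, 2.0)

    # per-visit nonmedical cost reconstruction
    errors = costing.UnitCostTable.default().reconstruction_errors()
    add("table1_nonmedical_max_abs_error",
        max(abs(e) for e in errors.values()), 0.0, 0.05)

    # point ICER (cost per clinically significant change) from printed means
    k1, n1 = reference.RCSC_COUNTS["CBT"]
    k0, n0 = reference.RCSC_COUNTS["WL"]
    icer, _ = econ.icer_point(t["CBT"]["total"][0], k1 / n1,
                              t["WL"]["total"][0], k0 / n0)
    add("point_icer_rcsc_CBT_WL", icer, 256.0 / (k1 / n1 - k0 / n0), 0.5)

    return checks
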