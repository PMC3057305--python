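"""Seeded synthetic three-arm trial cohorts.

The original participant-level trial data were never deposited, so every
downstream stage is exercised on synthetic cohorts that reproduce the
statistical structure the analysis assumes:

* three arms (CBT, PST, WL) of 88/88/87 participants;
* baseline CES-D drawn from a normal(31.7, 7.5) truncated below at the
  inclusion cutoff of 16, baseline EQ-5D utility with mean 0.61 and SD
  0.22 (clipped to [0, 1]), negatively coupled to baseline severity;
* follow-up trajectories at weeks 5, 8 and 12 with regression to the
  mean, AR(1)-correlated residuals, and additive per-arm treatment
  effects calibrated so that arm-level outcomes (share with clinically
  significant change, 12-week QALYs) land near the published values;
* right-skewed resource use: per-service zero-inflated counts with
  occurrence probabilities taken from the published service-use table,
  and log-normal productivity losses, giving cost distributions whose
  SDs exceed their means;
* missing-at-random dropout: monotone, with per-wave marginal
  missingness calibrated exactly and individual risk increasing with
  baseline severity — reaching ~44% missing cost data at week 12.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import reference, schema

__all__ = [
    "ConfigError",
    "ServiceUseModel",
    "ProductivityModel",
    "ArmEffects",
    "DropoutModel",
    "TrialConfig",
    "generate_cohort",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
    "synthetic_arm_data",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


def _check_pos(value: float, name: str) -> None:
    if value <= 0:
        raise ConfigError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class ServiceUseModel:
    """Zero-inflated count model for one service over a 4-week window.

    With probability ``p_use`` (scaled by period length) the participant
    uses the service ``1 + Poisson(extra_count_lam)`` times; otherwise
    the count is zero.
    """

    p_use: float
    extra_count_lam: float = 0.3

    def validate(self, name: str) -> None:
        _check_prob(self.p_use, f"service_use[{name}].p_use")
        if self.extra_count_lam < 0:
            raise ConfigError(
                f"service_use[{name}].extra_count_lam must be >= 0")


#: Default per-4-week occurrence probabilities, aligned with the share of
#: participants reporting each service at baseline in the published trial.
DEFAULT_SERVICE_USE: dict[str, ServiceUseModel] = {
    "gp": ServiceUseModel(0.38, 0.3),
    "mental_health": ServiceUseModel(0.17, 0.4),
    "psychotherapist": ServiceUseModel(0.28, 0.6),
    "psychotherapist_hospital": ServiceUseModel(0.06, 0.3),
    "company_doctor": ServiceUseModel(0.09, 0.2),
    "company_social_worker": ServiceUseModel(0.03, 0.2),
    "specialist": ServiceUseModel(0.19, 0.2),
    "physiotherapist": ServiceUseModel(0.21, 1.5),
    "social_worker": ServiceUseModel(0.03, 0.2),
    "alcohol_drugs": ServiceUseModel(0.005, 0.3),
    "home_care": ServiceUseModel(0.03, 4.0),
    "alternative_care": ServiceUseModel(0.15, 0.4),
    "self_help": ServiceUseModel(0.035, 0.6),
}


@dataclass(frozen=True)
class ProductivityModel:
    """Log-normal productivity-loss quantities per 4-week window."""

    p_workloss: float = 0.17
    workloss_mu: float = 2.3      # log-days
    workloss_sigma: float = 0.7
    p_cutback: float = 0.38
    cutback_mu: float = 2.1
    cutback_sigma: float = 0.6
    inefficiency_a: float = 2.0   # Beta parameters of the 0-1 score
    inefficiency_b: float = 3.0
    p_domestic: float = 0.78
    domestic_mu: float = 3.1      # log-hours
    domestic_sigma: float = 0.8

    def validate(self) -> None:
        for name in ("p_workloss", "p_cutback", "p_domestic"):
            _check_prob(getattr(self, name), f"productivity.{name}")
        for name in ("workloss_sigma", "cutback_sigma", "domestic_sigma",
                     "inefficiency_a", "inefficiency_b"):
            _check_pos(getattr(self, name), f"productivity.{name}")


@dataclass(frozen=True)
class ArmEffects:
    """Additive treatment effects for one arm at weeks 5, 8, 12.

    ``cesd_shift`` is added to the expected CES-D (negative = improvement),
    ``utility_shift`` to the expected utility. ``followup_use_multiplier``
    scales service-use and productivity-loss occurrence probabilities in
    the follow-up periods (interventions reduce care consumption).
    """

    cesd_shift: tuple[float, float, float]
    utility_shift: tuple[float, float, float]
    followup_use_multiplier: float = 1.0

    def validate(self, arm: str) -> None:
        if len(self.cesd_shift) != 3 or len(self.utility_shift) != 3:
            raise ConfigError(
                f"arm_effects[{arm}]: shifts need one value per follow-up "
                "wave (weeks 5, 8, 12)")
        if self.followup_use_multiplier < 0:
            raise ConfigError(
                f"arm_effects[{arm}].followup_use_multiplier must be >= 0")


DEFAULT_ARM_EFFECTS: dict[str, ArmEffects] = {
    "CBT": ArmEffects(cesd_shift=(-7.0, -10.0, -12.0),
                      utility_shift=(0.05, 0.08, 0.10),
                      followup_use_multiplier=0.88),
    "PST": ArmEffects(cesd_shift=(-8.0, -10.0, -11.5),
                      utility_shift=(0.07, 0.09, 0.10),
                      followup_use_multiplier=0.90),
    "WL": ArmEffects(cesd_shift=(-3.0, -6.0, -8.0),
                     utility_shift=(0.03, 0.05, 0.06),
                     followup_use_multiplier=1.0),
}


@dataclass(frozen=True)
class DropoutModel:
    """Monotone MAR dropout.

    ``wave_probs`` are the marginal probabilities that a participant's
    wave-k follow-up (outcomes and the corresponding cost period) is
    missing. Individual risk depends on baseline severity through
    ``beta_cesd`` (log-odds per baseline-CES-D standard deviation) and on
    arm through ``arm_offsets`` (log-odds); a per-wave intercept is solved
    so the configured marginal holds exactly in expectation. A single
    uniform per participant makes dropout monotone across waves.
    """

    wave_probs: tuple[float, float, float] = (0.20, 0.32, 0.44)
    beta_cesd: float = 0.5
    arm_offsets: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.0 for a in reference.ARMS})

    def validate(self) -> None:
        if len(self.wave_probs) != 3:
            raise ConfigError("dropout.wave_probs needs one value per "
                              "follow-up wave")
        for k, p in enumerate(self.wave_probs, start=1):
            _check_prob(p, f"dropout.wave_probs[{k}]")


@dataclass(frozen=True)
class TrialConfig:
    """Full specification of a synthetic three-arm cohort."""

    n_per_arm: Mapping[str, int] = field(
        default_factory=lambda: dict(reference.ARM_N))
    cesd_baseline_mean: float = reference.CESD_BASELINE_MEAN
    cesd_baseline_sd: float = reference.CESD_BASELINE_SD
    cesd_truncation: float = float(reference.CESD_CUTOFF)
    utility_baseline_mean: float = reference.UTILITY_BASELINE_MEAN
    utility_baseline_sd: float = reference.UTILITY_BASELINE_SD
    #: slope of baseline utility on baseline CES-D (per score point).
    utility_cesd_slope: float = -0.01
    #: regression-to-the-mean coefficient of follow-up CES-D on baseline.
    cesd_autoregression: float = 0.7
    cesd_resid_sd: float = 6.5
    util_resid_sd: float = 0.12
    #: loading of utility residuals on the CES-D residual (utility falls
    #: as depression rises).
    util_cesd_resid_slope: float = -0.012
    #: AR(1) correlation of residuals across the three follow-up waves.
    ar1_rho: float = 0.6
    arm_effects: Mapping[str, ArmEffects] = field(
        default_factory=lambda: dict(DEFAULT_ARM_EFFECTS))
    service_use: Mapping[str, ServiceUseModel] = field(
        default_factory=lambda: dict(DEFAULT_SERVICE_USE))
    p_medication: float = 0.54
    productivity: ProductivityModel = ProductivityModel()
    dropout: DropoutModel = DropoutModel()
    seed: int = 0

    def validate(self) -> None:
        for arm in reference.ARMS:
            n = self.n_per_arm.get(arm)
            if n is None or n < 1:
                raise ConfigError(f"n_per_arm[{arm}] must be >= 1, got {n}")
        _check_pos(self.cesd_baseline_sd, "cesd_baseline_sd")
        _check_pos(self.utility_baseline_sd, "utility_baseline_sd")
        _check_pos(self.cesd_resid_sd, "cesd_resid_sd")
        _check_pos(self.util_resid_sd, "util_resid_sd")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must lie in (-1, 1)")
        _check_prob(self.p_medication, "p_medication")
        for arm in reference.ARMS:
            if arm not in self.arm_effects:
                raise ConfigError(f"arm_effects missing arm {arm!r}")
            self.arm_effects[arm].validate(arm)
        for name, model in self.service_use.items():
            model.validate(name)
        self.productivity.validate()
        self.dropout.validate()

    @property
    def n_total(self) -> int:
        return sum(self.n_per_arm[a] for a in reference.ARMS)


def _truncnorm_params(mean: float, sd: float, lower: float
                      ) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose truncation at ``lower`` has the
    given mean and SD.

    The published baseline moments describe the *included* population
    (everyone scores at least the cutoff), so the generator solves for the
    untruncated parameters rather than truncating normal(mean, sd), which
    would shrink the sample SD below the configured value.
    """
    if lower <= mean - 8 * sd:  # truncation numerically inactive
        return mean, sd

    def residuals(theta):
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                     moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residuals, x0=[mean, math.log(sd)], tol=1e-10)
    if not sol.success:
        raise ConfigError(
            "cesd_baseline_mean/sd incompatible with the truncation bound: "
            "no underlying normal has these truncated moments")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _ar1_cov(sd: float, rho: float, k: int = 3) -> np.ndarray:
    idx = np.arange(k)
    return sd ** 2 * rho ** np.abs(idx[:, None] - idx[None, :])


def _draw_counts(rng: np.random.Generator, n: int, p: np.ndarray | float,
                 lam: float) -> np.ndarray:
    used = rng.random(n) < p
    counts = np.where(used, 1 + rng.poisson(lam, size=n), 0)
    return counts.astype(float)


def _draw_lognormal(rng: np.random.Generator, n: int, p: np.ndarray | float,
                    mu: float, sigma: float, cap: float) -> np.ndarray:
    occurs = rng.random(n) < p
    vals = np.where(occurs, rng.lognormal(mu, sigma, size=n), 0.0)
    return np.minimum(np.round(vals, 1), cap)


def generate_cohort(config: TrialConfig) -> pd.DataFrame:
    """Generate a complete cohort (no missingness) from the configuration.

    Returns one row per participant in the standard column layout; arm
    sizes are exactly as configured and the whole table is a deterministic
    function of ``(config, config.seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu0, sigma0 = _truncnorm_params(
        config.cesd_baseline_mean, config.cesd_baseline_sd,
        config.cesd_truncation)
    frames = []
    offset = 0
    for arm in reference.ARMS:
        n = config.n_per_arm[arm]
        eff = config.arm_effects[arm]
        df = pd.DataFrame(index=range(n))
        df["id"] = [f"P{offset + i + 1:04d}" for i in range(n)]
        df["arm"] = arm

        # baseline CES-D: truncated normal above the inclusion cutoff,
        # parameterized so the truncated moments match the configuration
        a = (config.cesd_truncation - mu0) / sigma0
        cesd0 = stats.truncnorm.rvs(
            a, np.inf, loc=mu0, scale=sigma0, size=n, random_state=rng)
        cesd0 = np.minimum(cesd0, 60.0)
        df[schema.cesd_col(0)] = np.round(cesd0, 1)

        # baseline utility, coupled to severity, clipped into [0, 1]
        util0 = (config.utility_baseline_mean
                 + config.utility_cesd_slope
                 * (cesd0 - config.cesd_baseline_mean)
                 + rng.normal(0.0, _marginal_util_sd(config), size=n))
        util0 = np.clip(util0, 0.0, 1.0)
        df[schema.util_col(0)] = np.round(util0, 3)

        # follow-up trajectories with AR(1)-correlated residuals
        eps_c = rng.multivariate_normal(
            np.zeros(3), _ar1_cov(config.cesd_resid_sd, config.ar1_rho),
            size=n)
        eps_u_ind = rng.multivariate_normal(
            np.zeros(3), _ar1_cov(config.util_resid_sd, config.ar1_rho),
            size=n)
        alpha = config.cesd_autoregression
        for k, (week, _period) in schema.FOLLOWUP_WAVES.items():
            cesd_k = (config.cesd_baseline_mean
                      + alpha * (cesd0 - config.cesd_baseline_mean)
                      + eff.cesd_shift[k - 1] + eps_c[:, k - 1])
            df[schema.cesd_col(week)] = np.round(np.clip(cesd_k, 0, 60), 1)
            util_k = (util0 + eff.utility_shift[k - 1]
                      + config.util_cesd_resid_slope * eps_c[:, k - 1]
                      + eps_u_ind[:, k - 1])
            df[schema.util_col(week)] = np.round(np.clip(util_k, 0, 1), 3)

        # resource use and productivity losses per costing period
        for period in schema.PERIODS:
            weeks = schema.PERIOD_WEEKS[period]
            scale = weeks / 4.0
            mult = 1.0 if period == "pre" else eff.followup_use_multiplier
            for slug in schema.SERVICES:
                model = config.service_use.get(slug, ServiceUseModel(0.0))
                p = min(1.0, model.p_use * scale * mult)
                df[schema.use_col(slug, period)] = _draw_counts(
                    rng, n, p, model.extra_count_lam)
            p_med = min(1.0, config.p_medication)
            on_med = rng.random(n) < p_med
            df[schema.med_col(period)] = np.where(
                on_med, np.round(weeks / 4.345, 2), 0.0)
            prod = config.productivity
            df[schema.workloss_col(period)] = _draw_lognormal(
                rng, n, min(1.0, prod.p_workloss * scale * mult),
                prod.workloss_mu, prod.workloss_sigma, cap=5.0 * weeks)
            df[schema.cutback_col(period)] = _draw_lognormal(
                rng, n, min(1.0, prod.p_cutback * scale * mult),
                prod.cutback_mu, prod.cutback_sigma, cap=5.0 * weeks)
            df[schema.inefficiency_col(period)] = np.round(
                rng.beta(prod.inefficiency_a, prod.inefficiency_b, size=n), 3)
            df[schema.domestic_col(period)] = _draw_lognormal(
                rng, n, min(1.0, prod.p_domestic * scale * mult),
                prod.domestic_mu, prod.domestic_sigma, cap=20.0 * weeks)
        frames.append(df)
        offset += n
    cohort = pd.concat(frames, ignore_index=True)
    return cohort[schema.cohort_columns()]


def _marginal_util_sd(config: TrialConfig) -> float:
    """Residual SD of baseline utility so its marginal SD is as configured."""
    explained = (config.utility_cesd_slope * config.cesd_baseline_sd) ** 2
    resid_var = config.utility_baseline_sd ** 2 - explained
    if resid_var <= 0:
        raise ConfigError(
            "utility_baseline_sd too small for utility_cesd_slope: the "
            "severity coupling alone exceeds the configured variance")
    return math.sqrt(resid_var)


def _wave_probabilities(cesd0: np.ndarray, arms: np.ndarray,
                        dropout: DropoutModel) -> np.ndarray:
    """Per-participant missingness probability for each follow-up wave.

    Solves the per-wave intercept so the population mean equals the
    configured marginal exactly under the logistic MAR model.
    """
    z = (cesd0 - cesd0.mean()) / (cesd0.std() if cesd0.std() > 0 else 1.0)
    shift = dropout.beta_cesd * z + np.array(
        [dropout.arm_offsets.get(a, 0.0) for a in arms])
    probs = np.empty((len(cesd0), 3))
    for k, p_wave in enumerate(dropout.wave_probs):
        if p_wave <= 0.0:
            probs[:, k] = 0.0
        elif p_wave >= 1.0:
            probs[:, k] = 1.0
        elif np.allclose(shift, 0.0):
            probs[:, k] = p_wave
        else:
            c = optimize.brentq(
                lambda c: special.expit(c + shift).mean() - p_wave,
                -40.0, 40.0)
            probs[:, k] = special.expit(c + shift)
    return probs


def _wave_columns(wave: int) -> list[str]:
    week, period = schema.FOLLOWUP_WAVES[wave]
    cols = [schema.cesd_col(week), schema.util_col(week)]
    cols += [schema.use_col(s, period) for s in schema.SERVICES]
    cols += [schema.med_col(period), schema.workloss_col(period),
             schema.cutback_col(period), schema.inefficiency_col(period),
             schema.domestic_col(period)]
    return cols


def apply_missingness(cohort: pd.DataFrame, dropout: DropoutModel,
                      seed: int | None = None) -> pd.DataFrame:
    """Blank out follow-up waves under monotone MAR dropout.

    Baseline fields (week 0, pre period) are never removed. A participant
    missing at wave k is missing that wave's outcomes and cost period; a
    single uniform per participant makes dropout monotone whenever the
    per-wave probabilities are non-decreasing. The expected missing
    fraction at each wave equals the configured marginal.
    """
    dropout.validate()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    probs = _wave_probabilities(
        cohort[schema.cesd_col(0)].to_numpy(dtype=float),
        cohort["arm"].to_numpy(), dropout)
    u = rng.random(len(cohort))
    for wave in (1, 2, 3):
        missing = u < probs[:, wave - 1]
        if missing.any():
            out.loc[missing, _wave_columns(wave)] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort file I/O

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV; empty cells denote missing values."""
    cohort.to_csv(path, index=False)


def _validate_cohort(df: pd.DataFrame, path) -> None:
    def fail(row: int, col: str, msg: str):
        raise ValueError(f"{path}: row {row + 2}, column {col!r}: {msg}")

    for col in df.columns:
        if col in ("id", "arm"):
            continue
        values = df[col]
        rng_bounds = schema.column_range(col)
        if rng_bounds is not None:
            lo, hi = rng_bounds
            bad = values.notna() & ((values < lo) | (values > hi))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                fail(i, col, f"value {values.iloc[i]} outside [{lo}, {hi}]")
        else:
            bad = values.notna() & (values < 0)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                fail(i, col, f"negative value {values.iloc[i]}")
    bad_arm = ~df["arm"].isin(reference.ARMS)
    if bad_arm.any():
        i = int(np.flatnonzero(bad_arm)[0])
        fail(i, "arm", f"unknown arm {df['arm'].iloc[i]!r}")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (inverse of :func:`write_cohort`)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    missing_cols = set(schema.cohort_columns()) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns "
                         f"{sorted(missing_cols)[:5]} ...")
    _validate_cohort(df, path)
    return df[schema.cohort_columns()]


# ---------------------------------------------------------------------------
# direct arm-level generator with known truth

def synthetic_arm_data(n: int, mean_cost: float, p_effect: float,
                       rng: np.random.Generator,
                       cost_shape: float = 1.2,
                       qaly_mean: float | None = None,
                       qaly_sd: float = 0.02):
    """Costs and effects for one arm with known population means.

    Used for parameter-recovery checks where the true incremental cost
    and effect must be known exactly: costs are gamma-distributed
    (right-skewed) with the given mean, the binary effect is
    Bernoulli(``p_effect``); a continuous QALY effect with the given mean
    is returned instead when ``qaly_mean`` is set.

    Returns an object with paired ``costs`` and ``effects`` arrays.
    """
    from .econ import ArmData

    costs = rng.gamma(cost_shape, mean_cost / cost_shape, size=n)
    if qaly_mean is not None:
        effects = rng.normal(qaly_mean, qaly_sd, size=n)
    else:
        effects = (rng.random(n) < p_effect).astype(float)
    return ArmData(costs=costs, effects=effects)
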