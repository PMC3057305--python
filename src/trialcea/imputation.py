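"""Missing-data imputation: multivariate-normal EM and regression.

The main analysis replaces missing follow-up outcomes and period cost
totals with their conditional expectations under a multivariate normal
model fitted by expectation-maximization on the observed data — the
maximum-likelihood approach that is valid when dropout is missing at
random (MAR). A deterministic least-squares regression imputation is
provided as the sensitivity analysis.

Both methods leave observed cells untouched and clip imputed cells to each
column's admissible range (utilities cannot exceed 1, CES-D lies in
[0, 60], costs are nonnegative), since a linear model is unaware of such
bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "EMResult",
    "em_impute",
    "regression_impute",
    "impute_by_arm",
]


@dataclass
class DataMatrix:
    """Numeric participant-by-variable matrix with admissible ranges.

    ``ranges`` maps a column name to inclusive (lo, hi) bounds; columns
    absent from the mapping are unconstrained (use -inf/inf or simply omit
    them). Missing cells are NaN.
    """

    values: pd.DataFrame
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("DataMatrix needs at least one column")
        for col in self.values.columns:
            obs = self.values[col].dropna()
            if len(obs) == 0:
                raise ValueError(f"column {col!r} has no observed values")
            lo, hi = self.ranges.get(col, (-np.inf, np.inf))
            if ((obs < lo) | (obs > hi)).any():
                raise ValueError(
                    f"observed values in column {col!r} violate the "
                    f"admissible range [{lo}, {hi}]")

    def clip_to_ranges(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, (lo, hi) in self.ranges.items():
            if col in out.columns:
                out[col] = out[col].clip(lo, hi)
        return out


@dataclass
class EMResult:
    completed: pd.DataFrame
    n_iterations: int
    loglik_trace: list[float]
    mean: pd.Series
    cov: pd.DataFrame
    converged: bool


def _check_pairwise_observed(mask_obs: np.ndarray,
                             columns: Sequence[str]) -> None:
    """Every column pair must be jointly observed at least twice, or the
    corresponding covariance entry is not estimable."""
    obs = mask_obs.astype(int)
    joint = obs.T @ obs
    p = joint.shape[0]
    for i in range(p):
        for j in range(i, p):
            if joint[i, j] < 2:
                raise ValueError(
                    "covariance not estimable: columns "
                    f"({columns[i]!r}, {columns[j]!r}) are jointly observed "
                    f"{joint[i, j]} time(s); need at least 2")


def _observed_loglik(X: np.ndarray, mask_obs: np.ndarray, mu: np.ndarray,
                     sigma: np.ndarray, patterns) -> float:
    ll = 0.0
    for obs_idx, rows in patterns:
        if len(obs_idx) == 0:
            continue
        sub = X[np.ix_(rows, obs_idx)]
        mu_o = mu[obs_idx]
        sig_oo = sigma[np.ix_(obs_idx, obs_idx)]
        sign, logdet = np.linalg.slogdet(sig_oo)
        if sign <= 0:
            sig_oo = sig_oo + 1e-8 * np.eye(len(obs_idx))
            sign, logdet = np.linalg.slogdet(sig_oo)
        diff = sub - mu_o
        sol = np.linalg.solve(sig_oo, diff.T)
        quad = np.einsum("ij,ji->i", diff, sol)
        k = len(obs_idx)
        ll += float(-0.5 * (quad.sum()
                            + len(rows) * (logdet + k * np.log(2 * np.pi))))
    return ll


def _patterns(mask_obs: np.ndarray):
    """Group row indices by observed-column pattern."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(mask_obs):
        groups.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, rows in groups.items():
        pattern = np.frombuffer(key, dtype=mask_obs.dtype)
        obs_idx = np.flatnonzero(pattern)
        out.append((obs_idx, np.asarray(rows)))
    return out


def em_impute(m: DataMatrix, tol: float = 1e-6,
              max_iter: int = 500) -> EMResult:
    """Impute missing cells by EM under a single multivariate normal.

    Each EM iteration replaces missing blocks with their conditional
    expectations given the observed block (E-step, including the
    conditional covariance in the second-moment statistics) and re-fits
    the mean and covariance from the completed sufficient statistics
    (M-step). The observed-data log-likelihood is non-decreasing; the
    algorithm stops when its relative change falls below ``tol``. Missing
    cells in the returned matrix are the conditional means under the final
    fit, clipped to the column ranges.
    """
    if m.values.shape[1] < 2:
        raise ValueError("EM imputation needs at least 2 columns")
    X = m.values.to_numpy(dtype=float)
    cols = list(m.values.columns)
    mask_obs = ~np.isnan(X)
    n, p = X.shape

    if mask_obs.all():
        return EMResult(
            completed=m.values.copy(), n_iterations=0,
            loglik_trace=[], mean=m.values.mean(),
            cov=m.values.cov(ddof=0), converged=True)

    _check_pairwise_observed(mask_obs, cols)
    patterns = _patterns(mask_obs)

    # init: observed means, pairwise-complete covariance with SD floor
    mu = np.array([X[mask_obs[:, j], j].mean() for j in range(p)])
    sigma = pd.DataFrame(X).cov(min_periods=2, ddof=0).to_numpy()
    sd = np.sqrt(np.diag(sigma))
    floor = np.maximum(sd, 1e-6 * np.maximum(np.abs(mu), 1.0))
    nanmask = np.isnan(sigma)
    sigma[nanmask] = 0.0
    np.fill_diagonal(sigma, np.maximum(np.diag(sigma), floor ** 2))

    trace: list[float] = []
    converged = False
    it = 0
    Xhat = X.copy()
    for it in range(1, max_iter + 1):
        # E-step
        S2_corr = np.zeros((p, p))
        for obs_idx, rows in patterns:
            mis_idx = np.setdiff1d(np.arange(p), obs_idx)
            if len(mis_idx) == 0:
                continue
            if len(obs_idx) == 0:
                Xhat[np.ix_(rows, mis_idx)] = mu[mis_idx]
                S2_corr[np.ix_(mis_idx, mis_idx)] += (
                    len(rows) * sigma[np.ix_(mis_idx, mis_idx)])
                continue
            sig_oo = sigma[np.ix_(obs_idx, obs_idx)]
            sig_mo = sigma[np.ix_(mis_idx, obs_idx)]
            try:
                B = np.linalg.solve(sig_oo, sig_mo.T).T  # regression coefs
            except np.linalg.LinAlgError:
                B = sig_mo @ np.linalg.pinv(sig_oo)
            diff = X[np.ix_(rows, obs_idx)] - mu[obs_idx]
            Xhat[np.ix_(rows, mis_idx)] = mu[mis_idx] + diff @ B.T
            C = sigma[np.ix_(mis_idx, mis_idx)] - B @ sig_mo.T
            S2_corr[np.ix_(mis_idx, mis_idx)] += len(rows) * C

        # M-step
        mu = Xhat.mean(axis=0)
        centered = Xhat - mu
        sigma = (centered.T @ centered + S2_corr) / n
        # guard against collapse of an almost fully missing column
        np.fill_diagonal(sigma, np.maximum(np.diag(sigma), 1e-12))

        ll = _observed_loglik(X, mask_obs, mu, sigma, patterns)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            denom = max(abs(prev), 1.0)
            if (ll - prev) / denom < tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations; returning the "
            "best iterate", RuntimeWarning, stacklevel=2)

    # final E-step: imputed cells are conditional means under the final fit
    for obs_idx, rows in patterns:
        mis_idx = np.setdiff1d(np.arange(p), obs_idx)
        if len(mis_idx) == 0:
            continue
        if len(obs_idx) == 0:
            Xhat[np.ix_(rows, mis_idx)] = mu[mis_idx]
            continue
        sig_oo = sigma[np.ix_(obs_idx, obs_idx)]
        sig_mo = sigma[np.ix_(mis_idx, obs_idx)]
        try:
            B = np.linalg.solve(sig_oo, sig_mo.T).T
        except np.linalg.LinAlgError:
            B = sig_mo @ np.linalg.pinv(sig_oo)
        diff = X[np.ix_(rows, obs_idx)] - mu[obs_idx]
        Xhat[np.ix_(rows, mis_idx)] = mu[mis_idx] + diff @ B.T

    Xhat[mask_obs] = X[mask_obs]  # observed cells untouched
    completed = pd.DataFrame(Xhat, index=m.values.index, columns=cols)
    completed = m.clip_to_ranges(completed)
    return EMResult(
        completed=completed, n_iterations=it, loglik_trace=trace,
        mean=pd.Series(mu, index=cols),
        cov=pd.DataFrame(sigma, index=cols, columns=cols),
        converged=converged)


def regression_impute(m: DataMatrix, seed: int | None = None,
                      add_residual: bool = False) -> pd.DataFrame:
    """Impute each missing cell from a least-squares fit on complete cases.

    For every column with missing values, an ordinary least-squares model
    is fitted on the complete cases, regressing the column on whichever of
    the remaining columns are observed in the target row (one fit per
    missing pattern). With fewer complete cases than predictors plus two
    the method falls back to column-mean imputation with a warning.
    Deterministic by default; ``add_residual=True`` adds normal residual
    draws using ``seed``.
    """
    df = m.values
    X = df.to_numpy(dtype=float)
    mask_obs = ~np.isnan(X)
    if mask_obs.all():
        return df.copy()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    out = X.copy()
    complete_rows = mask_obs.all(axis=1)
    cache: dict[tuple[int, bytes], tuple[np.ndarray, float]] = {}
    for j in range(p):
        miss_rows = np.flatnonzero(~mask_obs[:, j])
        if len(miss_rows) == 0:
            continue
        for i in miss_rows:
            pred_idx = np.flatnonzero(mask_obs[i] & (np.arange(p) != j))
            key = (j, pred_idx.tobytes())
            if key not in cache:
                fit_rows = complete_rows
                n_fit = int(fit_rows.sum())
                if n_fit < len(pred_idx) + 2 or len(pred_idx) == 0:
                    warnings.warn(
                        f"column {df.columns[j]!r}: too few complete cases "
                        f"({n_fit}) for regression; using column mean",
                        RuntimeWarning, stacklevel=2)
                    mean_j = X[mask_obs[:, j], j].mean()
                    cache[key] = (None, mean_j)  # type: ignore[arg-type]
                else:
                    A = np.column_stack([np.ones(n_fit),
                                         X[np.ix_(fit_rows, pred_idx)]])
                    y = X[fit_rows, j]
                    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                    resid = y - A @ beta
                    dof = max(n_fit - len(beta), 1)
                    scale = float(np.sqrt((resid ** 2).sum() / dof))
                    cache[key] = (beta, scale)
            beta, scale = cache[key]
            if beta is None:
                out[i, j] = scale  # column mean fallback
            else:
                out[i, j] = beta[0] + X[i, pred_idx] @ beta[1:]
                if add_residual:
                    out[i, j] += rng.normal(0.0, scale)
    out[mask_obs] = X[mask_obs]  # observed cells untouched
    completed = pd.DataFrame(out, index=df.index, columns=df.columns)
    return m.clip_to_ranges(completed)


def impute_by_arm(df: pd.DataFrame, columns: Sequence[str],
                  ranges: Mapping[str, tuple[float, float]],
                  method: str = "em", arm_col: str = "arm",
                  seed: int | None = None, **kwargs) -> pd.DataFrame:
    """Impute the given numeric columns separately within each trial arm.

    Within-arm imputation preserves between-arm contrasts: a treatment
    that lowers costs is not pulled toward the control mean. Returns a
    copy of ``df`` with the columns completed; other columns pass through.
    """
    if method not in {"em", "regression"}:
        raise ValueError(f"unknown imputation method {method!r}")
    out = df.copy()
    for arm in sorted(df[arm_col].unique()):
        rows = df[arm_col] == arm
        sub = DataMatrix(df.loc[rows, list(columns)].astype(float),
                         ranges=ranges)
        if method == "em":
            completed = em_impute(sub, **kwargs).completed
        else:
            completed = regression_impute(sub, seed=seed, **kwargs)
        out.loc[rows, list(columns)] = completed
    return out
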