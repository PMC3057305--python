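"""Incremental cost-effectiveness analysis with bootstrap uncertainty.

For a contrast of two trial arms the incremental cost-effectiveness ratio
is ICER = (C1 - C0) / (E1 - E0), with the effect either total QALYs
(cost-utility) or the 0/1 clinically-significant-change indicator
(cost-effectiveness, costs per reliably improved case). Because a ratio
of mean differences has no usable standard error, uncertainty is handled
nonparametrically: participants are resampled with replacement within
each arm (keeping every participant's cost-effect pair intact), each of B
replicates yields a (dC, dE) mean-difference pair, and the ICER is
summarised by the median and the 2.5th/97.5th percentiles of the
replicate ratios. The same draws give the cost-effectiveness-plane
quadrant probabilities and — through the net-monetary-benefit rule
NMB = lambda * dE - dC — the acceptability curve over willingness-to-pay
ceilings lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmData",
    "BootstrapDraws",
    "ICERResult",
    "CEACCurve",
    "icer_point",
    "bootstrap_pairs",
    "icer_summary",
    "ceac",
    "evaluate_contrast",
    "ContrastResult",
    "default_lambda_grid",
]

#: |dE| below this is treated as a zero effect difference for the point ICER.
EFFECT_EPS = 1e-12

CONTRASTS = {"CBT-WL": ("CBT", "WL"), "PST-WL": ("PST", "WL"),
             "PST-CBT": ("PST", "CBT")}


def default_lambda_grid(stop: float = 50_000.0,
                        step: float = 500.0) -> np.ndarray:
    """Willingness-to-pay grid 0..stop (EUR per effect unit)."""
    return np.arange(0.0, stop + step / 2, step)


@dataclass(frozen=True)
class ArmData:
    """Paired per-participant costs and effects for one arm."""

    costs: np.ndarray
    effects: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        e = np.asarray(self.effects, dtype=float)
        if c.shape != e.shape or c.ndim != 1:
            raise ValueError("costs and effects must be 1-d and aligned")
        if not (np.isfinite(c).all() and np.isfinite(e).all()):
            raise ValueError("costs and effects must be finite")
        object.__setattr__(self, "costs", c)
        object.__setattr__(self, "effects", e)

    @property
    def n(self) -> int:
        return len(self.costs)


@dataclass(frozen=True)
class BootstrapDraws:
    """B paired mean-difference replicates (dC, dE)."""

    dC: np.ndarray
    dE: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.dC) != len(self.dE) or len(self.dC) < 1:
            raise ValueError("need B >= 1 paired draws")
        if not (np.isfinite(self.dC).all() and np.isfinite(self.dE).all()):
            raise ValueError("draws must be finite")

    @property
    def B(self) -> int:
        return len(self.dC)


@dataclass(frozen=True)
class ICERResult:
    point_icer: float          # NaN when flagged undefined
    undefined: bool            # |dE| ~ 0 at the point estimate
    dC: float
    dE: float
    median_icer: float
    ci_lower: float
    ci_upper: float
    quadrants: dict = field(default_factory=dict)  # NE/SE/NW/SW -> prob
    n_zero_effect: int = 0     # draws with dE exactly 0 (reported separately)


@dataclass(frozen=True)
class CEACCurve:
    lambdas: np.ndarray
    probability: np.ndarray

    def at(self, lam: float) -> float:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.probability[i])


def icer_point(c1: float, e1: float, c0: float, e0: float,
               eps: float = EFFECT_EPS) -> tuple[float, bool]:
    """Point ICER from arm means; returns (value, undefined_flag).

    When the effect difference is numerically zero the ratio is flagged
    undefined (NaN) rather than raised — the incremental cost and effect
    are still meaningful and are reported alongside.
    """
    dC, dE = c1 - c0, e1 - e0
    if abs(dE) < eps:
        return float("nan"), True
    return dC / dE, False


def bootstrap_pairs(arm1: ArmData, arm0: ArmData, B: int = 5000,
                    seed: int | None = None) -> BootstrapDraws:
    """Within-arm participant-level bootstrap of mean differences.

    Each replicate resamples n1 participants from the intervention arm and
    n0 from the comparator, both with replacement, keeping each
    participant's (cost, effect) pair intact, and records the pair of
    mean differences. Reproducible for a given seed.
    """
    if arm1.n < 2 or arm0.n < 2:
        raise ValueError("bootstrap needs n >= 2 per arm")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx1 = rng.integers(0, arm1.n, size=(B, arm1.n))
    idx0 = rng.integers(0, arm0.n, size=(B, arm0.n))
    dC = arm1.costs[idx1].mean(axis=1) - arm0.costs[idx0].mean(axis=1)
    dE = arm1.effects[idx1].mean(axis=1) - arm0.effects[idx0].mean(axis=1)
    return BootstrapDraws(dC=dC, dE=dE, seed=seed)


def _quadrants(draws: BootstrapDraws) -> tuple[dict, int]:
    """CE-plane quadrant shares.

    Quadrants are named for the plane with dE on the horizontal axis and
    dC on the vertical: NE more effect at more cost, SE more effect at
    less cost (dominance), NW less effect at more cost (dominated), SW
    less effect at less cost. Boundary rule: draws with dE == 0 are
    assigned to the west side (NW/SW by the sign of dC) and counted
    separately in ``n_zero_effect``; dC == 0 counts as "not cheaper"
    (north). The four shares always sum to one.
    """
    e_pos = draws.dE > 0
    c_pos = draws.dC >= 0
    B = draws.B
    quads = {
        "NE": float(np.sum(e_pos & c_pos)) / B,
        "SE": float(np.sum(e_pos & ~c_pos)) / B,
        "NW": float(np.sum(~e_pos & c_pos)) / B,
        "SW": float(np.sum(~e_pos & ~c_pos)) / B,
    }
    return quads, int(np.sum(draws.dE == 0))


def icer_summary(draws: BootstrapDraws,
                 percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5),
                 min_B: int = 40) -> ICERResult:
    """Median and percentile CI of the replicate ICERs plus quadrants.

    Percentiles use the linear-interpolation (mid) rule, so the median of
    the ratios 1..100 is 50.5. The point ICER filled in here is the ratio
    of the mean replicate differences; :func:`evaluate_contrast` replaces
    it with the ratio of the observed sample means. Replicates with
    dE == 0 would make the ratio infinite; they are excluded from the
    percentile summary and reported in ``n_zero_effect``.
    """
    if draws.B < min_B:
        raise ValueError(f"need B >= {min_B} for a percentile CI "
                         f"(got {draws.B})")
    lo_p, mid_p, hi_p = percentiles
    nonzero = draws.dE != 0
    if nonzero.any():
        ratios = draws.dC[nonzero] / draws.dE[nonzero]
        lo, med, hi = np.percentile(ratios, [lo_p, mid_p, hi_p],
                                    method="linear")
    else:
        lo = med = hi = float("nan")
    quads, n_zero = _quadrants(draws)
    point, undefined = icer_point(float(draws.dC.mean()),
                                  float(draws.dE.mean()), 0.0, 0.0)
    return ICERResult(
        point_icer=point, undefined=undefined,
        dC=float(draws.dC.mean()), dE=float(draws.dE.mean()),
        median_icer=float(med), ci_lower=float(lo), ci_upper=float(hi),
        quadrants=quads, n_zero_effect=n_zero)


def ceac(draws: BootstrapDraws,
         lambda_grid: Sequence[float] | np.ndarray | None = None
         ) -> CEACCurve:
    """Cost-effectiveness acceptability curve via net monetary benefit.

    At each willingness-to-pay ceiling lambda the acceptability is the
    fraction of replicates with positive net monetary benefit
    lambda * dE - dC > 0 (ties count as not acceptable). Unlike an
    ICER-threshold rule, NMB orders draws correctly in all four
    quadrants. At lambda = 0 the curve equals P(dC < 0); as lambda grows
    it tends to P(dE > 0).
    """
    grid = (default_lambda_grid() if lambda_grid is None
            else np.asarray(lambda_grid, dtype=float))
    if (grid < 0).any() or (np.diff(grid) < 0).any():
        raise ValueError("lambda grid must be nonnegative and ascending")
    nmb = grid[:, None] * draws.dE[None, :] - draws.dC[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(lambdas=grid, probability=prob)


@dataclass(frozen=True)
class ContrastResult:
    """Full result bundle for one contrast and effect measure."""

    contrast: str
    effect_kind: str
    icer: ICERResult
    ceac: CEACCurve
    draws: BootstrapDraws


def evaluate_contrast(costs_effects: pd.DataFrame, contrast: str,
                      effect_kind: str = "qaly", B: int = 5000,
                      lambda_grid: Sequence[float] | None = None,
                      seed: int | None = None) -> ContrastResult:
    """Run the bootstrap chain for one arm contrast.

    ``costs_effects`` has one row per participant with columns ``arm``,
    ``total`` (12-week societal cost, EUR), ``qaly_total`` and
    ``clinically_significant``. ``contrast`` is one of ``CBT-WL``,
    ``PST-WL``, ``PST-CBT`` (intervention minus comparator).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of "
                         f"{sorted(CONTRASTS)}")
    effect_col = {"qaly": "qaly_total",
                  "rcsc": "clinically_significant"}.get(effect_kind)
    if effect_col is None:
        raise ValueError(f"unknown effect_kind {effect_kind!r}; "
                         "expected 'qaly' or 'rcsc'")
    a1, a0 = CONTRASTS[contrast]
    arms = {}
    for name in (a1, a0):
        sub = costs_effects[costs_effects["arm"] == name]
        if len(sub) == 0:
            raise ValueError(f"arm {name!r} absent from cohort")
        arms[name] = ArmData(costs=sub["total"].to_numpy(dtype=float),
                             effects=sub[effect_col].to_numpy(dtype=float))
    draws = bootstrap_pairs(arms[a1], arms[a0], B=B, seed=seed)
    summary = icer_summary(draws)
    point, undefined = icer_point(
        float(arms[a1].costs.mean()), float(arms[a1].effects.mean()),
        float(arms[a0].costs.mean()), float(arms[a0].effects.mean()))
    summary = ICERResult(
        point_icer=point, undefined=undefined,
        dC=float(arms[a1].costs.mean() - arms[a0].costs.mean()),
        dE=float(arms[a1].effects.mean() - arms[a0].effects.mean()),
        median_icer=summary.median_icer, ci_lower=summary.ci_lower,
        ci_upper=summary.ci_upper, quadrants=summary.quadrants,
        n_zero_effect=summary.n_zero_effect)
    curve = ceac(draws, lambda_grid)
    return ContrastResult(contrast=contrast, effect_kind=effect_kind,
                          icer=summary, ceac=curve, draws=draws)
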