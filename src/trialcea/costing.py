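"""Societal costing of health-service use and productivity losses.

Costs are valued from the societal perspective in 2007 Euros and split into
three categories:

* **direct medical** — intervention delivery, health-service contacts
  valued at standard unit cost prices, and psychotropic medication priced
  per standard daily dose per month;
* **direct nonmedical** — travel (0.17 EUR/km), parking (2.64 EUR per
  visit-hour) and patient time in travel, waiting and treatment
  (8.83 EUR/h);
* **indirect** — productivity losses under the friction-cost approach:
  work-loss days, work-cutback days (days worked while ill weighted by a
  0-1 self-rated inefficiency score) and lost domestic work replaced at
  8.83 EUR/h. Over a 12-week horizon friction and human-capital costing
  coincide.

Monetary amounts are handled in exact cents internally and rounded to whole
Euros only in report output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import reference

__all__ = [
    "ServiceCost",
    "UnitCostTable",
    "FrictionParams",
    "CostBreakdown",
    "direct_medical_cost",
    "direct_nonmedical_cost",
    "indirect_cost",
    "total_cost",
    "arm_cost_summary",
]


def _cents(x: float) -> float:
    """Round a Euro amount to exact cents (half away from zero)."""
    return round(round(x * 100) / 100, 2)


@dataclass(frozen=True)
class ServiceCost:
    """Unit-cost entry for one health-service type."""

    name: str
    unit: str
    unit_cost: float        # direct medical cost per unit, EUR
    km: float               # average travel distance per visit
    patient_hours: float    # travel + waiting + treatment time per visit
    nonmedical: float       # direct nonmedical cost per visit, EUR

    def __post_init__(self) -> None:
        for f in ("unit_cost", "km", "patient_hours", "nonmedical"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be >= 0")


def _nonmedical_per_visit(km: float, hours: float,
                          km_rate: float, parking_rate: float,
                          time_rate: float) -> float:
    """Direct nonmedical cost of one visit.

    Travel plus patient time, plus one parking-hour whenever any travel
    distance is involved. The parking surcharge reconstructs every printed
    per-visit nonmedical value to within five cents.
    """
    cost = km * km_rate + hours * time_rate
    if km > 0:
        cost += parking_rate
    return _cents(cost)


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs for all health services plus rate constants and prices."""

    services: Mapping[str, ServiceCost]
    km_rate: float = reference.KM_RATE
    parking_rate: float = reference.PARKING_RATE
    time_rate: float = reference.TIME_RATE
    intervention_cost: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.INTERVENTION_COST))
    medication_price: float = 11.0  # EUR per standard daily dose month

    @classmethod
    def default(cls) -> "UnitCostTable":
        """Unit-cost table holding the published 2007 Dutch cost prices."""
        services = {
            slug: ServiceCost(name, unit, cost, km, hours, nonmedical)
            for slug, (name, unit, cost, km, hours, nonmedical)
            in reference.UNIT_COSTS.items()
        }
        return cls(services=services)

    def service(self, slug: str) -> ServiceCost:
        try:
            return self.services[slug]
        except KeyError:
            known = ", ".join(sorted(self.services))
            raise KeyError(
                f"unknown service {slug!r}; known services: {known}"
            ) from None

    def nonmedical_per_visit(self, slug: str) -> float:
        s = self.service(slug)
        return _nonmedical_per_visit(s.km, s.patient_hours, self.km_rate,
                                     self.parking_rate, self.time_rate)

    def reconstruction_errors(self) -> dict[str, float]:
        """Computed-minus-printed nonmedical cost per visit, per service."""
        return {
            slug: self.nonmedical_per_visit(slug) - s.nonmedical
            for slug, s in self.services.items()
        }

    # ---- CSV round trip -------------------------------------------------
    CSV_COLUMNS = ("service", "unit", "unit_cost_eur", "km",
                   "patient_hours", "nonmedical_eur")

    def to_csv(self, path) -> None:
        rows = [
            {"service": slug, "unit": s.unit, "unit_cost_eur": s.unit_cost,
             "km": s.km, "patient_hours": s.patient_hours,
             "nonmedical_eur": s.nonmedical}
            for slug, s in self.services.items()
        ]
        pd.DataFrame(rows, columns=self.CSV_COLUMNS).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "UnitCostTable":
        df = pd.read_csv(path)
        missing = set(cls.CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"unit-cost CSV missing columns: {sorted(missing)}")
        services = {}
        for _, row in df.iterrows():
            slug = str(row["service"])
            canonical = reference.UNIT_COSTS.get(slug)
            services[slug] = ServiceCost(
                name=canonical[0] if canonical else slug,
                unit=str(row["unit"]),
                unit_cost=float(row["unit_cost_eur"]),
                km=float(row["km"]),
                patient_hours=float(row["patient_hours"]),
                nonmedical=float(row["nonmedical_eur"]),
            )
        return cls(services=services, **kwargs)


@dataclass(frozen=True)
class FrictionParams:
    """Friction-cost valuation of productivity losses.

    The published analysis used age- and gender-specific friction costs
    from the Dutch costing manual, which are not printed; a flat rate per
    lost work day is used here and is configurable.
    """

    day_rate: float = 115.0                      # EUR per work-loss day
    domestic_rate: float = reference.TIME_RATE   # EUR per domestic-help hour

    def __post_init__(self) -> None:
        if self.day_rate < 0 or self.domestic_rate < 0:
            raise ValueError("friction rates must be >= 0")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-participant costs (EUR) for one period, by category."""

    direct_medical: float
    direct_nonmedical: float
    indirect: float

    @property
    def total(self) -> float:
        return self.direct_medical + self.direct_nonmedical + self.indirect

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.direct_medical + other.direct_medical,
            self.direct_nonmedical + other.direct_nonmedical,
            self.indirect + other.indirect,
        )


def direct_medical_cost(use: Mapping[str, float], costs: UnitCostTable,
                        arm: str | None = None,
                        medication_months: float = 0.0) -> float:
    """Direct medical cost: services + medication (+ intervention).

    ``use`` maps service slug to unit count. The per-arm intervention cost
    is added only when ``arm`` is given; it is a once-per-trial constant
    and must be attached to the full 12-week aggregate, not to each period.
    """
    total = 0.0
    for slug, count in use.items():
        if count < 0:
            raise ValueError(f"negative use count for service {slug!r}")
        total += _cents(count * costs.service(slug).unit_cost)
    if medication_months < 0:
        raise ValueError("medication_months must be >= 0")
    total += _cents(medication_months * costs.medication_price)
    if arm is not None:
        try:
            total += costs.intervention_cost[arm]
        except KeyError:
            raise KeyError(f"unknown arm {arm!r}; expected one of "
                           f"{sorted(costs.intervention_cost)}") from None
    return _cents(total)


def direct_nonmedical_cost(use: Mapping[str, float],
                           costs: UnitCostTable) -> float:
    """Travel, parking and patient-time cost of the listed service use."""
    total = 0.0
    for slug, count in use.items():
        if count < 0:
            raise ValueError(f"negative use count for service {slug!r}")
        total += _cents(count * costs.nonmedical_per_visit(slug))
    return _cents(total)


def indirect_cost(work_loss_days: float, cutback_days: float,
                  inefficiency: float, domestic_hours: float,
                  friction: FrictionParams = FrictionParams()) -> float:
    """Friction-cost productivity losses for one period.

    ``cutback_days`` are days actually worked while ill; their cost is the
    day rate weighted by the self-rated inefficiency score in [0, 1].
    """
    if min(work_loss_days, cutback_days, domestic_hours) < 0:
        raise ValueError("days and hours must be >= 0")
    if not 0.0 <= inefficiency <= 1.0:
        raise ValueError("inefficiency score must lie in [0, 1]")
    return _cents(work_loss_days * friction.day_rate
                  + cutback_days * inefficiency * friction.day_rate
                  + domestic_hours * friction.domestic_rate)


def total_cost(periods: Iterable[CostBreakdown]) -> CostBreakdown:
    """Sum per-period breakdowns into a cumulative breakdown.

    Category-wise addition; the total is the sum of the three categories by
    construction.
    """
    acc = CostBreakdown(0.0, 0.0, 0.0)
    for p in periods:
        acc = acc + p
    return acc


def period_costs(cohort: pd.DataFrame, costs: UnitCostTable,
                 friction: FrictionParams = FrictionParams(),
                 periods: Iterable[str] = ("p1", "p2", "p3")) -> pd.DataFrame:
    """Per-participant per-period cost categories, tolerating missing data.

    Returns columns ``dm_<period>``, ``dnm_<period>``, ``ind_<period>``
    (EUR); any missing source cell makes the affected category NaN for that
    period, which downstream imputation then fills. Intervention costs are
    not included here (they are a known constant, added after imputation).
    """
    from . import schema

    out = pd.DataFrame({"id": cohort["id"], "arm": cohort["arm"]})
    for period in periods:
        dm = pd.Series(0.0, index=cohort.index)
        dnm = pd.Series(0.0, index=cohort.index)
        for slug in costs.services:
            col = schema.use_col(slug, period)
            if col not in cohort.columns:
                continue
            counts = cohort[col].astype(float)
            dm = dm + (counts * costs.service(slug).unit_cost).round(2)
            dnm = dnm + (counts * costs.nonmedical_per_visit(slug)).round(2)
        dm = dm + (cohort[schema.med_col(period)].astype(float)
                   * costs.medication_price).round(2)
        ineff = cohort[schema.inefficiency_col(period)].astype(float)
        bad = ineff.notna() & ((ineff < 0) | (ineff > 1))
        if bad.any():
            raise ValueError(f"inefficiency out of [0, 1] in period {period}")
        ind = (cohort[schema.workloss_col(period)].astype(float)
               * friction.day_rate
               + cohort[schema.cutback_col(period)].astype(float)
               * ineff * friction.day_rate
               + cohort[schema.domestic_col(period)].astype(float)
               * friction.domestic_rate).round(2)
        out[f"dm_{period}"] = dm.round(2)
        out[f"dnm_{period}"] = dnm.round(2)
        out[f"ind_{period}"] = ind
    return out


def participant_costs(cohort: pd.DataFrame, costs: UnitCostTable,
                      friction: FrictionParams = FrictionParams(),
                      periods: Iterable[str] = ("p1", "p2", "p3"),
                      include_intervention: bool = True) -> pd.DataFrame:
    """Per-participant cumulative cost breakdown over follow-up periods.

    Consumes a cohort table in the standard column layout; resource-use
    cells must be complete (run imputation first when the cohort has
    missing follow-up data).
    Returns one row per participant with ``arm``, ``direct_medical``,
    ``direct_nonmedical``, ``indirect`` and ``total`` in EUR. The per-arm
    intervention cost enters once, attached to the full follow-up horizon.
    """
    from . import schema

    out = pd.DataFrame({"id": cohort["id"], "arm": cohort["arm"]})
    dm = pd.Series(0.0, index=cohort.index)
    dnm = pd.Series(0.0, index=cohort.index)
    ind = pd.Series(0.0, index=cohort.index)
    for period in periods:
        for slug in costs.services:
            col = schema.use_col(slug, period)
            if col not in cohort.columns:
                continue
            counts = cohort[col].astype(float)
            dm += (counts * costs.service(slug).unit_cost).round(2)
            dnm += (counts * costs.nonmedical_per_visit(slug)).round(2)
        dm += (cohort[schema.med_col(period)].astype(float)
               * costs.medication_price).round(2)
        ineff = cohort[schema.inefficiency_col(period)].astype(float)
        if ((ineff < 0) | (ineff > 1)).any():
            raise ValueError(f"inefficiency out of [0, 1] in period {period}")
        ind += (cohort[schema.workloss_col(period)].astype(float)
                * friction.day_rate
                + cohort[schema.cutback_col(period)].astype(float)
                * ineff * friction.day_rate
                + cohort[schema.domestic_col(period)].astype(float)
                * friction.domestic_rate).round(2)
    if include_intervention:
        dm += cohort["arm"].map(costs.intervention_cost).astype(float)
    out["direct_medical"] = dm.round(2)
    out["direct_nonmedical"] = dnm.round(2)
    out["indirect"] = ind.round(2)
    out["total"] = (out["direct_medical"] + out["direct_nonmedical"]
                    + out["indirect"]).round(2)
    return out


def arm_cost_summary(costs_df: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean (sd) for each cost category plus pairwise differences.

    ``costs_df`` has one row per participant with columns ``arm``,
    ``direct_medical``, ``direct_nonmedical``, ``indirect``, ``total``
    (cumulative 12-week values). Output mirrors the published cost-table
    layout; ``summary.attrs["differences"]`` holds per-category mean
    contrasts (CBT-WL, PST-WL, PST-CBT) as a list of plain records.
    """
    categories = ["direct_medical", "direct_nonmedical", "indirect", "total"]
    arms = [a for a in reference.ARMS if a in set(costs_df["arm"])]
    if not arms:
        raise ValueError("no recognised arms in cost data")
    for arm in arms:
        if not len(costs_df[costs_df["arm"] == arm]):
            raise ValueError(f"empty arm {arm!r}")
    rows = []
    for arm in arms:
        sub = costs_df[costs_df["arm"] == arm]
        row: dict[str, float | str] = {"arm": arm, "n": len(sub)}
        for cat in categories:
            row[f"{cat}_mean"] = sub[cat].mean()
            row[f"{cat}_sd"] = sub[cat].std(ddof=1)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("arm")

    diffs = []
    pairs = {(a, b) for a in arms for b in arms if a != b}
    for a, b in [("CBT", "WL"), ("PST", "WL"), ("PST", "CBT")]:
        if (a, b) in pairs:
            entry: dict[str, float | str] = {"contrast": f"{a}-{b}"}
            for cat in categories:
                entry[cat] = float(summary.loc[a, f"{cat}_mean"]
                                   - summary.loc[b, f"{cat}_mean"])
            diffs.append(entry)
    summary.attrs["differences"] = diffs
    return summary
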