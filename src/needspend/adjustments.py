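"""Focal-practice adjustments and inflation, with an auditable ledger.

The comparison of a fast-growing digital-first practice against a regional
reference needs three bespoke corrections before its cost per weighted
patient is comparable:

1. *Site cohort removal* — members registered at a site outside the region
   covered by the spend extract are removed from the population (the spend
   total is deliberately untouched, because their hospital activity never
   entered it).
2. *Reference cohort removal* — a cohort that stayed with a traditional
   provider is removed by assigning it the reference area's average cost per
   patient and average need index, subtracting the implied spend, registered
   and weighted persons.
3. *Expected-cost correction* — published evidence that joiners used certain
   hospital services less than a matched population *before* joining is
   conservatively folded in by computing expected costs from attendance
   rates and unit costs twice (with and without the prior-use modifiers) and
   inflating the focal cost per weighted patient by the relative difference.

Costs from an earlier financial year are restated with a whole-economy GDP
deflator so both years are on the same price basis.

Every step is appended to an :class:`AdjustmentLedger` whose replay
reconstructs the final totals from the raw ones exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import DomainError, MissingDataError, SchemaError
from .population import AgeSexBand, PopulationProfile

# ---------------------------------------------------------------------------
# ledger


@dataclass(frozen=True)
class LedgerStep:
    name: str
    persons_removed: float
    spend_removed: float
    factor_applied: float  # multiplies the running cost figure; 1.0 = no-op
    registered_after: float
    spend_after: float
    weighted_after: float | None = None
    weighted_removed: float = 0.0

    def __post_init__(self) -> None:
        if self.persons_removed < 0 or self.spend_removed < 0:
            raise DomainError(f"ledger step {self.name}: negative removal")


@dataclass
class AdjustmentLedger:
    practice_id: str
    initial_registered: float
    initial_spend: float
    steps: list[LedgerStep] = field(default_factory=list)

    def append(self, step: LedgerStep) -> None:
        self.steps.append(step)

    def replay(self) -> tuple[float, float, float | None]:
        """Re-derive (registered, spend, weighted) from the raw totals by
        re-applying each step's arithmetic; raises if any step's recorded
        'after' values disagree."""
        registered, spend = self.initial_registered, self.initial_spend
        weighted: float | None = None
        for s in self.steps:
            registered -= s.persons_removed
            spend = (spend - s.spend_removed) * s.factor_applied
            if s.weighted_after is not None:
                if weighted is None:
                    # weighting happened outside the ledger; adopt its value
                    weighted = s.weighted_after
                else:
                    weighted -= s.weighted_removed
                    if not math.isclose(weighted, s.weighted_after, rel_tol=1e-12, abs_tol=1e-6):
                        raise DomainError(
                            f"ledger replay mismatch at {s.name}: weighted "
                            f"{weighted} != {s.weighted_after}"
                        )
            if not math.isclose(registered, s.registered_after, rel_tol=0, abs_tol=1e-6):
                raise DomainError(
                    f"ledger replay mismatch at {s.name}: registered "
                    f"{registered} != {s.registered_after}"
                )
            if not math.isclose(spend, s.spend_after, rel_tol=1e-12, abs_tol=1e-6):
                raise DomainError(
                    f"ledger replay mismatch at {s.name}: spend {spend} != {s.spend_after}"
                )
        return registered, spend, weighted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "practice_id": self.practice_id,
                    "step": s.name,
                    "persons_removed": s.persons_removed,
                    "weighted_removed": s.weighted_removed,
                    "spend_removed": s.spend_removed,
                    "factor_applied": s.factor_applied,
                    "registered_after": s.registered_after,
                    "weighted_after": s.weighted_after,
                    "spend_after": s.spend_after,
                }
                for s in self.steps
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort removals


def remove_site_cohort(
    profile: PopulationProfile,
    site_population: Mapping[AgeSexBand, float],
    spend: float,
    ledger: AdjustmentLedger | None = None,
) -> PopulationProfile:
    """Remove an out-of-region site's members from the averaged profile.

    The spend total is not adjusted: the extract never contained these
    members' hospital costs.
    """
    removed = float(sum(site_population.values()))
    new_profile = profile.minus(site_population)  # validates band-wise
    if ledger is not None:
        ledger.append(
            LedgerStep(
                name="site_cohort_removal",
                persons_removed=removed,
                spend_removed=0.0,
                factor_applied=1.0,
                registered_after=new_profile.total,
                spend_after=spend,
            )
        )
    return new_profile


def remove_reference_cohort(
    spend: float,
    registered: float,
    weighted: float,
    cohort_size: float,
    reference_cost_per_patient: float,
    reference_need_index: float,
    ledger: AdjustmentLedger | None = None,
) -> tuple[float, float, float]:
    """Remove a cohort priced at the reference area's averages.

    The cohort is assigned ``reference_cost_per_patient`` and
    ``reference_need_index``; spend, registered and weighted totals are
    reduced accordingly.  Returns the new ``(spend, registered, weighted)``.
    """
    if cohort_size < 0:
        raise DomainError("cohort size must be non-negative")
    if cohort_size >= registered and cohort_size > 0:
        raise DomainError(
            f"cohort size {cohort_size} not smaller than registered {registered}"
        )
    if cohort_size > 0 and (reference_cost_per_patient <= 0 or reference_need_index <= 0):
        raise DomainError("reference cost and need index must be positive")
    spend_removed = cohort_size * reference_cost_per_patient
    weighted_removed = cohort_size * reference_need_index
    new_spend = spend - spend_removed
    new_weighted = weighted - weighted_removed
    if new_spend < 0 or new_weighted < 0:
        raise DomainError(
            "reference cohort removal drives spend or weighted population "
            "below zero: inconsistent reference values"
        )
    new_registered = registered - cohort_size
    if ledger is not None:
        ledger.append(
            LedgerStep(
                name="reference_cohort_removal",
                persons_removed=cohort_size,
                weighted_removed=weighted_removed,
                spend_removed=spend_removed,
                factor_applied=1.0,
                registered_after=new_registered,
                spend_after=new_spend,
                weighted_after=new_weighted,
            )
        )
    return new_spend, new_registered, new_weighted


# ---------------------------------------------------------------------------
# expected-cost correction


class RateModifierTable:
    """Attendance rates, unit costs and prior-use modifiers keyed by
    (sex, age_band, service category).

    Delimited-text columns: sex, age_band, category, attendance_rate,
    unit_cost, modifier.
    """

    COLUMNS = ["sex", "age_band", "category", "attendance_rate", "unit_cost", "modifier"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"modifier table: missing columns {missing}")
        for col in ("attendance_rate", "unit_cost", "modifier"):
            vals = frame[col]
            bad = ~(vals > 0) | ~vals.map(math.isfinite)
            if bad.any():
                i = int(bad.idxmax())
                raise SchemaError(
                    f"modifier table: row {i} column {col}: entries must be "
                    f"positive and finite"
                )
        self.frame = frame.copy()
        self.frame["band"] = [
            AgeSexBand.parse(r.sex, r.age_band) for r in frame.itertuples()
        ]

    @classmethod
    def from_csv(cls, path) -> "RateModifierTable":
        return cls(pd.read_csv(path, dtype={"sex": str, "age_band": str, "category": str}))

    def to_csv(self, path) -> None:
        self.frame[self.COLUMNS].to_csv(path, index=False)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["category"].unique()))


def expected_cost_correction(
    profile: PopulationProfile, modifiers: RateModifierTable
) -> float:
    """Relative shortfall of modified vs baseline expected costs.

    ``expected_base = sum_(band,category) count x attendance_rate x unit_cost``;
    ``expected_modified`` repeats the sum with each attendance rate multiplied
    by its prior-use modifier.  The returned factor
    ``(expected_base - expected_modified) / expected_base`` is the fraction by
    which actual costs are expected to undershoot need-predicted costs; the
    focal cost per weighted patient is later multiplied by ``1 + factor``.
    """
    if profile.total <= 0:
        raise DomainError("expected-cost correction needs a non-empty population")
    base = 0.0
    modified = 0.0
    for r in modifiers.frame.itertuples():
        count = profile.counts.get(r.band, 0.0)
        cost = count * r.attendance_rate * r.unit_cost
        base += cost
        modified += cost * r.modifier
    if base <= 0:
        raise DomainError("expected base cost is non-positive")
    return (base - modified) / base


def apply_correction(
    cost_per_weighted_patient: float,
    factor: float,
    ledger: AdjustmentLedger | None = None,
) -> float:
    """Inflate a cost per weighted patient by the expected-cost correction."""
    if factor < -1:
        raise DomainError("correction factor below -1 would negate costs")
    corrected = cost_per_weighted_patient * (1.0 + factor)
    if ledger is not None:
        last_reg = ledger.steps[-1].registered_after if ledger.steps else ledger.initial_registered
        last_weighted = next(
            (s.weighted_after for s in reversed(ledger.steps) if s.weighted_after is not None),
            None,
        )
        last_spend = ledger.steps[-1].spend_after if ledger.steps else ledger.initial_spend
        ledger.append(
            LedgerStep(
                name="expected_cost_correction",
                persons_removed=0.0,
                spend_removed=0.0,
                factor_applied=1.0 + factor,
                registered_after=last_reg,
                spend_after=last_spend * (1.0 + factor),
                weighted_after=last_weighted,
            )
        )
    return corrected


# ---------------------------------------------------------------------------
# inflation


def apply_inflation(
    cost: float, deflator_source_year: float, deflator_target_year: float
) -> float:
    """Restate ``cost`` in target-year prices: cost x target / source."""
    if deflator_source_year <= 0 or deflator_target_year <= 0:
        raise DomainError("deflator index values must be positive")
    return cost * deflator_target_year / deflator_source_year


class Deflator:
    """A financial-year → price-index series (two-column delimited text)."""

    def __init__(self, series: Mapping[str, float]):
        for year, v in series.items():
            if not (v > 0 and math.isfinite(v)):
                raise SchemaError(f"deflator.{year}: index must be positive, got {v!r}")
        self.series = dict(series)

    @classmethod
    def from_csv(cls, path) -> "Deflator":
        df = pd.read_csv(path, dtype={"financial_year": str})
        for col in ("financial_year", "index"):
            if col not in df.columns:
                raise SchemaError(f"deflator file: missing column {col}")
        return cls(dict(zip(df["financial_year"], df["index"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"financial_year": list(self.series), "index": list(self.series.values())}
        ).to_csv(path, index=False)

    def index_for(self, year: str) -> float:
        try:
            return self.series[year]
        except KeyError:
            raise MissingDataError(f"deflator series has no entry for year {year!r}") from None

    def restate(self, cost: float, source_year: str, target_year: str) -> float:
        return apply_inflation(cost, self.index_for(source_year), self.index_for(target_year))
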