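"""Practice populations: age-sex banding, quarterly snapshots and the
averaged registered population.

Registered lists change within a financial year, so every downstream stage
works from the *average registered population*: the arithmetic mean, band by
band, of the list counts at the start of each quarter of the financial year
(April, July, October, January).  Fractional persons are carried at full
precision; rounding happens only in report formatting.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, MissingDataError, SchemaError

SEXES = ("female", "male")

# ---------------------------------------------------------------------------
# age-sex bands


@dataclass(frozen=True, order=True)
class AgeSexBand:
    """A closed age interval for one sex; ``upper=None`` means open-ended."""

    sex: str
    lower: int
    upper: int | None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"band sex must be one of {SEXES}, got {self.sex!r}")
        if self.lower < 0:
            raise SchemaError(f"band lower age must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise SchemaError(
                f"band upper age {self.upper} below lower age {self.lower}"
            )

    @property
    def age_label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    @property
    def label(self) -> str:
        """Combined key, e.g. ``'female 20-39'`` — used in coefficient files."""
        return f"{self.sex} {self.age_label}"

    @classmethod
    def parse(cls, sex: str, age_label: str) -> "AgeSexBand":
        age_label = age_label.strip()
        if age_label.endswith("+"):
            return cls(sex.strip().lower(), int(age_label[:-1]), None)
        lo, hi = age_label.split("-")
        return cls(sex.strip().lower(), int(lo), int(hi))

    @classmethod
    def parse_label(cls, label: str) -> "AgeSexBand":
        sex, age = label.strip().split()
        return cls.parse(sex, age)


def canonical_bands() -> tuple[AgeSexBand, ...]:
    """The 10-band default: 0-19, 20-39, 40-59, 60-79, 80+ per sex."""
    edges = [(0, 19), (20, 39), (40, 59), (60, 79), (80, None)]
    return tuple(
        AgeSexBand(sex, lo, hi) for sex in SEXES for lo, hi in edges
    )


def validate_banding(bands: Iterable[AgeSexBand]) -> None:
    """Check that for each sex the bands are disjoint and cover 0..open-ended."""
    by_sex: dict[str, list[AgeSexBand]] = {s: [] for s in SEXES}
    for b in bands:
        by_sex[b.sex].append(b)
    for sex, group in by_sex.items():
        if not group:
            raise SchemaError(f"banding: no bands for sex {sex!r}")
        group.sort(key=lambda b: b.lower)
        if group[0].lower != 0:
            raise SchemaError(f"banding[{sex}]: coverage must start at age 0")
        for prev, nxt in zip(group, group[1:]):
            if prev.upper is None:
                raise SchemaError(
                    f"banding[{sex}]: open-ended band {prev.age_label} is not last"
                )
            if prev.upper + 1 != nxt.lower:
                raise SchemaError(
                    f"banding[{sex}]: gap or overlap between {prev.age_label} "
                    f"and {nxt.age_label}"
                )
        if group[-1].upper is not None:
            raise SchemaError(f"banding[{sex}]: last band must be open-ended")


# ---------------------------------------------------------------------------
# financial years and quarters


def financial_year_of(date: dt.date) -> str:
    """NHS financial year label (April 1 – March 31), e.g. ``'2019/20'``."""
    start = date.year if date.month >= 4 else date.year - 1
    return f"{start}/{(start + 1) % 100:02d}"


def quarter_starts(year_label: str) -> tuple[dt.date, ...]:
    """The four quarter-start dates of a financial year: Apr/Jul/Oct/Jan."""
    start = int(year_label.split("/")[0])
    return (
        dt.date(start, 4, 1),
        dt.date(start, 7, 1),
        dt.date(start, 10, 1),
        dt.date(start + 1, 1, 1),
    )


# ---------------------------------------------------------------------------
# snapshots, records, profiles


@dataclass(frozen=True)
class QuarterlySnapshot:
    quarter_start: dt.date
    counts: Mapping[AgeSexBand, float]

    def __post_init__(self) -> None:
        for band, c in self.counts.items():
            if c < 0:
                raise DomainError(f"negative count {c} in band {band.label}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class PopulationProfile:
    """An averaged (possibly fractional) population by age-sex band."""

    counts: Mapping[AgeSexBand, float]

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def bands(self) -> tuple[AgeSexBand, ...]:
        return tuple(self.counts)

    def scaled(self, k: float) -> "PopulationProfile":
        return PopulationProfile({b: c * k for b, c in self.counts.items()})

    def minus(self, other: Mapping[AgeSexBand, float]) -> "PopulationProfile":
        new = dict(self.counts)
        for band, c in other.items():
            if c < 0:
                raise DomainError(f"cannot remove negative count from {band.label}")
            have = new.get(band, 0.0)
            if c > have + 1e-9:
                raise DomainError(
                    f"removal of {c} from band {band.label} exceeds count {have}"
                )
            new[band] = have - c
        return PopulationProfile(new)


@dataclass(frozen=True)
class PracticeRecord:
    """One practice in one financial year."""

    practice_id: str
    network_id: str
    area_id: str
    financial_year: str
    snapshots: Sequence[QuarterlySnapshot]
    total_spend: float
    deprivation_percentile: int | None = None

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise MissingDataError(
                f"practice {self.practice_id}: no population snapshots for "
                f"{self.financial_year}"
            )
        if self.total_spend < 0:
            raise DomainError(f"practice {self.practice_id}: negative total spend")
        for snap in self.snapshots:
            fy = financial_year_of(snap.quarter_start)
            if fy != self.financial_year:
                raise DomainError(
                    f"practice {self.practice_id}: snapshot dated "
                    f"{snap.quarter_start} lies outside financial year "
                    f"{self.financial_year}"
                )

    def averaged_profile(self) -> PopulationProfile:
        return average_registered_population(self.snapshots)


def average_registered_population(
    snapshots: Sequence[QuarterlySnapshot],
) -> PopulationProfile:
    """Band-wise arithmetic mean of the quarterly counts.

    Practices observed for fewer than four quarters (opened or closed
    mid-year) are averaged over the snapshots available.
    """
    if not snapshots:
        raise MissingDataError("no quarterly snapshots: population data missing")
    bands = sorted({b for s in snapshots for b in s.counts})
    n = len(snapshots)
    return PopulationProfile(
        {b: sum(s.counts.get(b, 0.0) for s in snapshots) / n for b in bands}
    )


def band_share(profile: PopulationProfile, band: AgeSexBand) -> float:
    """Percentage of the averaged population in one band."""
    total = profile.total
    if total <= 0:
        raise DomainError("band share undefined for zero total population")
    return 100.0 * profile.counts.get(band, 0.0) / total


# ---------------------------------------------------------------------------
# delimited-text interface
#
# One row per practice x quarter x band:
# practice_id, network_id, area_id, quarter_start, sex, age_band, count,
# deprivation_percentile

POPULATION_COLUMNS = [
    "practice_id",
    "network_id",
    "area_id",
    "quarter_start",
    "sex",
    "age_band",
    "count",
    "deprivation_percentile",
]

SPEND_COLUMNS = ["practice_id", "financial_year", "total_spend"]


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"practice_id": str, "network_id": str,
                                  "area_id": str, "sex": str, "age_band": str})
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"population file: missing columns {missing}")
    if (df["count"] < 0).any():
        raise SchemaError("population file: negative counts present")
    return df


def write_population(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=POPULATION_COLUMNS)


def read_spend(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"practice_id": str, "financial_year": str})
    missing = [c for c in SPEND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spend file: missing columns {missing}")
    return df


def write_spend(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SPEND_COLUMNS)


def build_practice_records(
    population: pd.DataFrame,
    spend: pd.DataFrame,
    financial_year: str,
) -> tuple[dict[str, PracticeRecord], float, list[str]]:
    """Assemble one PracticeRecord per practice for one financial year.

    Spend rows whose practice has no population rows in the year cannot be
    attributed to a patient population; they are excluded and their total is
    returned alongside the offending identifiers.
    """
    pop = population.copy()
    pop["quarter_start"] = pd.to_datetime(pop["quarter_start"]).dt.date
    pop["fy"] = [financial_year_of(d) for d in pop["quarter_start"]]
    pop = pop[pop["fy"] == financial_year]
    if pop.empty:
        raise MissingDataError(f"no population rows for financial year {financial_year}")

    sp = spend[spend["financial_year"] == financial_year]
    spend_by_practice = sp.groupby("practice_id")["total_spend"].sum()

    known = set(pop["practice_id"])
    orphan_ids = sorted(set(spend_by_practice.index) - known)
    excluded_spend = float(spend_by_practice.loc[orphan_ids].sum()) if orphan_ids else 0.0

    records: dict[str, PracticeRecord] = {}
    for pid, g in pop.groupby("practice_id", sort=True):
        snaps = []
        for q, gq in g.groupby("quarter_start", sort=True):
            counts = {
                AgeSexBand.parse(r.sex, r.age_band): float(r.count)
                for r in gq.itertuples()
            }
            snaps.append(QuarterlySnapshot(q, counts))
        dep = g["deprivation_percentile"].dropna()
        records[pid] = PracticeRecord(
            practice_id=pid,
            network_id=str(g["network_id"].iloc[0]),
            area_id=str(g["area_id"].iloc[0]),
            financial_year=financial_year,
            snapshots=snaps,
            total_spend=float(spend_by_practice.get(pid, 0.0)),
            deprivation_percentile=int(dep.iloc[0]) if len(dep) else None,
        )
    return records, excluded_spend, orphan_ids
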