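"""End-to-end orchestration: averaging → weighting → adjustments → cost per
weighted patient → normality screen → z comparison → percentile → savings.

`analyse_region` works on in-memory frames and coefficient tables (this is
what the experiments and tests drive); `run_pipeline` wraps it with file
input/output for the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import comparison as cmp
from .adjustments import (
    AdjustmentLedger,
    Deflator,
    RateModifierTable,
    apply_correction,
    expected_cost_correction,
    remove_reference_cohort,
    remove_site_cohort,
)
from .errors import DomainError, MissingDataError, SchemaError
from .population import (
    AgeSexBand,
    PopulationProfile,
    build_practice_records,
    read_population,
    read_spend,
)
from .weighting import CoefficientTable, weight_profile


@dataclass(frozen=True)
class ReferenceCohort:
    """A cohort removed from the focal practice at reference-area averages."""

    size: float
    cost_per_patient: float
    need_index: Mapping[str, float] | float  # per scheme, or one value


@dataclass
class YearResult:
    financial_year: str
    focal_practice_id: str
    excluded_spend: float
    excluded_practices: list[str]
    practice_tables: dict[str, pd.DataFrame]  # per scheme
    network_tables: dict[str, pd.DataFrame]
    results: dict[str, cmp.ComparisonResult]
    ledgers: dict[str, AdjustmentLedger]
    correction_factor: float
    inflation_factor: float


@dataclass
class ResultsBundle:
    years: list[YearResult]

    @property
    def results(self) -> list[cmp.ComparisonResult]:
        return [r for yr in self.years for r in yr.results.values()]

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scheme": r.scheme,
                    "financial_year": r.financial_year,
                    "focal_cost_pwp": r.focal_cost_pwp,
                    "reference_cost_pwp": r.reference_cost_pwp,
                    "abs_difference": r.abs_difference,
                    "pct_difference": r.pct_difference,
                    "z": r.z_statistic,
                    "p_one_sided": r.p_value,
                    "normality_passed": r.normality_passed,
                    "percentile": r.percentile,
                    "focal_weighted": r.focal_weighted,
                    "total_savings": r.total_savings,
                }
                for r in self.results
            ]
        )


def analyse_region(
    population: pd.DataFrame,
    spend: pd.DataFrame,
    tables: Mapping[str, CoefficientTable],
    *,
    focal_practice_id: str,
    financial_years: Sequence[str],
    schemes: Sequence[str] | None = None,
    alpha: float = 0.05,
    ddof: int = 1,
    deflator: Deflator | None = None,
    inflation_target_year: str | None = None,
    modifiers: RateModifierTable | None = None,
    correction: str | float | None = None,
    site_cohort: Mapping[str, Mapping[AgeSexBand, float]] | None = None,
    reference_cohort: Mapping[str, ReferenceCohort] | None = None,
    resident_mix: Mapping[str, float] | None = None,
    nursing_home_rates: Mapping[str, float] | None = None,
) -> ResultsBundle:
    """Run the full comparison for each scheme and financial year.

    ``correction`` selects the expected-cost correction mode: ``"recompute"``
    derives the factor from ``modifiers`` and the focal profile each year; a
    float pins the factor; ``None`` applies no correction.  ``site_cohort``
    and ``reference_cohort`` are keyed by financial year.  Costs of years
    other than ``inflation_target_year`` are restated with the deflator.
    """
    schemes = list(schemes) if schemes is not None else list(tables)
    for s in schemes:
        if s not in tables:
            raise SchemaError(f"no coefficient table supplied for scheme {s!r}")
    nh = dict(nursing_home_rates or {})
    years_out: list[YearResult] = []

    for year in financial_years:
        records, excluded_spend, orphans = build_practice_records(population, spend, year)
        if focal_practice_id not in records:
            raise MissingDataError(
                f"focal practice {focal_practice_id!r} absent from population in {year}"
            )
        focal_rec = records[focal_practice_id]
        profiles = {pid: rec.averaged_profile() for pid, rec in records.items()}

        # inflation restatement factor for this year's costs
        if deflator is not None and inflation_target_year is not None and year != inflation_target_year:
            inflation = deflator.restate(1.0, year, inflation_target_year)
        else:
            inflation = 1.0

        # focal bespoke adjustments: site cohort first (population only)
        focal_profile = profiles[focal_practice_id]
        base_ledger = AdjustmentLedger(
            practice_id=focal_practice_id,
            initial_registered=focal_profile.total,
            initial_spend=focal_rec.total_spend,
        )
        site = (site_cohort or {}).get(year)
        if site:
            focal_profile = remove_site_cohort(
                focal_profile, site, focal_rec.total_spend, base_ledger
            )

        # expected-cost correction factor (from the post-site-removal profile)
        if correction is None:
            corr_factor = 0.0
        elif correction == "recompute":
            if modifiers is None:
                raise SchemaError("correction='recompute' needs a modifier table")
            corr_factor = expected_cost_correction(focal_profile, modifiers)
        else:
            corr_factor = float(correction)

        practice_tables: dict[str, pd.DataFrame] = {}
        network_tables: dict[str, pd.DataFrame] = {}
        results: dict[str, cmp.ComparisonResult] = {}
        ledgers: dict[str, AdjustmentLedger] = {}

        for scheme in schemes:
            table = tables[scheme]
            rows = []
            for pid, rec in records.items():
                profile = focal_profile if pid == focal_practice_id else profiles[pid]
                mix = resident_mix if pid == focal_practice_id else None
                wp = weight_profile(
                    profile,
                    table,
                    area_id=rec.area_id,
                    resident_area_mix=mix,
                    nursing_home_rate=nh.get(pid, 0.0),
                    practice_id=pid,
                )
                rows.append(
                    {
                        "practice_id": pid,
                        "network_id": rec.network_id,
                        "registered": profile.total,
                        "weighted": wp.weighted,
                        "spend": rec.total_spend * inflation,
                        "need_index": wp.need_index,
                    }
                )
            ptable = pd.DataFrame(rows)

            # scheme-specific ledger continues from the shared base steps
            ledger = AdjustmentLedger(
                practice_id=focal_practice_id,
                initial_registered=base_ledger.initial_registered,
                initial_spend=base_ledger.initial_spend,
                steps=list(base_ledger.steps),
            )
            focal_row = ptable[ptable["practice_id"] == focal_practice_id].iloc[0]
            f_spend = float(focal_row["spend"])
            f_registered = float(focal_row["registered"])
            f_weighted = float(focal_row["weighted"])

            rc = (reference_cohort or {}).get(year)
            if rc is not None and rc.size > 0:
                ni = (
                    rc.need_index.get(scheme)
                    if isinstance(rc.need_index, Mapping)
                    else float(rc.need_index)
                )
                if ni is None:
                    raise SchemaError(
                        f"reference cohort need_index missing for scheme {scheme!r}"
                    )
                f_spend, f_registered, f_weighted = remove_reference_cohort(
                    f_spend,
                    f_registered,
                    f_weighted,
                    rc.size,
                    rc.cost_per_patient * inflation,
                    ni,
                    ledger,
                )
                idx = ptable.index[ptable["practice_id"] == focal_practice_id][0]
                ptable.loc[idx, ["spend", "registered", "weighted"]] = (
                    f_spend, f_registered, f_weighted,
                )
                ptable.loc[idx, "need_index"] = f_weighted / f_registered

            # per-practice ratios for the percentile rank (focal corrected)
            ptable["cost_pwp"] = ptable["spend"] / ptable["weighted"]
            focal_cost = cmp.cost_per_weighted_patient(f_spend, f_weighted)
            if correction is None:
                focal_cost_corr = focal_cost
            else:
                focal_cost_corr = apply_correction(focal_cost, corr_factor, ledger)
            idx = ptable.index[ptable["practice_id"] == focal_practice_id][0]
            ptable.loc[idx, "cost_pwp"] = focal_cost_corr

            reference_networks = cmp.aggregate_to_network(
                ptable[ptable["practice_id"] != focal_practice_id]
            )
            result = cmp.compare(
                scheme=scheme,
                financial_year=year,
                focal_spend=f_spend,
                focal_weighted=f_weighted,
                reference_networks=reference_networks,
                practice_costs_pwp=ptable["cost_pwp"].tolist(),
                alpha=alpha,
                correction_factor=corr_factor,
                ddof=ddof,
            )
            practice_tables[scheme] = ptable
            network_tables[scheme] = reference_networks
            results[scheme] = result
            ledgers[scheme] = ledger

        years_out.append(
            YearResult(
                financial_year=year,
                focal_practice_id=focal_practice_id,
                excluded_spend=excluded_spend,
                excluded_practices=orphans,
                practice_tables=practice_tables,
                network_tables=network_tables,
                results=results,
                ledgers=ledgers,
                correction_factor=corr_factor,
                inflation_factor=inflation,
            )
        )
    return ResultsBundle(years=years_out)


# ---------------------------------------------------------------------------
# file-driven runner


@dataclass
class RunConfig:
    population_path: str
    spend_path: str
    coefficient_paths: Mapping[str, str]  # scheme -> yaml path
    focal_practice_id: str
    financial_years: tuple[str, ...]
    schemes: tuple[str, ...] | None = None
    alpha: float = 0.05
    ddof: int = 1
    deflator_path: str | None = None
    inflation_target_year: str | None = None
    modifier_path: str | None = None
    correction: str | float | None = None  # "recompute" | pinned float | None
    resident_mix_path: str | None = None
    nursing_home_rates_path: str | None = None
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            raw["financial_years"] = tuple(raw["financial_years"])
            if raw.get("schemes") is not None:
                raw["schemes"] = tuple(raw["schemes"])
            return cls(**raw)
        except (KeyError, TypeError) as e:
            raise SchemaError(f"run config: {e}") from None


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Load all inputs, run :func:`analyse_region` and write the results
    bundle (full-precision machine-readable file, formatted tables, ledgers
    and every intermediate table) under ``config.output_dir``."""
    from . import reporting  # local import to avoid a cycle

    population = read_population(config.population_path)
    spend = read_spend(config.spend_path)
    tables = {
        scheme: CoefficientTable.from_yaml(path)
        for scheme, path in config.coefficient_paths.items()
    }
    deflator = Deflator.from_csv(config.deflator_path) if config.deflator_path else None
    modifiers = (
        RateModifierTable.from_csv(config.modifier_path) if config.modifier_path else None
    )
    resident_mix = None
    if config.resident_mix_path:
        mix_df = pd.read_csv(config.resident_mix_path, dtype={"area_id": str})
        resident_mix = dict(zip(mix_df["area_id"], mix_df["fraction"].astype(float)))
    nh_rates = None
    if config.nursing_home_rates_path:
        nh_df = pd.read_csv(config.nursing_home_rates_path, dtype={"practice_id": str})
        nh_rates = dict(zip(nh_df["practice_id"], nh_df["nursing_home_rate"].astype(float)))

    bundle = analyse_region(
        population,
        spend,
        tables,
        focal_practice_id=config.focal_practice_id,
        financial_years=config.financial_years,
        schemes=config.schemes,
        alpha=config.alpha,
        ddof=config.ddof,
        deflator=deflator,
        inflation_target_year=config.inflation_target_year,
        modifiers=modifiers,
        correction=config.correction,
        resident_mix=resident_mix,
        nursing_home_rates=nh_rates,
    )
    reporting.write_bundle(bundle, config.output_dir)
    return bundle
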