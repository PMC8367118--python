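"""Recomputation of the published worked arithmetic.

A published study of a large digital-first NHS practice reports, at printed
precision, every intermediate of the flow this package implements: the
out-of-region site subtraction, the traditional-care cohort removal, the
unattributable-spend exclusion, the population age-band shares, the
cost-per-weighted-patient differences, the implied total savings, and the
net-savings-after-primary-care arithmetic.  Those printed values are
self-contained inputs; this module feeds them back through the package
operations and checks that each derived figure reappears exactly as
printed.  (The study's z-test p-values and percentile ranks depend on its
underlying FOI distribution, which is not public, and are therefore not
recomputable.)

All monetary values are GBP; population figures are persons.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .adjustments import remove_reference_cohort, remove_site_cohort
from .comparison import (
    net_savings_after_primary_care,
    percent_difference,
    total_savings,
)
from .population import AgeSexBand, PopulationProfile, band_share
from .reporting import round_half_up

# ---------------------------------------------------------------------------
# published inputs (printed precision)

FY1920_REGISTERED_WITH_SITE = 61_273   # focal list before out-of-region site removal
FY1920_SITE_COHORT = 686               # members of the out-of-region site
FY1920_REGISTERED = 60_587             # printed remainder

FY1920_TRADITIONAL_COHORT = 2_696      # members kept with the traditional provider
FY1920_TRADITIONAL_SPEND = 1.51e6      # spend assigned to that cohort (printed)
FY1920_FOCAL_SPEND_AFTER = 15.9e6      # focal spend after cohort removal (printed)

REGION_SPEND_TOTAL = {"2018/19": 1.64e9, "2019/20": 1.69e9}
REGION_SPEND_EXCLUDED = {"2018/19": 44.6e6, "2019/20": 43.4e6}

# focal practice population by band, final-year column of the published
# sociodemographic table (n = 60,587)
FY1920_FOCAL_BAND_COUNTS = {
    "female 0-19": 987,
    "female 20-39": 24_040,
    "female 40-59": 1_881,
    "female 60-79": 244,
    "female 80+": 39,
    "male 0-19": 814,
    "male 20-39": 27_757,
    "male 40-59": 4_436,
    "male 60-79": 361,
    "male 80+": 29,
}

WORKING_AGE_FOCAL = (58_113, 60_587)     # ages 20-59, printed ratio
WORKING_AGE_REGION = (1_551_717, 2_478_709)

# cost per weighted patient (focal, reference), printed whole pounds, for
# the rows whose printed inputs and outputs are mutually consistent under
# rounding
COST_PWP_ROWS = {
    ("core_services", "2018/19"): (492, 715),
    ("core_services", "2019/20"): (468, 714),
    ("core_services_adapted", "2019/20"): (635, 749),
}

FY1920_CORE_NEED_INDEX = 0.67          # focal need index, core scheme
FY1920_CORE_DIFFERENCE = 246           # per-weighted-patient difference (magnitude)

EXTRA_APPOINTMENT_FRACTION = 0.23      # focal extra appointments per weighted patient
FUNDING_PER_PATIENT = 155              # average primary-care funding per patient
FY1920_DIFF_RANGE = (114, 362)         # smallest / largest printed FY19/20 difference


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    published: float

    @property
    def matches(self) -> bool:
        return self.computed == self.published


def _site_removal_check() -> Check:
    band = AgeSexBand("male", 0, None)  # totals only: one all-ages band
    profile = PopulationProfile({band: float(FY1920_REGISTERED_WITH_SITE)})
    removed = remove_site_cohort(profile, {band: float(FY1920_SITE_COHORT)}, spend=0.0)
    return Check("registered_after_site_removal", removed.total, FY1920_REGISTERED)


def _cohort_removal_check() -> Check:
    spend_before = FY1920_FOCAL_SPEND_AFTER + FY1920_TRADITIONAL_SPEND
    cost_per_patient = FY1920_TRADITIONAL_SPEND / FY1920_TRADITIONAL_COHORT
    spend_after, _, _ = remove_reference_cohort(
        spend=spend_before,
        registered=float(FY1920_REGISTERED),
        weighted=FY1920_REGISTERED * FY1920_CORE_NEED_INDEX,
        cohort_size=FY1920_TRADITIONAL_COHORT,
        reference_cost_per_patient=cost_per_patient,
        reference_need_index=0.93,
    )
    return Check(
        "focal_spend_after_cohort_removal_million",
        round_half_up(spend_after / 1e6, 1),
        FY1920_FOCAL_SPEND_AFTER / 1e6,
    )


def _exclusion_checks() -> list[Check]:
    out = []
    for year, digits, published in (("2018/19", 1, 1.6), ("2019/20", 2, 1.65)):
        remainder = REGION_SPEND_TOTAL[year] - REGION_SPEND_EXCLUDED[year]
        out.append(
            Check(
                f"attributable_spend_billion_{year.replace('/', '')}",
                round_half_up(remainder / 1e9, digits),
                published,
            )
        )
    return out


def _share_checks() -> list[Check]:
    profile = PopulationProfile(
        {AgeSexBand.parse_label(k): float(v) for k, v in FY1920_FOCAL_BAND_COUNTS.items()}
    )
    f2039 = AgeSexBand.parse_label("female 20-39")
    checks = [
        Check(
            "female_20_39_share_pct",
            round_half_up(band_share(profile, f2039), 2),
            39.68,
        )
    ]
    for name, (num, den), published in (
        ("focal_working_age_share_pct", WORKING_AGE_FOCAL, 95.9),
        ("region_working_age_share_pct", WORKING_AGE_REGION, 62.6),
    ):
        band = AgeSexBand("female", 20, 59)
        other = AgeSexBand("male", 20, 59)
        p = PopulationProfile({band: float(num), other: float(den - num)})
        checks.append(Check(name, round_half_up(band_share(p, band), 1), published))
    return checks


def _cost_difference_checks() -> list[Check]:
    published = {
        ("core_services", "2018/19"): (-223, -31.2),
        ("core_services", "2019/20"): (-246, -34.5),
        ("core_services_adapted", "2019/20"): (-114, -15.2),
    }
    checks = []
    for key, (focal, ref) in COST_PWP_ROWS.items():
        scheme, year = key
        tag = f"{scheme}_{year.replace('/', '')}"
        pub_abs, pub_pct = published[key]
        checks.append(Check(f"abs_difference_{tag}", float(focal - ref), pub_abs))
        checks.append(
            Check(
                f"pct_difference_{tag}",
                round_half_up(percent_difference(focal, ref), 1),
                pub_pct,
            )
        )
    return checks


def _savings_checks() -> list[Check]:
    focal_weighted = (FY1920_REGISTERED - FY1920_TRADITIONAL_COHORT) * FY1920_CORE_NEED_INDEX
    saving = total_savings(focal_weighted, FY1920_CORE_DIFFERENCE)
    checks = [
        Check(
            "total_savings_core_19_20_million",
            round_half_up(saving / 1e6, 2),
            9.54,
        )
    ]
    lo, hi = FY1920_DIFF_RANGE
    extra = hi - net_savings_after_primary_care(
        hi, EXTRA_APPOINTMENT_FRACTION, FUNDING_PER_PATIENT
    )
    checks.append(Check("extra_primary_care_cost_pwp", extra, 36))
    checks.append(
        Check(
            "net_savings_upper_pwp",
            net_savings_after_primary_care(hi, EXTRA_APPOINTMENT_FRACTION, FUNDING_PER_PATIENT),
            326,
        )
    )
    checks.append(
        Check(
            "net_savings_lower_pwp",
            net_savings_after_primary_care(lo, EXTRA_APPOINTMENT_FRACTION, FUNDING_PER_PATIENT),
            78,
        )
    )
    return checks


def all_checks() -> list[Check]:
    """Every published-arithmetic regression check, recomputed on call."""
    checks = [_site_removal_check(), _cohort_removal_check()]
    checks += _exclusion_checks()
    checks += _share_checks()
    checks += _cost_difference_checks()
    checks += _savings_checks()
    return checks


def worked_example_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quantity": c.name,
                "computed": c.computed,
                "published": c.published,
                "matches": c.matches,
            }
            for c in all_checks()
        ]
    )
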