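"""Cost per weighted patient, network aggregation and the statistical
comparison of one focal entity against a reference distribution.

The comparison metric is total spend divided by weighted population.  The
focal practice (or its network) is compared to the distribution of the
reference networks with a one-sided simple z test — the alternative being
that the focal cost per weighted patient is *lower* — after a normality
screen (Shapiro-Wilk plus Kolmogorov-Smirnov) on the reference sample.
Practice-level distributions are typically heavy-tailed, so the z test is
reserved for aggregation levels that pass the screen; at practice level a
percentile rank is reported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError


@dataclass(frozen=True)
class ComparisonResult:
    """Per-scheme, per-year comparison of the focal entity to the reference."""

    scheme: str
    financial_year: str
    focal_cost_pwp: float
    reference_cost_pwp: float
    abs_difference: float       # focal - reference; negative when focal lower
    pct_difference: float       # 100 * abs_difference / reference
    z_statistic: float | None
    p_value: float | None
    normality_passed: bool
    percentile: int
    focal_weighted: float
    total_savings: float        # focal_weighted * (reference - focal); >0 = saving


def cost_per_weighted_patient(total_spend: float, weighted: float) -> float:
    """Total spend divided by weighted population (GBP per weighted patient)."""
    if weighted <= 0:
        raise DomainError("cost per weighted patient needs weighted > 0")
    if total_spend < 0:
        raise DomainError("negative total spend")
    return total_spend / weighted


def aggregate_to_network(
    practice_table: pd.DataFrame, network_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Sum spend and weighted persons within networks, then divide.

    ``practice_table`` needs columns practice_id, spend, weighted,
    registered and (unless ``network_map`` is given) network_id.  The
    network ratio is the ratio of sums, not the mean of practice ratios.
    """
    df = practice_table.copy()
    if network_map is not None:
        unknown = [p for p in df["practice_id"] if p not in network_map]
        if unknown:
            raise DomainError(f"practices with unknown network: {unknown}")
        df["network_id"] = [network_map[p] for p in df["practice_id"]]
    elif "network_id" not in df.columns:
        raise DomainError("no network_id column and no network map supplied")
    agg = (
        df.groupby("network_id")
        .agg(
            spend=("spend", "sum"),
            weighted=("weighted", "sum"),
            registered=("registered", "sum"),
            n_practices=("practice_id", "count"),
        )
        .reset_index()
    )
    agg["cost_pwp"] = agg["spend"] / agg["weighted"]
    return agg


def percent_difference(focal: float, reference: float) -> float:
    """100 x (focal - reference) / reference; negative when focal is lower."""
    if reference <= 0:
        raise DomainError("reference cost per weighted patient must be positive")
    return 100.0 * (focal - reference) / reference


def one_sided_z(
    focal_value: float, reference_sample: Sequence[float], ddof: int = 1
) -> tuple[float, float]:
    """One-sided simple z test of the focal value against the reference
    distribution (alternative: focal lower).

    z = (focal - mean) / sd with the n-1 denominator by default
    (``ddof=0`` switches to the n denominator); p is the standard-normal
    lower-tail probability.
    """
    sample = np.asarray(reference_sample, dtype=float)
    if sample.size < 3:
        raise DomainError("reference sample must have at least 3 values")
    sd = float(sample.std(ddof=ddof))
    if sd <= 0:
        raise DomainError("zero variance in reference sample")
    z = (focal_value - float(sample.mean())) / sd
    p = float(stats.norm.cdf(z))
    return z, p


@dataclass(frozen=True)
class NormalityScreen:
    shapiro_statistic: float
    shapiro_p: float
    ks_statistic: float
    ks_p: float
    alpha: float
    passed: bool


def normality_screen(sample: Sequence[float], alpha: float = 0.05) -> NormalityScreen:
    """Shapiro-Wilk and Kolmogorov-Smirnov screen at level ``alpha``.

    The KS test is run against a normal with the sample's own mean and
    standard deviation.  The screen passes only if neither test rejects;
    the z comparison is reported only at levels that pass.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DomainError("normality screen needs at least 3 values")
    sd = float(x.std(ddof=1))
    if sd <= 0:
        raise DomainError("normality screen undefined for constant sample")
    sw_stat, sw_p = stats.shapiro(x)
    ks_stat, ks_p = stats.kstest(x, "norm", args=(float(x.mean()), sd))
    passed = (sw_p > alpha) and (ks_p > alpha)
    return NormalityScreen(
        float(sw_stat), float(sw_p), float(ks_stat), float(ks_p), alpha, passed
    )


def percentile_rank(focal_value: float, all_values: Sequence[float]) -> int:
    """Percentile rank (1-100) of the focal among all comparison values.

    1st percentile = lowest cost per weighted patient.  Ties count as <=
    (focal included), and the rank is ceil(100 * count / (n + 1)) clamped
    to [1, 100].
    """
    values = np.asarray(all_values, dtype=float)
    if values.size == 0:
        raise DomainError("percentile rank needs at least one comparison value")
    count = int((values <= focal_value).sum())
    rank = math.ceil(100.0 * count / (values.size + 1))
    return min(100, max(1, rank))


def total_savings(focal_weighted: float, abs_difference: float) -> float:
    """Total spending difference implied for the focal population:
    weighted persons times the per-weighted-patient difference."""
    if focal_weighted <= 0:
        raise DomainError("focal weighted population must be positive")
    return focal_weighted * abs_difference


def net_savings_after_primary_care(
    abs_difference: float,
    extra_appointment_fraction: float,
    funding_per_patient: float,
) -> float:
    """Per-weighted-patient saving net of extra primary-care provision.

    If the focal practice delivers a fraction more appointments per weighted
    patient than average, and primary-care costs grow linearly with
    appointments at ``funding_per_patient``, the extra cost is
    round(fraction x funding) pounds; the net saving is the gross
    per-weighted-patient difference minus that.
    """
    if extra_appointment_fraction < 0 or funding_per_patient < 0:
        raise DomainError("inputs must be non-negative")
    extra_cost = round(extra_appointment_fraction * funding_per_patient)
    return abs_difference - extra_cost


def compare(
    *,
    scheme: str,
    financial_year: str,
    focal_spend: float,
    focal_weighted: float,
    reference_networks: pd.DataFrame,
    practice_costs_pwp: Sequence[float],
    alpha: float = 0.05,
    correction_factor: float = 0.0,
    ddof: int = 1,
) -> ComparisonResult:
    """Assemble a full :class:`ComparisonResult`.

    ``reference_networks`` is the output of :func:`aggregate_to_network` for
    the reference networks only (focal network excluded);
    ``practice_costs_pwp`` are the per-practice ratios (focal included)
    used for the percentile rank.  ``correction_factor`` is the
    expected-cost correction applied to the focal ratio.
    """
    focal_cost = cost_per_weighted_patient(focal_spend, focal_weighted)
    focal_cost *= 1.0 + correction_factor
    reference_cost = cost_per_weighted_patient(
        float(reference_networks["spend"].sum()),
        float(reference_networks["weighted"].sum()),
    )
    diff = focal_cost - reference_cost
    sample = np.asarray(reference_networks["cost_pwp"], dtype=float)
    if sample.std(ddof=1) <= 0:
        # degenerate reference distribution (possible in noise-free
        # synthetic limits): no z comparison is reportable
        screen_passed = False
        z, p = None, None
    else:
        screen = normality_screen(sample, alpha=alpha)
        screen_passed = screen.passed
        if screen.passed:
            z, p = one_sided_z(focal_cost, sample, ddof=ddof)
        else:
            z, p = None, None
    return ComparisonResult(
        scheme=scheme,
        financial_year=financial_year,
        focal_cost_pwp=focal_cost,
        reference_cost_pwp=reference_cost,
        abs_difference=diff,
        pct_difference=percent_difference(focal_cost, reference_cost),
        z_statistic=z,
        p_value=p,
        normality_passed=screen_passed,
        percentile=percentile_rank(focal_cost, practice_costs_pwp),
        focal_weighted=focal_weighted,
        total_savings=focal_weighted * (reference_cost - focal_cost),
    )
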