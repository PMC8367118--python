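"""Report formatting and the results bundle writer.

Formatting conventions: per-patient costs in whole pounds; totals in
millions to 3 significant figures; percentages to 1 decimal place (2 in the
population-shares table); half-up rounding throughout.  Full-precision
values are always written alongside the formatted tables in a
machine-readable YAML file, and the two agree after applying these rules.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from .population import PopulationProfile, band_share


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pounds(x: float) -> str:
    return f"£{round_half_up(x):,.0f}"


def fmt_millions(x: float) -> str:
    m = x / 1e6
    if m == 0:
        return "£0.00M"
    d = Decimal(repr(m))
    exp = d.adjusted()  # 3 significant figures
    q = d.quantize(Decimal(1).scaleb(exp - 2), rounding=ROUND_HALF_UP)
    return f"£{q}M"


def fmt_pct(x: float, ndigits: int = 1) -> str:
    return f"{round_half_up(x, ndigits):.{ndigits}f}%"


def population_share_table(profile: PopulationProfile) -> pd.DataFrame:
    """Band counts and percentage shares (2 dp) of an averaged profile."""
    rows = [
        {
            "band": b.label,
            "count": profile.counts[b],
            "share_pct": round_half_up(band_share(profile, b), 2),
        }
        for b in sorted(profile.counts)
    ]
    return pd.DataFrame(rows)


def comparison_table(bundle) -> pd.DataFrame:
    """Cost-per-weighted-patient comparison, one row per scheme and year."""
    rows = []
    for r in bundle.results:
        rows.append(
            {
                "scheme": r.scheme,
                "financial_year": r.financial_year,
                "focal_cost_pwp": fmt_pounds(r.focal_cost_pwp),
                "reference_cost_pwp": fmt_pounds(r.reference_cost_pwp),
                "difference": fmt_pounds(r.abs_difference),
                "difference_pct": fmt_pct(r.pct_difference),
                "p_one_sided": "n/a (screen failed)"
                if r.p_value is None
                else f"{r.p_value:.3g}",
                "percentile": r.percentile,
                "total_savings": fmt_millions(r.total_savings),
            }
        )
    return pd.DataFrame(rows)


def need_index_table(bundle) -> pd.DataFrame:
    """Focal vs reference need index per scheme and year (2 dp)."""
    rows = []
    for yr in bundle.years:
        for scheme, ptable in yr.practice_tables.items():
            is_focal = ptable["practice_id"] == yr.focal_practice_id
            ref = ptable[~is_focal]
            ref_ni = ref["weighted"].sum() / ref["registered"].sum()
            focal_row = ptable[is_focal].iloc[0]
            focal_ni = focal_row["weighted"] / focal_row["registered"]
            rows.append(
                {
                    "scheme": scheme,
                    "financial_year": yr.financial_year,
                    "focal_need_index": round_half_up(focal_ni, 2),
                    "reference_need_index": round_half_up(ref_ni, 2),
                    "difference": round_half_up(ref_ni - focal_ni, 2),
                    "difference_pct": round_half_up(100 * (ref_ni - focal_ni) / ref_ni, 1),
                }
            )
    return pd.DataFrame(rows)


def write_bundle(bundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    full = bundle.results_frame()
    full.to_csv(out / "results_full_precision.csv", index=False)

    cmp_table = comparison_table(bundle)
    ni_table = need_index_table(bundle)
    cmp_table.to_csv(out / "comparison_table.csv", index=False)
    ni_table.to_csv(out / "need_index_table.csv", index=False)

    machine = {
        "results": full.to_dict(orient="records"),
        "years": [
            {
                "financial_year": yr.financial_year,
                "excluded_spend": float(yr.excluded_spend),
                "excluded_practices": list(yr.excluded_practices),
                "correction_factor": float(yr.correction_factor),
                "inflation_factor": float(yr.inflation_factor),
            }
            for yr in bundle.years
        ],
    }
    with open(out / "results.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(machine, fh, sort_keys=False)

    lines = [
        "Cost per weighted patient comparison",
        "====================================",
        cmp_table.to_string(index=False),
        "",
        "Need indices",
        "============",
        ni_table.to_string(index=False),
        "",
    ]
    for yr in bundle.years:
        lines.append(
            f"{yr.financial_year}: excluded unattributable spend "
            f"{fmt_millions(yr.excluded_spend)} "
            f"({len(yr.excluded_practices)} source(s)); "
            f"correction factor {yr.correction_factor:.4f}; "
            f"inflation factor {yr.inflation_factor:.4f}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    for yr in bundle.years:
        tag = yr.financial_year.replace("/", "-")
        for scheme, ptable in yr.practice_tables.items():
            ptable.to_csv(out / f"practice_{scheme}_{tag}.csv", index=False)
        for scheme, ntable in yr.network_tables.items():
            ntable.to_csv(out / f"network_{scheme}_{tag}.csv", index=False)
        for scheme, ledger in yr.ledgers.items():
            ledger.to_csv(out / f"ledger_{scheme}_{tag}.csv")
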