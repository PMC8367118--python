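"""Synthetic region generator with known ground truth.

No practice-level spend extract of the kind this pipeline analyses is
publicly deposited (such extracts arrive via freedom-of-information
requests), so the generator emulates one: a commissioning region of ~350
practices grouped into ~48 networks of roughly 50,000 patients, each
practice with quarterly age-sex band counts, a deprivation percentile, a
home area and an annual acute spend total — plus one large, fast-growing
focal practice whose membership is concentrated in ages 20-39 and whose
underlying spend rate is set by ``true_spend_multiplier``.

Ground truth construction: a practice's expected spend is its weighted
population under the *generating* coefficient tables times a base cost per
need unit; multiplicative gamma noise with shape proportional to the
weighted population keeps spends positive and right-skewed at practice
level while network aggregates are near-normal (practice spends are then
sums of iid gamma increments, so entities of equal weighted size have
identically distributed cost per weighted patient — which is what makes the
focal-vs-network comparison well calibrated).

All coefficient tables produced here are synthetic and clearly non-official:
a plausible U-shaped age-cost curve with a deprivation gradient, normalized
to Table-like need-index magnitudes.  Every random draw flows through one
seeded generator; identical seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .adjustments import Deflator
from .errors import SchemaError
from .population import (
    AgeSexBand,
    POPULATION_COLUMNS,
    canonical_bands,
    quarter_starts,
    validate_banding,
)
from .weighting import (
    ADAPTED_COMPONENTS,
    CARR_HILL_LOCAL_FACTORS,
    CORE_COMPONENTS,
    CORE_LOCAL_FACTORS,
    CoefficientTable,
)

# Default regional age-sex mixture: a working-age-heavy urban English
# commissioning region (shares of the registered list by band).
_REGIONAL_SHARES = {
    "female 0-19": 0.1059,
    "female 20-39": 0.1764,
    "female 40-59": 0.1238,
    "female 60-79": 0.0648,
    "female 80+": 0.0177,
    "male 0-19": 0.1113,
    "male 20-39": 0.1784,
    "male 40-59": 0.1474,
    "male 60-79": 0.0618,
    "male 80+": 0.0126,
}

# Skeleton for the non-20-39 remainder of the focal practice's mixture
# (digital-first lists skew male and 40-59 within the remainder).
_FOCAL_REMAINDER_SKELETON = {
    "female 0-19": 0.0163,
    "female 40-59": 0.0310,
    "female 60-79": 0.0040,
    "female 80+": 0.0006,
    "male 0-19": 0.0134,
    "male 40-59": 0.0732,
    "male 60-79": 0.0060,
    "male 80+": 0.0005,
}

_FEMALE_SHARE_20_39 = 0.464  # within the 20-39 block


def regional_mixture(banding: Sequence[AgeSexBand] | None = None) -> dict[AgeSexBand, float]:
    bands = tuple(banding) if banding is not None else canonical_bands()
    if set(b.label for b in bands) == set(_REGIONAL_SHARES):
        raw = {b: _REGIONAL_SHARES[b.label] for b in bands}
    else:
        # arbitrary bandings: uniform fallback
        raw = {b: 1.0 for b in bands}
    total = sum(raw.values())
    return {b: v / total for b, v in raw.items()}


def focal_age_mixture(
    banding: Sequence[AgeSexBand] | None = None, young_adult_share: float = 0.855
) -> dict[AgeSexBand, float]:
    """Age-sex mixture of the focal practice: ``young_adult_share`` of the
    list in ages 20-39, the remainder spread over the other bands."""
    if not 0 < young_adult_share < 1:
        raise SchemaError("young_adult_share must be in (0, 1)")
    bands = tuple(banding) if banding is not None else canonical_bands()
    mix: dict[AgeSexBand, float] = {}
    young = [b for b in bands if b.lower == 20 and b.upper == 39]
    others = [b for b in bands if b not in young]
    if len(young) == 2:
        for b in young:
            frac = _FEMALE_SHARE_20_39 if b.sex == "female" else 1 - _FEMALE_SHARE_20_39
            mix[b] = young_adult_share * frac
        skel = {
            b: _FOCAL_REMAINDER_SKELETON.get(b.label, 0.01) for b in others
        }
    else:  # non-canonical banding: concentrate on bands overlapping 20-39
        young = [b for b in bands if b.lower <= 39 and (b.upper is None or b.upper >= 20)]
        others = [b for b in bands if b not in young]
        for b in young:
            mix[b] = young_adult_share / len(young)
        skel = {b: 1.0 for b in others}
    s = sum(skel.values())
    for b in others:
        mix[b] = (1 - young_adult_share) * skel[b] / s
    return mix


def expected_need_index(
    mixture: Mapping[AgeSexBand, float], table: CoefficientTable
) -> float:
    """Need index of a population with the given band mixture, neutral
    local factors."""
    return sum(share * table.combined_band_need(b) for b, share in mixture.items())


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FocalConfig:
    practice_id: str = "FOCAL"
    network_id: str = "net_focal"
    quarterly_sizes: tuple[float, ...] = (55000.0, 59000.0, 63000.0, 67000.0)
    young_adult_share: float = 0.855
    true_spend_multiplier: float = 0.65
    annual_growth: float = 2.0  # list-size multiple year over year


@dataclass(frozen=True)
class RegionConfig:
    n_practices: int = 357          # reference practices (excluding focal)
    n_networks: int = 48            # reference networks (excluding focal's)
    n_areas: int = 8
    mean_list_size: float = 6900.0
    list_size_sigma: float = 0.45   # lognormal dispersion of list sizes
    mixture_concentration: float = 300.0  # Dirichlet conc. of per-practice mixes
    base_cost_per_need_unit: float = 715.0  # GBP per weighted patient per year
    spend_noise_shape: float = 50.0  # gamma shape for an average-size practice
    financial_years: tuple[str, ...] = ("2019/20",)
    focal: FocalConfig = field(default_factory=FocalConfig)
    seed: int = 0
    analysis_table_perturbation: float = 0.0  # >0: mis-specified analysis tables
    target_need_index: float = 0.93

    def __post_init__(self) -> None:
        if self.n_practices < self.n_networks or self.n_networks < 1:
            raise SchemaError("need n_practices >= n_networks >= 1")
        if self.mean_list_size <= 0 or self.base_cost_per_need_unit <= 0:
            raise SchemaError("sizes and costs must be positive")
        if self.spend_noise_shape <= 0:
            raise SchemaError("spend_noise_shape must be positive")
        if not self.financial_years:
            raise SchemaError("at least one financial year required")

    @property
    def banding(self) -> tuple[AgeSexBand, ...]:
        return canonical_bands()

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "RegionConfig":
        """A small region (60 practices, 8 networks) that runs the full
        pipeline in seconds; the focal practice is scaled to stay comparable
        to a network."""
        defaults = dict(
            n_practices=60,
            n_networks=8,
            n_areas=4,
            focal=FocalConfig(quarterly_sizes=(46000.0, 49000.0, 52000.0, 55000.0)),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# coefficient generation


def _age_cost_curve(band: AgeSexBand) -> float:
    """Synthetic U-shaped age-cost curve evaluated at the band midpoint."""
    mid = band.lower + 10 if band.upper is None else (band.lower + band.upper) / 2
    if mid >= 25:
        return 0.55 + 1.9 * ((mid - 25) / 60) ** 2
    return 0.55 + 0.5 * ((25 - mid) / 25) ** 2


def generate_coefficients(
    seed: int,
    banding: Sequence[AgeSexBand] | None = None,
    area_deprivation: Mapping[str, float] | None = None,
    reference_shares: Mapping[AgeSexBand, float] | None = None,
    target_need_index: float = 0.93,
) -> dict[str, CoefficientTable]:
    """Generate one synthetic CoefficientTable per scheme.

    The tables are labelled synthetic and are not official allocation
    coefficients.  Band needs follow a U-shaped age-cost curve with
    per-component tilts; local factors carry a deprivation gradient
    (more-deprived areas get larger factors) and are normalized so the area
    factor products average 1, making the regional population-weighted need
    index land near ``target_need_index``.
    """
    rng = np.random.default_rng(seed)
    bands = tuple(banding) if banding is not None else canonical_bands()
    validate_banding(bands)
    shares = dict(reference_shares) if reference_shares else regional_mixture(bands)
    if area_deprivation is None:
        area_deprivation = {"area_1": 50.0}

    # per-component band needs: base curve x component tilt x jitter
    def tilt(comp: str, band: AgeSexBand) -> float:
        mid = band.lower + 10 if band.upper is None else (band.lower + band.upper) / 2
        if comp == "maternity":
            return 4.0 if (band.sex == "female" and 15 <= mid <= 45) else 0.08
        if comp == "mental_health":
            # concentrated in working age
            return 1.8 if 20 <= mid <= 65 else 0.6
        if comp == "prescribing":
            return 0.6 + 0.012 * mid
        if comp == "general_acute":
            # acute use by healthy young adults is disproportionately low
            return 0.72 if 18 <= mid <= 45 else 1.12
        return 1.0  # community follows the base curve

    weights = {
        "general_acute": 0.60,
        "mental_health": 0.13,
        "maternity": 0.06,
        "community": 0.12,
        "prescribing": 0.09,
    }
    component_need = {
        comp: {
            b: _age_cost_curve(b) * tilt(comp, b) * rng.uniform(0.95, 1.05)
            for b in bands
        }
        for comp in CORE_COMPONENTS
    }
    # normalize so the reference mixture evaluates to the target index
    raw = sum(
        shares[b] * sum(weights[c] * component_need[c][b] for c in CORE_COMPONENTS)
        for b in bands
    )
    scale = target_need_index / raw
    component_need = {
        c: {b: v * scale for b, v in m.items()} for c, m in component_need.items()
    }

    # local factors with deprivation gradient; products normalized to mean 1
    def core_factors(dep: float) -> dict[str, float]:
        return {
            "utilization": float(rng.normal(1.0, 0.03)),
            "supply": float(rng.normal(1.0, 0.03)),
            "price": float(rng.normal(1.0, 0.05)),
            "unmet_need": float(rng.normal(1.0, 0.02)),
            "deprivation": 1.0 + 0.12 * (50.5 - dep) / 100.0,
            "smallness": 1.0,
        }

    core_local = {a: core_factors(d) for a, d in area_deprivation.items()}
    products = np.array([np.prod(list(f.values())) for f in core_local.values()])
    norm = float(products.mean())
    for f in core_local.values():
        f["utilization"] /= norm

    core = CoefficientTable(
        scheme="core_services",
        bands=bands,
        reference_mean=target_need_index,
        reference_shares=shares,
        component_weights=weights,
        component_need=component_need,
        local_factors=core_local,
    )

    # adapted: general & acute + maternity only, weights renormalized
    w_ad = {c: weights[c] for c in ADAPTED_COMPONENTS}
    w_sum = sum(w_ad.values())
    w_ad = {c: w / w_sum for c, w in w_ad.items()}
    need_ad = {c: dict(component_need[c]) for c in ADAPTED_COMPONENTS}
    ref_ad = sum(
        shares[b] * sum(w_ad[c] * need_ad[c][b] for c in ADAPTED_COMPONENTS)
        for b in bands
    )
    adapted = CoefficientTable(
        scheme="core_services_adapted",
        bands=bands,
        reference_mean=float(ref_ad),
        reference_shares=shares,
        component_weights=w_ad,
        component_need=need_ad,
        local_factors={a: dict(f) for a, f in core_local.items()},
    )

    # carr-hill: workload curve, flatter than the cost curve, female uplift
    def workload(b: AgeSexBand) -> float:
        mid = b.lower + 10 if b.upper is None else (b.lower + b.upper) / 2
        base = 0.95 if mid < 20 else 0.80 + 1.1 * max(0.0, (mid - 35) / 55) ** 2
        sex_uplift = 1.10 if b.sex == "female" else 1.0
        return base * sex_uplift * float(rng.uniform(0.97, 1.03))

    band_need = {b: workload(b) for b in bands}
    raw_ch = sum(shares[b] * band_need[b] for b in bands)
    band_need = {b: v * target_need_index / raw_ch for b, v in band_need.items()}
    ch_local = {
        a: {
            "mortality": float(rng.normal(1.0, 0.04)),
            "market_forces": float(rng.normal(1.0, 0.05)),
            "rurality": 1.0,  # phased out; neutral default
        }
        for a in area_deprivation
    }
    ch_products = np.array([np.prod(list(f.values())) for f in ch_local.values()])
    for f in ch_local.values():
        f["mortality"] /= float(ch_products.mean())
    carr_hill = CoefficientTable(
        scheme="carr_hill",
        bands=bands,
        reference_mean=target_need_index,
        reference_shares=shares,
        band_need=band_need,
        nursing_home_premium=0.43,
        local_factors=ch_local,
    )

    tables = {"core_services": core, "core_services_adapted": adapted, "carr_hill": carr_hill}
    for t in tables.values():
        t.validate()
    return tables


def perturb_table(table: CoefficientTable, seed: int, scale: float) -> CoefficientTable:
    """Mis-specification mode: multiply every band need by lognormal noise
    of the given relative scale (renormalizing the reference mean)."""
    rng = np.random.default_rng(seed)

    def jitter(m: Mapping[AgeSexBand, float]) -> dict[AgeSexBand, float]:
        return {b: v * float(rng.lognormal(0.0, scale)) for b, v in m.items()}

    if table.scheme == "carr_hill":
        band_need = jitter(table.band_need)
        ref = sum(table.reference_shares[b] * band_need[b] for b in table.bands)
        band_need = {b: v * table.reference_mean / ref for b, v in band_need.items()}
        new = dataclasses.replace(table, band_need=band_need)
    else:
        comp = {c: jitter(m) for c, m in table.component_need.items()}
        ref = sum(
            table.reference_shares[b]
            * sum(table.component_weights[c] * comp[c][b] for c in comp)
            for b in table.bands
        )
        comp = {c: {b: v * table.reference_mean / ref for b, v in m.items()}
                for c, m in comp.items()}
        new = dataclasses.replace(table, component_need=comp)
    new.validate()
    return new


# ---------------------------------------------------------------------------
# region generation


@dataclass
class SyntheticRegion:
    config: RegionConfig
    population: pd.DataFrame
    spend: pd.DataFrame
    tables: dict[str, CoefficientTable]           # generating tables
    analysis_tables: dict[str, CoefficientTable]  # == tables unless perturbed
    network_map: pd.DataFrame
    resident_mix: dict[str, float]                # focal practice's areas
    nursing_home_rates: dict[str, float]
    deflator: Deflator
    truth: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(out / "population.csv", index=False,
                               columns=POPULATION_COLUMNS)
        self.spend.to_csv(out / "spend.csv", index=False)
        for scheme, table in self.analysis_tables.items():
            table.to_yaml(out / f"coefficients_{scheme}.yaml")
        self.network_map.to_csv(out / "network_map.csv", index=False)
        pd.DataFrame(
            {"area_id": list(self.resident_mix), "fraction": list(self.resident_mix.values())}
        ).to_csv(out / "resident_mix.csv", index=False)
        pd.DataFrame(
            {"practice_id": list(self.nursing_home_rates),
             "nursing_home_rate": list(self.nursing_home_rates.values())}
        ).to_csv(out / "nursing_home_rates.csv", index=False)
        self.deflator.to_csv(out / "deflator.csv")
        with open(out / "truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)


def _gamma_noise(rng: np.random.Generator, shape: float) -> float:
    """Mean-1 gamma multiplier; an infinite shape means no noise."""
    if not np.isfinite(shape):
        return 1.0
    return float(rng.gamma(shape)) / shape


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Draw a full synthetic region (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    bands = config.banding
    band_list = list(bands)

    areas = [f"area_{i + 1}" for i in range(config.n_areas)]
    area_dep = {a: float(rng.uniform(20, 80)) for a in areas}
    tables = generate_coefficients(
        seed=int(rng.integers(0, 2**31 - 1)),
        banding=bands,
        area_deprivation=area_dep,
        target_need_index=config.target_need_index,
    )
    if config.analysis_table_perturbation > 0:
        pseed = int(rng.integers(0, 2**31 - 1))
        analysis_tables = {
            s: perturb_table(t, pseed + i, config.analysis_table_perturbation)
            for i, (s, t) in enumerate(tables.items())
        }
    else:
        analysis_tables = tables

    networks = [f"net_{i + 1:02d}" for i in range(config.n_networks)]
    network_area = {n: areas[i % len(areas)] for i, n in enumerate(networks)}

    mix_regional = regional_mixture(bands)
    alpha = np.array([mix_regional[b] for b in band_list]) * config.mixture_concentration

    # reference practices
    practices = []
    mu = np.log(config.mean_list_size) - config.list_size_sigma**2 / 2
    for i in range(config.n_practices):
        pid = f"P{i + 1:04d}"
        net = networks[i % config.n_networks]
        area = network_area[net]
        size = max(200.0, float(rng.lognormal(mu, config.list_size_sigma)))
        mix = rng.dirichlet(alpha)
        growth = float(rng.normal(0.002, 0.004))
        dep = int(np.clip(round(rng.normal(area_dep[area], 12)), 1, 100))
        nh_rate = float(rng.beta(2, 200))
        practices.append((pid, net, area, size, mix, growth, dep, nh_rate))

    focal = config.focal
    focal_mix_map = focal_age_mixture(bands, focal.young_adult_share)
    focal_mix = np.array([focal_mix_map[b] for b in band_list])
    focal_resident_mix_arr = rng.dirichlet(np.full(len(areas), 2.0))
    focal_resident_mix = {a: float(v) for a, v in zip(areas, focal_resident_mix_arr)}
    focal_dep = int(np.clip(round(rng.normal(45, 8)), 1, 100))
    focal_area = areas[int(np.argmax(focal_resident_mix_arr))]

    core_gen = tables["core_services"]
    need_vec = np.array([core_gen.combined_band_need(b) for b in band_list])
    area_factor = {a: core_gen.local_factor_product(a) for a in areas}
    ref_weighted_unit = config.mean_list_size * config.target_need_index

    pop_rows: list[tuple] = []
    spend_rows: list[tuple] = []
    truth_mult: dict[str, float] = {}
    n_years = len(config.financial_years)

    for y, year in enumerate(config.financial_years):
        qstarts = quarter_starts(year)
        year_back = n_years - 1 - y  # 0 for the final year
        for pid, net, area, size, mix, growth, dep, nh in practices:
            counts_sum = np.zeros(len(band_list))
            size_y = size / (1.0 + growth) ** (4 * year_back)
            for q, qs in enumerate(qstarts):
                total_q = max(50, int(round(size_y * (1.0 + growth) ** q)))
                counts = rng.multinomial(total_q, mix)
                counts_sum += counts
                for b, c in zip(band_list, counts):
                    if c > 0:
                        pop_rows.append(
                            (pid, net, area, qs.isoformat(), b.sex, b.age_label,
                             int(c), dep)
                        )
            avg_counts = counts_sum / len(qstarts)
            weighted = float(avg_counts @ need_vec) * area_factor[area]
            noise = _gamma_noise(rng, config.spend_noise_shape * weighted / ref_weighted_unit)
            spend = weighted * config.base_cost_per_need_unit * noise
            spend_rows.append((pid, year, round(spend, 2)))
            truth_mult[pid] = 1.0

        # focal practice: young-skewed, growing trajectory
        fsizes = [s / focal.annual_growth**year_back for s in focal.quarterly_sizes]
        counts_sum = np.zeros(len(band_list))
        for qs, total_q in zip(qstarts, fsizes):
            counts = rng.multinomial(int(round(total_q)), focal_mix)
            counts_sum += counts
            for b, c in zip(band_list, counts):
                if c > 0:
                    pop_rows.append(
                        (focal.practice_id, focal.network_id, focal_area,
                         qs.isoformat(), b.sex, b.age_label, int(c), focal_dep)
                    )
        avg_counts = counts_sum / len(qstarts)
        # truth prices every practice at its home area's factor product; the
        # resident mix is emitted for the adapted scheme's consumption
        weighted = float(avg_counts @ need_vec) * area_factor[focal_area]
        noise = _gamma_noise(rng, config.spend_noise_shape * weighted / ref_weighted_unit)
        spend = weighted * config.base_cost_per_need_unit * noise * focal.true_spend_multiplier
        spend_rows.append((focal.practice_id, year, round(spend, 2)))
        truth_mult[focal.practice_id] = focal.true_spend_multiplier

    population = pd.DataFrame(pop_rows, columns=POPULATION_COLUMNS)
    spend = pd.DataFrame(spend_rows, columns=["practice_id", "financial_year", "total_spend"])
    network_map = pd.DataFrame(
        sorted({(p, n) for p, n, *_ in pop_rows}),
        columns=["practice_id", "network_id"],
    )
    nh_rates = {pid: nh for pid, _, _, _, _, _, _, nh in practices}
    nh_rates[focal.practice_id] = 0.0

    # simple two-year whole-economy price index ending at 100
    years_all = sorted(set(config.financial_years) | {"2018/19", "2019/20"})
    deflator = Deflator(
        {yr: round(100.0 / 1.022 ** (len(years_all) - 1 - i), 3)
         for i, yr in enumerate(years_all)}
    )

    truth = {
        "seed": int(config.seed),
        "base_cost_per_need_unit": float(config.base_cost_per_need_unit),
        "true_spend_multiplier": {k: float(v) for k, v in truth_mult.items()},
        "focal_practice_id": focal.practice_id,
        "focal_network_id": focal.network_id,
        "generating_tables_perturbed_for_analysis": config.analysis_table_perturbation > 0,
    }
    return SyntheticRegion(
        config=config,
        population=population,
        spend=spend,
        tables=tables,
        analysis_tables=analysis_tables,
        network_map=network_map,
        resident_mix=focal_resident_mix,
        nursing_home_rates=nh_rates,
        deflator=deflator,
        truth=truth,
    )
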