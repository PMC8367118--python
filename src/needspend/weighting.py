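"""Need-based population weighting.

Three capitation-style schemes convert an averaged registered population into
a *weighted* population, so that populations with different age-sex mixes,
deprivation and local cost conditions become directly comparable:

* ``core_services`` — the commissioner-allocation style formula: per-service
  need components (general & acute, mental health, maternity, community,
  prescribing) combined by component weights, then multiplied by the
  practice's local adjustment factors (utilization, supply, price, unmet
  need, deprivation, smallness).
* ``core_services_adapted`` — the same engine restricted to the general &
  acute and maternity components (matching spend data that exclude mental
  health, community and prescribing costs), always evaluated on the
  practice's *actual* averaged age-sex profile, with local factors averaged
  over the areas where the patients actually live.
* ``carr_hill`` — the primary-care global-sum style formula: an age-sex
  workload curve times mortality, market-forces and rurality factors, with a
  premium proportional to the practice's nursing-home registration rate.

All schemes compose multiplicatively: (band-level product-sum) x (product of
local factors).  Coefficient values are supplied entirely by the caller's
table — nothing official is bundled; :mod:`needspend.synthetic` generates
clearly-labelled synthetic tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import DomainError, SchemaError
from .population import AgeSexBand, PopulationProfile, validate_banding

SCHEMES = ("core_services", "core_services_adapted", "carr_hill")

CORE_COMPONENTS = (
    "general_acute",
    "mental_health",
    "maternity",
    "community",
    "prescribing",
)
ADAPTED_COMPONENTS = ("general_acute", "maternity")

CORE_LOCAL_FACTORS = (
    "utilization",
    "supply",
    "price",
    "unmet_need",
    "deprivation",
    "smallness",
)
CARR_HILL_LOCAL_FACTORS = ("mortality", "market_forces", "rurality")


@dataclass(frozen=True)
class WeightedPopulation:
    practice_id: str
    scheme: str
    registered: float
    weighted: float
    """Weighted persons; ``need_index`` is ``weighted / registered``."""

    @property
    def need_index(self) -> float:
        return need_index(self.weighted, self.registered)


def need_index(weighted: float, registered: float) -> float:
    """Weighted population relative to registered population (>1 means
    higher-than-baseline expected cost)."""
    if registered <= 0:
        raise DomainError("need index undefined for zero registered population")
    return weighted / registered


@dataclass
class CoefficientTable:
    """Per-scheme need multipliers and local factors.

    ``reference_shares`` is the band mixture of the reference (national)
    population; the table is normalized so that this mixture, evaluated with
    neutral local factors, yields need index ``reference_mean``.
    """

    scheme: str
    bands: tuple[AgeSexBand, ...]
    reference_mean: float
    reference_shares: Mapping[AgeSexBand, float]
    # core schemes
    component_weights: Mapping[str, float] = field(default_factory=dict)
    component_need: Mapping[str, Mapping[AgeSexBand, float]] = field(default_factory=dict)
    # carr-hill
    band_need: Mapping[AgeSexBand, float] = field(default_factory=dict)
    nursing_home_premium: float = 0.0
    # per-area named multipliers
    local_factors: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Schema check; raises :class:`SchemaError` naming the first
        violating path."""
        if self.scheme not in SCHEMES:
            raise SchemaError(f"scheme: unknown scheme {self.scheme!r}")
        validate_banding(self.bands)
        if self.scheme == "carr_hill":
            self._validate_band_map("band_need", self.band_need)
            if self.nursing_home_premium < 0:
                raise SchemaError("nursing_home_premium: must be >= 0")
            factor_names = CARR_HILL_LOCAL_FACTORS
        else:
            allowed = (
                CORE_COMPONENTS if self.scheme == "core_services" else ADAPTED_COMPONENTS
            )
            if not self.component_weights:
                raise SchemaError("component_weights: empty")
            for comp in self.component_weights:
                if comp not in allowed:
                    raise SchemaError(
                        f"component_weights.{comp}: component not permitted for "
                        f"scheme {self.scheme}"
                    )
            wsum = sum(self.component_weights.values())
            if abs(wsum - 1.0) > 1e-9:
                raise SchemaError(
                    f"component_weights: weights sum to {wsum!r}, expected 1"
                )
            for comp in self.component_weights:
                need = self.component_need.get(comp)
                if need is None:
                    raise SchemaError(f"component_need.{comp}: missing")
                self._validate_band_map(f"component_need.{comp}", need)
            factor_names = CORE_LOCAL_FACTORS
        for area, factors in self.local_factors.items():
            for name, v in factors.items():
                if name not in factor_names:
                    raise SchemaError(
                        f"local_factors.{area}.{name}: unknown factor for "
                        f"scheme {self.scheme}"
                    )
                if not (v > 0 and math.isfinite(v)):
                    raise SchemaError(
                        f"local_factors.{area}.{name}: must be positive and "
                        f"finite, got {v!r}"
                    )
        shares_sum = sum(self.reference_shares.values())
        if abs(shares_sum - 1.0) > 1e-6:
            raise SchemaError(
                f"reference_shares: shares sum to {shares_sum!r}, expected 1"
            )
        # normalization: reference mixture with neutral local factors
        ref_index = sum(
            self.reference_shares.get(b, 0.0) * self.combined_band_need(b)
            for b in self.bands
        )
        if abs(ref_index - self.reference_mean) > 1e-6:
            raise SchemaError(
                f"reference_mean: stated {self.reference_mean!r} but reference "
                f"mixture evaluates to {ref_index!r}"
            )

    def _validate_band_map(self, path: str, mapping: Mapping[AgeSexBand, float]) -> None:
        for band in self.bands:
            v = mapping.get(band)
            if v is None:
                raise SchemaError(f"{path}.{band.label}: missing band multiplier")
            if not (v > 0 and math.isfinite(v)):
                raise SchemaError(
                    f"{path}.{band.label}: must be positive and finite, got {v!r}"
                )

    # -- evaluation helpers ------------------------------------------------

    def combined_band_need(self, band: AgeSexBand) -> float:
        """Component-weight-combined need multiplier for one band."""
        if self.scheme == "carr_hill":
            try:
                return self.band_need[band]
            except KeyError:
                raise DomainError(
                    f"band {band.label} absent from {self.scheme} table"
                ) from None
        total = 0.0
        for comp, w in self.component_weights.items():
            need = self.component_need[comp]
            try:
                total += w * need[band]
            except KeyError:
                raise DomainError(
                    f"band {band.label} absent from {self.scheme} table "
                    f"(component {comp})"
                ) from None
        return total

    def local_factor_product(self, area_id: str) -> float:
        try:
            factors = self.local_factors[area_id]
        except KeyError:
            raise DomainError(
                f"area {area_id!r} absent from {self.scheme} local factors"
            ) from None
        return math.prod(factors.values())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "scheme": self.scheme,
            "banding": [b.label for b in self.bands],
            "reference_mean": float(self.reference_mean),
            "reference_shares": {b.label: float(v) for b, v in self.reference_shares.items()},
            "local_factors": {a: {k: float(v) for k, v in f.items()}
                              for a, f in self.local_factors.items()},
        }
        if self.scheme == "carr_hill":
            d["band_need"] = {b.label: float(v) for b, v in self.band_need.items()}
            d["nursing_home_premium"] = float(self.nursing_home_premium)
        else:
            d["components"] = {
                comp: {
                    "weight": float(self.component_weights[comp]),
                    "need": {b.label: float(v) for b, v in self.component_need[comp].items()},
                }
                for comp in self.component_weights
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientTable":
        try:
            bands = tuple(AgeSexBand.parse_label(s) for s in d["banding"])
            kwargs: dict = dict(
                scheme=d["scheme"],
                bands=bands,
                reference_mean=float(d["reference_mean"]),
                reference_shares={
                    AgeSexBand.parse_label(k): float(v)
                    for k, v in d["reference_shares"].items()
                },
                local_factors={
                    str(a): {str(k): float(v) for k, v in f.items()}
                    for a, f in d.get("local_factors", {}).items()
                },
            )
            if d["scheme"] == "carr_hill":
                kwargs["band_need"] = {
                    AgeSexBand.parse_label(k): float(v)
                    for k, v in d["band_need"].items()
                }
                kwargs["nursing_home_premium"] = float(d.get("nursing_home_premium", 0.0))
            else:
                comps = d["components"]
                kwargs["component_weights"] = {c: float(v["weight"]) for c, v in comps.items()}
                kwargs["component_need"] = {
                    c: {AgeSexBand.parse_label(k): float(x) for k, x in v["need"].items()}
                    for c, v in comps.items()
                }
        except KeyError as e:
            raise SchemaError(f"coefficient table: missing key {e}") from None
        table = cls(**kwargs)
        table.validate()
        return table

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CoefficientTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# scheme evaluation


def _band_product_sum(profile: PopulationProfile, table: CoefficientTable) -> float:
    return sum(
        count * table.combined_band_need(band)
        for band, count in profile.counts.items()
        if count != 0
    )


def core_services_weight(
    profile: PopulationProfile,
    table: CoefficientTable,
    area_id: str,
    practice_id: str = "",
) -> WeightedPopulation:
    """Core-services weighting: component product-sum times the home-area
    local factor product."""
    if table.scheme != "core_services":
        raise SchemaError(f"expected core_services table, got {table.scheme}")
    weighted = _band_product_sum(profile, table) * table.local_factor_product(area_id)
    return WeightedPopulation(practice_id, table.scheme, profile.total, weighted)


def core_services_adapted_weight(
    profile: PopulationProfile,
    table: CoefficientTable,
    resident_area_mix: Mapping[str, float],
    practice_id: str = "",
) -> WeightedPopulation:
    """Adapted core-services weighting.

    Differences from :func:`core_services_weight`: only the general & acute
    and maternity components enter (reweighted to sum to one — enforced by
    the table schema); the profile supplied must be the practice's actual
    averaged profile; and the local factor is the residence-mix-weighted
    average of the per-area factor products.
    """
    if table.scheme != "core_services_adapted":
        raise SchemaError(f"expected core_services_adapted table, got {table.scheme}")
    mix_sum = sum(resident_area_mix.values())
    if abs(mix_sum - 1.0) > 1e-6:
        raise DomainError(f"residence mix sums to {mix_sum!r}, expected 1")
    for frac in resident_area_mix.values():
        if frac < 0:
            raise DomainError("residence mix fractions must be non-negative")
    factor = sum(
        frac * table.local_factor_product(area)
        for area, frac in resident_area_mix.items()
        if frac != 0
    )
    weighted = _band_product_sum(profile, table) * factor
    return WeightedPopulation(practice_id, table.scheme, profile.total, weighted)


def carr_hill_weight(
    profile: PopulationProfile,
    table: CoefficientTable,
    area_id: str,
    nursing_home_rate: float = 0.0,
    practice_id: str = "",
) -> WeightedPopulation:
    """Carr-Hill style weighting: age-sex workload curve x mortality x
    market forces x rurality x (1 + premium x nursing-home rate)."""
    if table.scheme != "carr_hill":
        raise SchemaError(f"expected carr_hill table, got {table.scheme}")
    if nursing_home_rate < 0:
        raise DomainError("nursing home rate must be >= 0")
    weighted = (
        _band_product_sum(profile, table)
        * table.local_factor_product(area_id)
        * (1.0 + table.nursing_home_premium * nursing_home_rate)
    )
    return WeightedPopulation(practice_id, table.scheme, profile.total, weighted)


def weight_profile(
    profile: PopulationProfile,
    table: CoefficientTable,
    *,
    area_id: str | None = None,
    resident_area_mix: Mapping[str, float] | None = None,
    nursing_home_rate: float = 0.0,
    practice_id: str = "",
) -> WeightedPopulation:
    """Scheme-dispatching convenience used by the pipeline."""
    if table.scheme == "core_services":
        return core_services_weight(profile, table, area_id, practice_id)
    if table.scheme == "core_services_adapted":
        mix = resident_area_mix if resident_area_mix is not None else {area_id: 1.0}
        return core_services_adapted_weight(profile, table, mix, practice_id)
    if table.scheme == "carr_hill":
        return carr_hill_weight(profile, table, area_id, nursing_home_rate, practice_id)
    raise SchemaError(f"unknown scheme {table.scheme!r}")
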