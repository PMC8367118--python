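import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from needspend.errors import DomainError, SchemaError
from needspend.population import AgeSexBand, PopulationProfile
from needspend.synthetic import regional_mixture
from needspend.weighting import (
    CoefficientTable,
    carr_hill_weight,
    core_services_adapted_weight,
    core_services_weight,
    need_index,
)

from .conftest import (
    FEMALE_ALL,
    MALE_ALL,
    toy_carr_hill_table,
    toy_core_table,
    two_band_profile,
)


def brute_force_core(profile, table, factor_product):
    """Independent nested-loop evaluation of the core product-sum."""
    total = 0.0
    for band, count in profile.counts.items():
        band_need = 0.0
        for comp, w in table.component_weights.items():
            band_need += w * table.component_need[comp][band]
        total += count * band_need
    return total * factor_product


class TestCoreServices:
    def test_identity_table_returns_registered(self):
        profile = two_band_profile(400, 600)
        wp = core_services_weight(profile, toy_core_table(), "A")
        assert wp.weighted == pytest.approx(1000.0)
        assert wp.need_index == pytest.approx(1.0)

    def test_two_band_hand_oracle(self):
        # (100 x 0.5 + 300 x 1.5) x 1.1 = 550, need index 1.375
        profile = two_band_profile(100, 300)
        table = toy_core_table(
            needs=(0.5, 1.5), local_factors={"A": {"utilization": 1.1}}
        )
        wp = core_services_weight(profile, table, "A")
        assert wp.weighted == pytest.approx(550.0)
        assert wp.need_index == pytest.approx(1.375)

    def test_unknown_area_is_named(self):
        with pytest.raises(DomainError, match="nowhere"):
            core_services_weight(two_band_profile(1, 1), toy_core_table(), "nowhere")

    def test_band_absent_from_table_is_an_error(self):
        profile = PopulationProfile({AgeSexBand("female", 0, 19): 10.0})
        with pytest.raises(DomainError, match="absent"):
            core_services_weight(profile, toy_core_table(), "A")

    def test_matches_brute_force_on_synthetic_region(self, desk_region):
        from needspend.population import build_practice_records

        table = desk_region.analysis_tables["core_services"]
        records, _, _ = build_practice_records(
            desk_region.population, desk_region.spend, "2019/20"
        )
        for rec in list(records.values())[:10]:
            profile = rec.averaged_profile()
            wp = core_services_weight(profile, table, rec.area_id)
            expected = brute_force_core(
                profile, table, math.prod(table.local_factors[rec.area_id].values())
            )
            assert wp.weighted == pytest.approx(expected, rel=1e-9)


class TestAdapted:
    def test_single_area_mix_equals_core_with_reduced_components(self):
        weights = {"general_acute": 0.8, "maternity": 0.2}
        factors = {"A": {"utilization": 1.07}, "B": {"utilization": 0.9}}
        profile = two_band_profile(120, 80)
        adapted = toy_core_table(
            needs=(0.7, 1.3), scheme="core_services_adapted",
            weights=weights, local_factors=factors,
        )
        core_like = toy_core_table(needs=(0.7, 1.3), weights={"general_acute": 1.0},
                                   local_factors=factors)
        wa = core_services_adapted_weight(profile, adapted, {"A": 1.0})
        # same need curve in every component, so the reduced set is identical
        wc = core_services_weight(profile, core_like, "A")
        assert wa.weighted == pytest.approx(wc.weighted, rel=1e-12)

    def test_symmetric_mix_averages_local_factors(self):
        factors = {"A": {"utilization": 0.9}, "B": {"utilization": 1.1}}
        table = toy_core_table(scheme="core_services_adapted",
                               weights={"general_acute": 1.0}, local_factors=factors)
        wp = core_services_adapted_weight(
            two_band_profile(500, 500), table, {"A": 0.5, "B": 0.5}
        )
        assert wp.weighted == pytest.approx(1000.0)  # effective factor 1.0

    def test_two_area_mix_matches_brute_force(self):
        factors = {"A": {"utilization": 1.2, "price": 0.95}, "B": {"deprivation": 1.05}}
        table = toy_core_table(
            needs=(0.6, 1.4), scheme="core_services_adapted",
            weights={"general_acute": 0.75, "maternity": 0.25},
            local_factors=factors,
        )
        profile = two_band_profile(210, 90)
        mix = {"A": 0.3, "B": 0.7}
        wp = core_services_adapted_weight(profile, table, mix)
        eff = 0.3 * (1.2 * 0.95) + 0.7 * 1.05
        assert wp.weighted == pytest.approx(
            brute_force_core(profile, table, eff), rel=1e-12
        )

    def test_mix_must_sum_to_one(self):
        table = toy_core_table(scheme="core_services_adapted",
                               weights={"general_acute": 1.0})
        with pytest.raises(DomainError, match="sums to"):
            core_services_adapted_weight(two_band_profile(1, 1), table, {"A": 0.7})

    def test_excluded_component_rejected_by_schema(self):
        with pytest.raises(SchemaError, match="mental_health"):
            toy_core_table(
                scheme="core_services_adapted",
                weights={"general_acute": 0.5, "mental_health": 0.5},
            )


class TestCarrHill:
    def test_identity_with_zero_nursing_rate(self):
        wp = carr_hill_weight(two_band_profile(700, 300), toy_carr_hill_table(), "A", 0.0)
        assert wp.weighted == pytest.approx(1000.0)

    def test_hand_product(self):
        # 100 persons x band need 1.2 x mortality 1.05 = 126
        profile = PopulationProfile({FEMALE_ALL: 100.0, MALE_ALL: 0.0})
        table = toy_carr_hill_table(
            needs=(1.2, 1.0), local_factors={"A": {"mortality": 1.05}}
        )
        wp = carr_hill_weight(profile, table, "A")
        assert wp.weighted == pytest.approx(126.0)

    def test_nursing_home_premium(self):
        table = toy_carr_hill_table(premium=0.43)
        wp = carr_hill_weight(two_band_profile(500, 500), table, "A", nursing_home_rate=0.1)
        assert wp.weighted == pytest.approx(1000 * (1 + 0.43 * 0.1))

    def test_negative_nursing_rate_errors(self):
        with pytest.raises(DomainError):
            carr_hill_weight(two_band_profile(1, 1), toy_carr_hill_table(), "A", -0.1)


class TestSchemeProperties:
    @given(k=st.floats(0.01, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_degree_one_homogeneity(self, k, synthetic_tables):
        mix = regional_mixture()
        profile = PopulationProfile({b: 1000 * s for b, s in mix.items()})
        scaled = profile.scaled(k)
        for scheme, table in synthetic_tables.items():
            area = next(iter(table.local_factors))
            if scheme == "carr_hill":
                base = carr_hill_weight(profile, table, area, 0.02)
                big = carr_hill_weight(scaled, table, area, 0.02)
            elif scheme == "core_services":
                base = core_services_weight(profile, table, area)
                big = core_services_weight(scaled, table, area)
            else:
                base = core_services_adapted_weight(profile, table, {area: 1.0})
                big = core_services_adapted_weight(scaled, table, {area: 1.0})
            assert big.weighted == pytest.approx(base.weighted * k, rel=1e-9)
            assert big.need_index == pytest.approx(base.need_index, rel=1e-9)

    def test_need_multiplier_monotonicity(self):
        profile = two_band_profile(100, 300)
        lo = toy_core_table(needs=(0.5, 1.5))
        hi = toy_core_table(needs=(0.5, 1.6))
        assert (
            core_services_weight(profile, hi, "A").weighted
            > core_services_weight(profile, lo, "A").weighted
        )


class TestNeedIndex:
    def test_ratio_definition(self):
        assert need_index(66.0, 100.0) == pytest.approx(0.66)
        assert need_index(123.4, 123.4) == 1.0

    def test_zero_registered_errors(self):
        with pytest.raises(DomainError):
            need_index(1.0, 0.0)

    def test_regional_mean_matches_reference_mean(self, desk_region):
        """Population-weighted mean practice need index lands on the table's
        normalization target (within sampling error of the generator)."""
        from needspend.pipeline import analyse_region

        table = desk_region.analysis_tables["core_services"]
        bundle = analyse_region(
            desk_region.population,
            desk_region.spend,
            {"core_services": table},
            focal_practice_id="FOCAL",
            financial_years=["2019/20"],
        )
        ptable = bundle.years[0].practice_tables["core_services"]
        ref = ptable[ptable["practice_id"] != "FOCAL"]
        realized = ref["weighted"].sum() / ref["registered"].sum()
        assert realized == pytest.approx(table.reference_mean, rel=0.05)


class TestSchema:
    def test_component_weights_must_sum_to_one(self):
        with pytest.raises(SchemaError, match="sum to"):
            toy_core_table(weights={"general_acute": 0.6, "maternity": 0.3})

    def test_nonpositive_multiplier_reports_path(self):
        with pytest.raises(SchemaError, match="positive"):
            toy_core_table(needs=(0.0, 1.0))

    def test_reference_mean_mismatch_detected(self):
        table = toy_core_table(needs=(0.5, 1.5))
        table.reference_mean = 2.0
        with pytest.raises(SchemaError, match="reference_mean"):
            table.validate()

    def test_yaml_round_trip_preserves_evaluation(self, synthetic_tables, tmp_path):
        for scheme, table in synthetic_tables.items():
            path = tmp_path / f"{scheme}.yaml"
            table.to_yaml(path)
            loaded = CoefficientTable.from_yaml(path)
            area = next(iter(table.local_factors))
            for b in table.bands:
                assert loaded.combined_band_need(b) == pytest.approx(
                    table.combined_band_need(b), rel=1e-12
                )
            assert loaded.local_factor_product(area) == pytest.approx(
                table.local_factor_product(area), rel=1e-12
            )
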