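import numpy as np
import pandas as pd
import pytest

from needspend.comparison import (
    aggregate_to_network,
    compare,
    cost_per_weighted_patient,
    net_savings_after_primary_care,
    normality_screen,
    one_sided_z,
    percent_difference,
    percentile_rank,
    total_savings,
)
from needspend.errors import DomainError


class TestCostPerWeightedPatient:
    def test_division(self):
        assert cost_per_weighted_patient(1_000_000, 2_000) == 500.0
        assert cost_per_weighted_patient(0.0, 10.0) == 0.0

    def test_scale_invariance(self):
        assert cost_per_weighted_patient(2e6, 4000) == cost_per_weighted_patient(1e6, 2000)

    def test_nonpositive_weighted_errors(self):
        with pytest.raises(DomainError):
            cost_per_weighted_patient(1.0, 0.0)


class TestNetworkAggregation:
    def practice_frame(self):
        return pd.DataFrame(
            [
                {"practice_id": "a", "network_id": "n1", "spend": 1e6,
                 "weighted": 2000.0, "registered": 2100.0},
                {"practice_id": "b", "network_id": "n1", "spend": 3e6,
                 "weighted": 4000.0, "registered": 4500.0},
                {"practice_id": "c", "network_id": "n2", "spend": 5e5,
                 "weighted": 1000.0, "registered": 900.0},
            ]
        )

    def test_ratio_of_sums_not_mean_of_ratios(self):
        agg = aggregate_to_network(self.practice_frame())
        n1 = agg[agg["network_id"] == "n1"].iloc[0]
        assert n1["cost_pwp"] == pytest.approx(4e6 / 6000)  # 666.67
        # mean of member ratios would be (500 + 750) / 2 = 625: different
        assert n1["cost_pwp"] != pytest.approx(625.0)

    def test_single_practice_network_equals_practice(self):
        agg = aggregate_to_network(self.practice_frame())
        n2 = agg[agg["network_id"] == "n2"].iloc[0]
        assert n2["cost_pwp"] == pytest.approx(500.0)
        assert n2["n_practices"] == 1

    def test_conservation_of_totals(self, desk_region):
        from needspend.pipeline import analyse_region

        bundle = analyse_region(
            desk_region.population, desk_region.spend, desk_region.analysis_tables,
            focal_practice_id="FOCAL", financial_years=["2019/20"],
            schemes=["core_services"], resident_mix=desk_region.resident_mix,
        )
        ptable = bundle.years[0].practice_tables["core_services"]
        ref = ptable[ptable["practice_id"] != "FOCAL"]
        agg = aggregate_to_network(ref)
        assert agg["spend"].sum() == pytest.approx(ref["spend"].sum(), rel=1e-12)
        assert agg["weighted"].sum() == pytest.approx(ref["weighted"].sum(), rel=1e-12)

    def test_unknown_network_lists_offenders(self):
        frame = self.practice_frame().drop(columns=["network_id"])
        with pytest.raises(DomainError, match="b"):
            aggregate_to_network(frame, network_map={"a": "n1", "c": "n2"})


class TestPercentDifference:
    @pytest.mark.parametrize(
        "focal, reference, expected",
        [(492, 715, -31.2), (468, 714, -34.5), (635, 749, -15.2), (700, 700, 0.0)],
    )
    def test_published_rows_and_identity(self, focal, reference, expected):
        assert round(percent_difference(focal, reference), 1) == expected

    def test_nonpositive_reference_errors(self):
        with pytest.raises(DomainError):
            percent_difference(1.0, 0.0)


class TestOneSidedZ:
    def test_focal_at_mean(self):
        z, p = one_sided_z(10.0, [8.0, 10.0, 12.0])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_five_percent_quantile(self):
        rng = np.random.default_rng(4)
        sample = rng.normal(100, 15, size=500)
        focal = sample.mean() - 1.6448536 * sample.std(ddof=1)
        _, p = one_sided_z(focal, sample)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_p_matches_trapezoid_integration(self):
        # independent oracle: trapezoidal integration of the normal density
        grid = np.linspace(-12, 12, 2_000_001)
        dens = np.exp(-grid**2 / 2) / np.sqrt(2 * np.pi)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        sample = [90.0, 100.0, 110.0]  # mean 100, sd 10
        for z_target in np.arange(-6, 2.01, 0.5):
            focal = 100.0 + z_target * 10.0
            z, p = one_sided_z(focal, sample)
            p_oracle = float(np.interp(z, grid, cdf))
            assert z == pytest.approx(z_target, rel=1e-12)
            assert p == pytest.approx(p_oracle, abs=1e-6)

    def test_lower_tail_monotonicity(self):
        sample = [90.0, 100.0, 110.0]
        ps = [one_sided_z(100 - d, sample)[1] for d in (0, 1, 5, 10, 20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_sample_errors(self):
        with pytest.raises(DomainError):
            one_sided_z(1.0, [5.0, 5.0, 5.0])
        with pytest.raises(DomainError):
            one_sided_z(1.0, [1.0, 2.0])

    def test_population_sd_switch(self):
        sample = [90.0, 100.0, 110.0]
        z1, _ = one_sided_z(95.0, sample, ddof=1)
        z0, _ = one_sided_z(95.0, sample, ddof=0)
        assert abs(z0) > abs(z1)  # n denominator gives the smaller sd


class TestNormalityScreen:
    def test_normal_samples_rarely_rejected(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(700, 40, size=300)
            if normality_screen(x).passed:
                passes += 1
        assert passes >= 90

    def test_heavy_tailed_sample_rejected(self):
        x = np.random.default_rng(12).lognormal(6.0, 1.5, size=300)
        screen = normality_screen(x)
        assert screen.shapiro_p < 0.05
        assert not screen.passed

    def test_constant_sample_errors(self):
        with pytest.raises(DomainError):
            normality_screen([3.0, 3.0, 3.0, 3.0])


class TestPercentileRank:
    def test_extremes_of_hundred(self):
        values = list(range(100))
        assert percentile_rank(0, values) == 1
        assert percentile_rank(99, values) == 100

    def test_mid_rank_matches_sort_and_count(self):
        values = [12.0, 5.0, 9.0, 30.0, 22.0, 7.0, 15.0, 3.0, 18.0]
        focal = 9.0
        count = sum(1 for v in sorted(values) if v <= focal)
        import math

        expected = min(100, max(1, math.ceil(100 * count / (len(values) + 1))))
        assert percentile_rank(focal, values) == expected == 40

    def test_empty_errors(self):
        with pytest.raises(DomainError):
            percentile_rank(1.0, [])


class TestSavings:
    def test_published_total_savings(self):
        # (60,587 - 2,696) registered x 0.67 need index x £246 ≈ £9.54M
        weighted = (60_587 - 2_696) * 0.67
        assert round(total_savings(weighted, 246) / 1e6, 2) == 9.54

    def test_zero_difference(self):
        assert total_savings(10_000, 0.0) == 0.0
        assert total_savings(10_000, 50.0) == 500_000.0

    @pytest.mark.parametrize(
        "diff, expected", [(362, 326), (114, 78)]
    )
    def test_net_savings_published(self, diff, expected):
        assert net_savings_after_primary_care(diff, 0.23, 155) == expected

    def test_zero_extra_fraction_is_gross(self):
        assert net_savings_after_primary_care(200.0, 0.0, 155) == 200.0


class TestCompareScaleInvariance:
    def make_networks(self, k=1.0):
        rng = np.random.default_rng(9)
        spend = rng.normal(35e6, 2e6, size=12) * k
        weighted = rng.normal(48_000, 2_000, size=12)
        df = pd.DataFrame({"spend": spend, "weighted": weighted})
        df["cost_pwp"] = df["spend"] / df["weighted"]
        return df

    def test_spend_scaling(self):
        k = 3.5
        base = compare(
            scheme="core_services", financial_year="2019/20",
            focal_spend=20e6, focal_weighted=40_000,
            reference_networks=self.make_networks(),
            practice_costs_pwp=[500.0, 700.0, 720.0],
        )
        scaled = compare(
            scheme="core_services", financial_year="2019/20",
            focal_spend=20e6 * k, focal_weighted=40_000,
            reference_networks=self.make_networks(k),
            practice_costs_pwp=[500.0 * k, 700.0 * k, 720.0 * k],
        )
        assert scaled.focal_cost_pwp == pytest.approx(base.focal_cost_pwp * k, rel=1e-9)
        assert scaled.abs_difference == pytest.approx(base.abs_difference * k, rel=1e-9)
        assert scaled.total_savings == pytest.approx(base.total_savings * k, rel=1e-9)
        assert scaled.pct_difference == pytest.approx(base.pct_difference, rel=1e-9)
        if base.z_statistic is not None:
            assert scaled.z_statistic == pytest.approx(base.z_statistic, rel=1e-9)
            assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)
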