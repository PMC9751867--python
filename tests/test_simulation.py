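"""Monte Carlo engine, binning, analytic oracle, grids and the n-planner."""

import math

import numpy as np
import pytest

from simindex import (
    BIN_LABELS,
    Category,
    SimilarityInterval,
    SimilarityVerdict,
    SimulationConfig,
    StudySetting,
    UNREACHABLE,
    ValidationError,
    analytic_coverage_oracle,
    bin_isim_values,
    compute_isim,
    coverage_gap,
    draw_observed_means,
    find_min_n,
    replicate_table1,
    simulate_isim_distribution,
)
from simindex.simulation import SI_BIN_LABELS, _setting_rng


def verdicts(values):
    """Verdicts whose isim equals each value exactly (0 -> opposite-direction)."""
    return [compute_isim(v, 1.0) if v != 0 else compute_isim(0.2, -1.0) for v in values]


class TestDrawObservedMeans:
    def test_deterministic_given_stream(self):
        setting = StudySetting.matched_setting(0.5, 100)
        a = draw_observed_means(setting, _setting_rng(1, setting), size=100)
        b = draw_observed_means(setting, _setting_rng(1, setting), size=100)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_group_means_are_unbiased(self):
        """Sample mean of the treatment mean approaches its population value."""
        setting = StudySetting.matched_setting(0.5, 1000)
        _, m1 = draw_observed_means(setting, _setting_rng(2, setting), size=10_000)
        se = (1 / math.sqrt(1000)) / math.sqrt(10_000)
        assert abs(m1.mean() - 0.5) < 3 * se

    def test_mean_spread_matches_t_kernel(self):
        """Empirical sd of a group mean is pop_sd/sqrt(n) * sqrt(df/(df-2))."""
        n = 20
        setting = StudySetting.matched_setting(0.5, n)
        _, m1 = draw_observed_means(setting, _setting_rng(3, setting), size=40_000)
        expected = math.sqrt((n - 1) / (n - 3)) / math.sqrt(n)
        assert m1.std() == pytest.approx(expected, rel=0.03)

    def test_normal_mode_spread(self):
        setting = StudySetting.matched_setting(0.5, 100)
        _, m1 = draw_observed_means(
            setting, _setting_rng(4, setting), size=40_000, df_mode="normal"
        )
        assert m1.std() == pytest.approx(0.1, rel=0.03)

    def test_raw_draws_mode_is_centred(self):
        setting = StudySetting.matched_setting(0.5, 30)
        m0, m1 = draw_observed_means(
            setting, _setting_rng(5, setting), size=2000, df_mode="raw_draws"
        )
        assert abs(m0.mean()) < 0.02 and abs(m1.mean() - 0.5) < 0.02

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValidationError):
            StudySetting.matched_setting(0.5, 1)


class TestBinning:
    def test_all_ones_land_in_their_bin(self):
        dist = bin_isim_values(verdicts([1.0, 1.0, 1.0, 1.0]))
        assert dist.bin_percent["(0.9,1.0]"] == pytest.approx(100.0)

    def test_hand_binned_mix_with_opposite(self):
        dist = bin_isim_values(verdicts([0.55, 0.65, 1.45, 0]))
        assert dist.bin_percent["<=0.6"] == pytest.approx(50.0)  # 0.55 + the opposite 0
        assert dist.bin_percent["(0.6,0.7]"] == pytest.approx(25.0)
        assert dist.bin_percent[">1.4"] == pytest.approx(25.0)
        assert dist.n_opposite == 1

    def test_boundary_is_right_closed(self):
        dist = bin_isim_values(verdicts([0.70]))
        assert dist.bin_percent["(0.6,0.7]"] == pytest.approx(100.0)

    def test_undefined_excluded_from_percentages(self):
        vs = verdicts([1.0, 1.0]) + [compute_isim(0.2, 0.0)]
        dist = bin_isim_values(vs)
        assert dist.n_undefined == 1
        assert dist.bin_percent["(0.9,1.0]"] == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            bin_isim_values([])


class TestSimulateDistribution:
    def test_deterministic_given_config(self, fast_config):
        setting = StudySetting.matched_setting(0.5, 50)
        a = simulate_isim_distribution(setting, fast_config)
        b = simulate_isim_distribution(setting, fast_config)
        assert a.bin_percent == b.bin_percent
        assert a.si_coverage_percent == b.si_coverage_percent

    def test_seed_changes_draws(self, fast_config):
        setting = StudySetting.matched_setting(0.5, 50)
        other = SimulationConfig(reps=fast_config.reps, seed=fast_config.seed + 1)
        a = simulate_isim_distribution(setting, fast_config)
        b = simulate_isim_distribution(setting, other)
        assert a.bin_percent != b.bin_percent

    def test_bins_account_for_all_defined_reps(self, fast_config):
        setting = StudySetting(m1_pop=0.2, m_theo=0.5, n0=30, n1=30)
        dist = simulate_isim_distribution(setting, fast_config)
        assert sum(dist.bin_percent.values()) == pytest.approx(100.0, abs=0.01)
        assert dist.n_undefined + (dist.n_reps - dist.n_undefined) == dist.n_reps

    def test_si_coverage_equals_sum_of_si_bins(self, fast_config):
        setting = StudySetting.matched_setting(0.8, 100)
        dist = simulate_isim_distribution(setting, fast_config)
        assert dist.si_coverage_percent == pytest.approx(
            sum(dist.bin_percent[k] for k in SI_BIN_LABELS), abs=0.01
        )

    def test_opposite_reps_fall_in_lowest_bin(self, fast_config):
        """A tiny prediction with noisy control often flips sign; those land at <=0.6."""
        setting = StudySetting(m1_pop=0.1, m_theo=0.1, n0=20, n1=20)
        dist = simulate_isim_distribution(setting, fast_config)
        assert dist.n_opposite > 0
        defined = dist.n_reps - dist.n_undefined
        assert dist.bin_percent["<=0.6"] >= 100.0 * dist.n_opposite / defined - 0.01


class TestOracle:
    def test_normal_kernel_matched_large_effect(self):
        """Frozen quadrature value for the matched 1.00 / n=100 normal case."""
        setting = StudySetting.matched_setting(1.0, 100)
        cov = analytic_coverage_oracle(setting, df_mode="normal")
        assert cov == pytest.approx(0.9423, abs=0.005)

    def test_limits_in_n(self):
        matched = StudySetting.matched_setting(0.5, 10_000)
        assert analytic_coverage_oracle(matched) > 0.995
        mismatch = StudySetting(m1_pop=0.2, m_theo=0.5, n0=10_000, n1=10_000)
        assert analytic_coverage_oracle(mismatch) < 0.001

    @pytest.mark.parametrize(
        "theo,pop,n",
        [(1.0, 1.0, 100), (0.2, 0.2, 50), (0.5, 0.2, 100), (1.0, 1.2, 30)],
    )
    def test_simulation_agrees_with_oracle(self, theo, pop, n):
        setting = StudySetting(m1_pop=pop, m_theo=theo, n0=n, n1=n)
        config = SimulationConfig(reps=10_000, seed=11)
        sim = simulate_isim_distribution(setting, config).si_coverage_percent
        p = analytic_coverage_oracle(setting)
        se = 100 * math.sqrt(max(p * (1 - p), 1e-8) / config.reps)
        assert abs(sim - 100 * p) <= 3 * se + 0.05

    def test_unequal_group_sizes_supported(self):
        setting = StudySetting(m1_pop=0.5, m_theo=0.5, n0=50, n1=200)
        config = SimulationConfig(reps=10_000, seed=12)
        sim = simulate_isim_distribution(setting, config).si_coverage_percent
        p = analytic_coverage_oracle(setting)
        assert abs(sim - 100 * p) < 2.0


class TestGrids:
    def test_small_grid_shape_and_row_sums(self):
        config = SimulationConfig(reps=2000, seed=5)
        dists = replicate_table1(config, effects=(0.2, 0.5), sample_sizes=(20, 50))
        assert len(dists) == 4
        for dist in dists:
            assert set(dist.bin_percent) == set(BIN_LABELS)
            assert sum(dist.bin_percent.values()) == pytest.approx(100.0, abs=0.1)
            assert dist.setting.matched

    def test_gap_grows_with_n(self):
        config = SimulationConfig(reps=10_000, seed=6)
        assert coverage_gap(0.5, 0.2, 1000, config) > coverage_gap(0.5, 0.2, 20, config)

    def test_gap_requires_positive_effects(self):
        with pytest.raises(ValidationError):
            coverage_gap(-0.5, 0.2, 100)


class TestFindMinN:
    def test_matched_large_effect_is_cheap(self):
        n = find_min_n(1.0, 1.0, 90.0)
        assert n is not UNREACHABLE and n <= 100
        assert 100 * analytic_coverage_oracle(StudySetting.matched_setting(1.0, n)) >= 90
        assert 100 * analytic_coverage_oracle(StudySetting.matched_setting(1.0, n - 1)) < 90

    def test_matched_medium_effect_needs_hundreds(self):
        n = find_min_n(0.5, 0.5, 99.0)
        assert 600 <= n <= 1000

    def test_off_ratio_mismatch_unreachable(self):
        assert find_min_n(0.5, 0.2, 50.0) is UNREACHABLE

    def test_ratio_inside_si_reaches_high_coverage(self):
        n = find_min_n(0.9, 1.0, 99.0)
        assert n is not UNREACHABLE

    def test_invalid_target_rejected(self):
        with pytest.raises(ValidationError):
            find_min_n(1.0, 1.0, 0.0)
        with pytest.raises(ValidationError):
            find_min_n(1.0, 1.0, 100.0)


class TestConfigValidation:
    def test_bad_reps_and_mode(self):
        with pytest.raises(ValidationError):
            SimulationConfig(reps=0)
        with pytest.raises(ValidationError):
            SimulationConfig(df_mode="bootstrap")

    def test_setting_validation(self):
        with pytest.raises(ValidationError):
            StudySetting(m1_pop=0.5, m_theo=0.5, n0=100, n1=100, pop_sd=0.0)
        with pytest.raises(ValidationError):
            StudySetting(m1_pop=math.inf, m_theo=0.5, n0=100, n1=100)
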