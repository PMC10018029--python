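"""Derivation arithmetic: rate/probability conversion, cost inflation,
discounting, distribution moment matching and the background-mortality
lookup."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from hfcea import (
    CpiChain,
    InputError,
    LifeTable,
    derive_discount_rate,
    inflate_and_convert_cost,
    load_config,
    moment_match_beta,
    moment_match_gamma,
    monthly_prob_from_period,
    monthly_prob_with_hazard_ratio,
    noncv_mortality,
    save_config,
)

PAPER_CPI = CpiChain(
    multipliers=(1.027, 1.038, 1.06, 1.043, 1.024, 1.018, 1.004),
    cny_per_usd=6.4515,
)


class TestPeriodToMonthConversion:
    @pytest.mark.parametrize(
        "events, at_risk, period, expected",
        [
            (10, 440, 2, 0.0114),  # vulnerable-phase CV death, sac-val arm
            (558, 4187, 27, 0.0053),  # stable-phase CV death, sac-val arm
            (392, 1157, 12, 0.0339),  # stable-phase hospitalization, enalapril
            (0, 440, 2, 0.0),  # no events
            (220, 440, 1, 0.5),  # period 1 returns the proportion exactly
        ],
    )
    def test_published_and_edge_values(self, events, at_risk, period, expected):
        assert monthly_prob_from_period(events, at_risk, period) == pytest.approx(
            expected, abs=5e-5
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        frac=st.floats(1e-6, 0.99),
        period=st.floats(0.5, 120),
    )
    def test_exact_inverse_of_compounding(self, frac, period):
        """Compounding the monthly probability over the period recovers the
        observed event proportion to machine precision."""
        p = monthly_prob_from_period(frac * 1000, 1000, period)
        assert 1 - (1 - p) ** period == pytest.approx(frac, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            monthly_prob_from_period(440, 440, 2)
        with pytest.raises(InputError):
            monthly_prob_from_period(10, 0, 2)
        with pytest.raises(InputError):
            monthly_prob_from_period(10, 440, 0)


class TestHazardRatioConversion:
    def test_published_values(self):
        # HR applied to the event count before conversion
        assert monthly_prob_with_hazard_ratio(392, 1157, 12, 0.79) == pytest.approx(
            0.0256, abs=5e-5
        )
        assert monthly_prob_with_hazard_ratio(392, 1157, 12, 1.0) == pytest.approx(
            0.0339, abs=5e-5
        )
        assert monthly_prob_with_hazard_ratio(392, 1157, 12, 0.0) == 0.0

    def test_identity_at_unit_hr_and_monotone(self):
        base = monthly_prob_from_period(392, 1157, 12)
        assert monthly_prob_with_hazard_ratio(392, 1157, 12, 1.0) == base
        hrs = np.linspace(0.0, 1.5, 20)
        probs = [monthly_prob_with_hazard_ratio(392, 1157, 12, h) for h in hrs]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_hr_scaling_beyond_risk_pool_rejected(self):
        with pytest.raises(ValueError):
            monthly_prob_with_hazard_ratio(392, 1157, 12, 3.0)


class TestCostInflation:
    def test_published_hospitalization_cost(self):
        assert inflate_and_convert_cost(12_351.0, PAPER_CPI) == pytest.approx(
            2361.5, abs=0.05
        )

    def test_published_monthly_standard_cost(self):
        assert inflate_and_convert_cost(
            28_974.0 * 0.082 / 12.0, PAPER_CPI
        ) == pytest.approx(37.9, abs=0.05)

    def test_identity_chain(self):
        cpi = CpiChain(multipliers=(1.0, 1.0), cny_per_usd=1.0)
        assert inflate_and_convert_cost(123.4, cpi) == 123.4

    def test_single_multiplier_hand_arithmetic(self):
        cpi = CpiChain(multipliers=(1.1,), cny_per_usd=6.4515)
        # 100 * 1.1 / 6.4515 = 17.05030...
        assert inflate_and_convert_cost(100.0, cpi) == pytest.approx(
            110.0 / 6.4515, rel=1e-12
        )

    def test_chaining_is_multiplicative(self):
        full = CpiChain(multipliers=(1.027, 1.038, 1.06), cny_per_usd=1.0)
        a = CpiChain(multipliers=(1.027,), cny_per_usd=1.0)
        b = CpiChain(multipliers=(1.038, 1.06), cny_per_usd=1.0)
        chained = inflate_and_convert_cost(
            inflate_and_convert_cost(50.0, a), b
        )
        assert chained == pytest.approx(inflate_and_convert_cost(50.0, full), rel=1e-12)


class TestDiscountRate:
    def test_published_rate(self):
        assert round(derive_discount_rate(PAPER_CPI), 2) == 0.03

    def test_flat_chain(self):
        assert derive_discount_rate(
            CpiChain(multipliers=(1.0, 1.0, 1.0), cny_per_usd=1.0)
        ) == pytest.approx(0.0, abs=1e-14)

    def test_geometric_mean_closed_form(self):
        assert derive_discount_rate(
            CpiChain(multipliers=(1.05, 1.05), cny_per_usd=1.0)
        ) == pytest.approx(0.05, rel=1e-12)


class TestMomentMatching:
    def test_symmetric_beta(self):
        spec = moment_match_beta(0.5, 0.1)
        assert spec.shape_a == pytest.approx(spec.shape_b)

    @pytest.mark.parametrize(
        "mean, sd", [(0.0114, 0.0035), (0.0172, 0.0044), (0.5, 0.1), (0.0698, 0.0036)]
    )
    def test_beta_recovers_moments(self, mean, sd):
        spec = moment_match_beta(mean, sd)
        dist = stats.beta(spec.shape_a, spec.shape_b)
        assert dist.mean() == pytest.approx(mean, rel=1e-3)
        assert dist.std() == pytest.approx(sd, rel=1e-3)
        # cross-check the closed form by numerical integration
        m_num, _ = integrate.quad(lambda x: x * dist.pdf(x), 0, 1)
        assert m_num == pytest.approx(mean, rel=1e-6)

    @pytest.mark.parametrize("mean, sd", [(2361.5, 236.0), (50.5, 18.0)])
    def test_gamma_recovers_moments_and_by_sampling(self, mean, sd):
        spec = moment_match_gamma(mean, sd)
        dist = stats.gamma(spec.shape_a, scale=spec.shape_b)
        assert dist.mean() == pytest.approx(mean, rel=1e-3)
        assert dist.std() == pytest.approx(sd, rel=1e-3)
        draws = spec.draw(np.random.default_rng(7), size=1_000_000)
        assert abs(draws.mean() - mean) < 3 * sd / math.sqrt(draws.size)

    def test_beta_sampling_mean(self):
        spec = moment_match_beta(0.0172, 0.0044)
        draws = spec.draw(np.random.default_rng(11), size=1_000_000)
        assert abs(draws.mean() - 0.0172) < 3 * 0.0044 / math.sqrt(draws.size)

    def test_exponential_special_case(self):
        assert moment_match_gamma(3.7, 3.7).shape_a == pytest.approx(1.0)

    def test_infeasible_moments_rejected(self):
        with pytest.raises(InputError):
            moment_match_beta(0.01, 0.2)  # sd^2 >= mean(1-mean)
        with pytest.raises(InputError):
            moment_match_gamma(-1.0, 1.0)


class TestLifeTable:
    def test_band_lookup(self, life_table):
        assert noncv_mortality(62, life_table) == 0.0004
        assert noncv_mortality(65, life_table) == 0.0007  # boundary enters next band
        assert noncv_mortality(85, life_table) == 0.0054
        assert noncv_mortality(120, life_table) == 0.0054  # clamps to last band

    def test_below_first_band_rejected(self, life_table):
        with pytest.raises(InputError):
            noncv_mortality(40, life_table)

    def test_decreasing_table_rejected(self):
        with pytest.raises(InputError):
            LifeTable(band_starts=(60.0, 65.0), monthly_probs=(0.002, 0.001))


class TestParameterSet:
    def test_validation_flags_bad_inputs(self, base_params, life_table):
        base_params.validate(life_table)  # the shipped base case is valid
        with pytest.raises(InputError, match="p_cvd_early_sv"):
            base_params.replace(p_cvd_early_sv=1.2).validate(life_table)
        with pytest.raises(InputError, match="u_sv_month"):
            base_params.replace(u_sv_month=0.2).validate(life_table)
        with pytest.raises(InputError, match="u_hosp_event"):
            base_params.replace(u_hosp_event=0.1).validate(life_table)
        with pytest.raises(Exception, match="competing"):
            base_params.replace(p_cvd_early_ena=0.6, p_hosp_early_ena=0.5).validate(
                life_table
            )

    def test_range_check_skippable_for_monte_carlo(self, base_params, life_table):
        shifted = base_params.replace(cost_sv_month=300.0)  # outside [25.2, 180.7]
        with pytest.raises(InputError, match="cost_sv_month"):
            shifted.validate(life_table)
        shifted.validate(life_table, check_ranges=False)

    def test_config_round_trip(self, base_inputs, tmp_path):
        params, table, cpi = base_inputs
        path = tmp_path / "cfg.yaml"
        save_config(path, params, table, cpi)
        params2, table2, cpi2 = load_config(path)
        assert params2 == params
        assert table2 == table
        assert cpi2 == cpi

    def test_missing_key_is_named(self, base_inputs, tmp_path):
        import yaml

        from hfcea import base_case_path

        doc = yaml.safe_load(base_case_path().read_text())
        del doc["parameters"]["cost_sv_month"]
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(InputError, match="cost_sv_month"):
            load_config(path)
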