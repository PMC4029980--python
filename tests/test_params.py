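"""Closed-form conversions, distribution specs and config validation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vbprice import (
    ConfigError,
    DistributionSpec,
    ParameterError,
    beta_from_counts,
    beta_from_mean_se,
    cycle_discount_factor,
    gamma_from_moments,
    monthly_risk_from_median,
    prob_from_rate,
    rate_from_median,
    wtp_from_gdp,
)
from vbprice.params import config_from_dict, config_to_dict, load_reference_config

# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "median, expected, tol",
    [
        (1.0, 0.5, 1e-12),                      # by definition of the median
        (5.5, 0.1184087450039788, 1e-12),       # direct evaluation of 1 - 0.5^(1/5.5)
    ],
)
def test_monthly_risk_values(median, expected, tol):
    assert monthly_risk_from_median(median) == pytest.approx(expected, abs=tol)


def test_monthly_risk_no_event_limit():
    assert monthly_risk_from_median(1e9) < 1e-8


@given(st.floats(min_value=0.05, max_value=500.0))
def test_risk_and_rate_formulas_are_identical(median):
    direct = monthly_risk_from_median(median)
    via_rate = prob_from_rate(rate_from_median(median))
    assert via_rate == pytest.approx(direct, rel=1e-12)


@given(st.floats(min_value=0.05, max_value=499.0), st.floats(min_value=0.01, max_value=1.0))
def test_monthly_risk_strictly_decreasing_in_median(median, bump):
    lo, hi = monthly_risk_from_median(median), monthly_risk_from_median(median + bump)
    assert 0.0 < hi < lo < 1.0


def test_rate_from_median_one_month_is_log_two():
    assert rate_from_median(1.0) == pytest.approx(math.log(2.0), rel=1e-12)


def test_prob_from_zero_rate():
    assert prob_from_rate(0.0) == 0.0


@pytest.mark.parametrize(
    "fn, args",
    [
        (monthly_risk_from_median, (0.0,)),
        (monthly_risk_from_median, (-3.0,)),
        (rate_from_median, (-1.0,)),
        (prob_from_rate, (-0.1,)),
        (gamma_from_moments, (0.0, 1.0)),
        (gamma_from_moments, (100.0, -1.0)),
        (beta_from_mean_se, (0.5, 0.6)),       # se^2 >= mean(1-mean)
        (beta_from_mean_se, (1.2, 0.03)),
        (beta_from_counts, (0, 10)),
        (beta_from_counts, (10, 10)),
        (wtp_from_gdp, (20000.0, 4)),
        (wtp_from_gdp, (-5.0, 3)),
    ],
)
def test_invalid_parameters_are_rejected(fn, args):
    with pytest.raises(ParameterError):
        fn(*args)


def test_gamma_moment_fit_reproduces_published_parameterisation():
    spec = gamma_from_moments(770.0, 770.0 / 4.8)
    assert spec.params == pytest.approx((3696.0, 4.8), rel=1e-12)
    assert DistributionSpec.gamma(1336, 4.8).mean() == pytest.approx(278.3333333333334)


def test_gamma_unit_rate_case():
    spec = gamma_from_moments(50.0, 50.0)
    assert spec.params == pytest.approx((50.0, 1.0), rel=1e-12)


@pytest.mark.parametrize(
    "mean, se, alpha, beta",
    [
        (0.76, 0.03, 153.26666666666668, 48.4),
        (0.68, 0.04, 91.8, 43.2),
    ],
)
def test_beta_fit_reproduces_published_utility_parameters(mean, se, alpha, beta):
    spec = beta_from_mean_se(mean, se)
    assert spec.params == pytest.approx((alpha, beta), rel=1e-9)
    assert spec.mean() == pytest.approx(mean, rel=1e-12)
    assert spec.sd() == pytest.approx(se, rel=1e-12)


def test_published_utility_beta_mean():
    assert DistributionSpec.beta(153.26, 48.4).mean() == pytest.approx(
        0.7599920658534166, rel=1e-12
    )


@given(
    st.floats(min_value=1.0, max_value=1e5),
    st.floats(min_value=0.01, max_value=1e4),
)
def test_gamma_moment_round_trip(mean, variance):
    spec = gamma_from_moments(mean, variance)
    assert spec.mean() == pytest.approx(mean, rel=1e-10)
    assert spec.variance() == pytest.approx(variance, rel=1e-10)


@given(
    st.floats(min_value=0.05, max_value=0.95),
    st.floats(min_value=0.005, max_value=0.1),
)
def test_beta_moment_round_trip(mean, se):
    if se * se >= mean * (1 - mean) / 2:
        se = math.sqrt(mean * (1 - mean)) / 4
    spec = beta_from_mean_se(mean, se)
    assert spec.mean() == pytest.approx(mean, rel=1e-10)
    assert spec.sd() == pytest.approx(se, rel=1e-10)


def test_beta_from_counts():
    assert beta_from_counts(10, 100).params == (10.0, 90.0)
    assert beta_from_counts(1, 2).params == (1.0, 1.0)  # uniform on (0,1)
    assert beta_from_counts(47, 451).mean() == pytest.approx(
        0.10421286031042129, rel=1e-12
    )


@pytest.mark.parametrize(
    "gdp, mult, rounding, expected",
    [
        (20517.0, 3, 10_000.0, 60_000.0),
        (20517.0, 2, 10_000.0, 40_000.0),  # 41,034 to the nearest 10,000
        (20000.0, 1, None, 20_000.0),
    ],
)
def test_wtp_from_gdp(gdp, mult, rounding, expected):
    assert wtp_from_gdp(gdp, mult, rounding) == expected


@pytest.mark.parametrize(
    "rate, cycle, expected",
    [
        (0.0, 37, 1.0),
        (0.035, 0, 1.0),
        (0.035, 12, 0.9661835748792271),  # one year back at 3.5%
    ],
)
def test_cycle_discount_factor(rate, cycle, expected):
    assert cycle_discount_factor(rate, cycle, 12) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kind, params",
    [
        ("beta", (0.0, 2.0)),
        ("beta", (2.0, -1.0)),
        ("gamma", (-1.0, 4.8)),
        ("uniform", (5.0, 1.0)),
        ("point", (1.0, 2.0)),
        ("lognormal", (0.0, 1.0)),
    ],
)
def test_distribution_invariants_rejected(kind, params):
    with pytest.raises(ParameterError):
        DistributionSpec(kind, params)


def test_sample_supports():
    rng = np.random.default_rng(0)
    b = DistributionSpec.beta(153.26, 48.4).sample(rng, 1000)
    g = DistributionSpec.gamma(1714, 4.8).sample(rng, 1000)
    u = DistributionSpec.uniform(2880, 2900).sample(rng, 1000)
    assert np.all((b > 0) & (b < 1))
    assert np.all(g > 0)
    assert np.all((u >= 2880) & (u <= 2900))


def test_sampling_reproduces_analytic_means_for_reference_distributions(ref_config):
    """10^5 draws from each fixture distribution land within 3 MC SEs of its mean."""
    rng = np.random.default_rng(12345)
    specs = [
        ref_config.utility_pfs,
        ref_config.utility_pd,
        ref_config.intervention.cost_pfs_monthly,
        ref_config.intervention.cost_pd_early_monthly,
        ref_config.intervention.cost_pd_late_monthly,
        ref_config.intervention.drug_cost_monthly,
        ref_config.comparator.cost_pfs_monthly,
        ref_config.comparator.cost_pd_early_monthly,
        ref_config.intervention.transitions.p_pfs_to_pd,
        ref_config.comparator.transitions.p_pd_to_death,
    ]
    n = 100_000
    for spec in specs:
        draws = spec.sample(rng, n)
        se = spec.sd() / math.sqrt(n)
        assert abs(float(np.mean(draws)) - spec.mean()) < 3.0 * se


# ---------------------------------------------------------------------------
# configuration loading and validation
# ---------------------------------------------------------------------------


def test_reference_fixture_loads_with_published_values(ref_config):
    cfg = ref_config
    assert cfg.horizon_cycles == 120
    assert cfg.cohort_size == 1000
    assert cfg.discount_annual == 0.035
    assert cfg.wtp_thresholds == (20_000.0, 40_000.0, 60_000.0)
    assert cfg.intervention.transitions.point() == pytest.approx((0.104, 0.034, 0.05))
    assert cfg.comparator.transitions.point() == pytest.approx((0.21, 0.042, 0.051))
    assert cfg.intervention.cost_pfs_monthly.mean() == pytest.approx(357.08, abs=0.01)
    assert cfg.comparator.cost_pfs_monthly.mean() == pytest.approx(278.33, abs=0.01)
    assert cfg.intervention.drug_cost_monthly.params == (2880.0, 2900.0)
    assert cfg.comparator.drug_cost_monthly is None
    assert cfg.utility_pfs.mean() == pytest.approx(0.76, abs=1e-4)
    assert cfg.trial.n_intervention == 451


def test_config_round_trips_through_yaml_dict(ref_config):
    again = config_from_dict(config_to_dict(ref_config))
    assert again == ref_config


def test_decimal_comma_values_normalised(ref_config):
    doc = config_to_dict(ref_config)
    doc["discount_annual"] = "0,035"
    cfg = config_from_dict(doc)
    assert cfg.discount_annual == 0.035


def test_validation_rejects_pfs_exit_sum_above_one(ref_config):
    doc = config_to_dict(ref_config)
    arm = [a for a in doc["arms"] if a["role"] == "comparator"][0]
    arm["transitions"]["pfs_to_pd"] = 0.7
    arm["transitions"]["pfs_to_death"] = 0.5
    with pytest.raises(ConfigError) as err:
        config_from_dict(doc)
    assert any("transitions" in f for f, _ in err.value.issues)


def test_validation_rejects_gamma_utility(ref_config):
    doc = config_to_dict(ref_config)
    doc["utilities"]["pfs"] = {"dist": "gamma", "params": [10, 10]}
    with pytest.raises(ConfigError) as err:
        config_from_dict(doc)
    assert any(f == "utility_pfs" for f, _ in err.value.issues)


def test_reference_loader_is_pure():
    assert load_reference_config() == load_reference_config()
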