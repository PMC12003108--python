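"""Parameter records, configuration I/O, and PSA distribution fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strokecea as sc
from strokecea._validate import ConfigurationError, ValidationError
from strokecea.params import (
    MRSDistribution,
    Quantity,
    fit_beta_from_summary,
    fit_dirichlet_from_ranges,
    fit_gamma_from_summary,
    fit_lognormal_from_ci,
    load_parameters,
    parameters_to_dict,
    psa_distributions,
    save_parameters,
    scalar_parameter_names,
    get_scalar,
    set_scalar,
)

CONTROL_DIST = (0.116, 0.211, 0.175, 0.231, 0.112, 0.092, 0.063)


def moment_match_beta(m, sd):
    """Independent closed-form oracle for beta moment matching."""
    nu = m * (1 - m) / sd**2 - 1
    return m * nu, (1 - m) * nu


class TestLoading:
    def test_default_config_matches_published_inputs(self, params):
        assert params.control_mrs_dist.probs == pytest.approx(CONTROL_DIST)
        assert params.rr.point == pytest.approx((1.63, 0.99, 0.92, 1.07, 0.90, 0.58, 0.64))
        assert params.costs.drug_price_per_mg.value == 1.614
        assert params.discount_rate.value == 0.05
        assert params.start_age == 66 and params.n_markov_cycles == 119

    def test_invalid_probability_rejected(self, params):
        doc = parameters_to_dict(params)
        doc["probabilities"]["p_sich_control"] = {"point": 1.5, "low": 0, "high": 1.5}
        with pytest.raises(ValidationError, match="p_sich_control"):
            load_parameters(doc)

    def test_missing_required_key_names_it(self, params):
        doc = parameters_to_dict(params)
        del doc["risk_ratios"]
        with pytest.raises(ConfigurationError, match="risk_ratios"):
            load_parameters(doc)

    def test_missing_discount_rate_defaults_to_5_percent(self, params):
        doc = parameters_to_dict(params)
        del doc["settings"]["discount_rate"]
        assert load_parameters(doc).discount_rate.value == 0.05

    def test_round_trip_is_bit_exact(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        assert load_parameters(str(path)) == params

    def test_mrs_distribution_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            MRSDistribution((0.5, 0.1, 0.1, 0.1, 0.1, 0.05, 0.04))


class TestBetaFit:
    def test_case_fatality_summary(self):
        fit = fit_beta_from_summary(0.21, 0.189, 0.232)
        sd = (0.232 - 0.189) / 3.92
        a, b = moment_match_beta(0.21, sd)
        assert fit.family == "beta"
        assert fit.params == pytest.approx((a, b))
        assert fit.mean() == pytest.approx(0.21, rel=1e-9)
        assert fit.sd() == pytest.approx(sd, rel=1e-9)

    def test_zero_width_range_gives_point_mass(self):
        fit = fit_beta_from_summary(0.5, 0.5, 0.5)
        assert fit.family == "point" and fit.params == (0.5,)
        assert fit.sd() == 0.0

    def test_recurrence_probability_mean_preserved(self):
        fit = fit_beta_from_summary(0.112, 0.096, 0.128)
        assert fit.mean() == pytest.approx(0.112, abs=1e-9)

    def test_boundary_mean_is_clamped_not_fatal(self):
        fit = fit_beta_from_summary(0.0, 0.0, 0.02)
        assert fit.family == "beta"
        assert 0 < fit.mean() < 1e-5


class TestGammaFit:
    def test_recurrent_stroke_cost_summary(self):
        fit = fit_gamma_from_summary(18_380, 13_785, 22_976)
        assert fit.mean() == pytest.approx(18_380, rel=1e-6)
        assert fit.sd() == pytest.approx((22_976 - 13_785) / 3.92, rel=1e-9)

    def test_zero_width_is_point_mass(self):
        assert fit_gamma_from_summary(100, 100, 100).family == "point"


class TestLognormalFit:
    def test_rr_ci_maps_to_log_scale(self):
        fit = fit_lognormal_from_ci(1.63, 1.10, 2.40)
        assert fit.params[0] == pytest.approx(math.log(1.63))
        assert fit.params[1] == pytest.approx((math.log(2.40) - math.log(1.10)) / 3.92)
        assert fit.median() == pytest.approx(1.63, abs=1e-9)

    def test_degenerate_ci_is_point_mass(self):
        assert fit_lognormal_from_ci(1.0, 1.0, 1.0).family == "point"

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValidationError):
            fit_lognormal_from_ci(1.0, 0.0, 2.0)


class TestDirichletFit:
    def test_effective_sample_size_from_published_ranges(self, params):
        fit = fit_dirichlet_from_ranges(params.control_mrs_dist)
        # oracle: per-category implied n = m(1-m)/sd^2, averaged
        ns = []
        for m, lo, hi in zip(CONTROL_DIST, params.control_mrs_dist.low,
                             params.control_mrs_dist.high):
            ns.append(m * (1 - m) / ((hi - lo) / 3.92) ** 2)
        n_eff = np.mean(ns)
        assert sum(fit.params) == pytest.approx(n_eff, rel=1e-9)
        assert n_eff == pytest.approx(300, rel=0.05)

    def test_marginal_means_equal_input(self, params):
        fit = fit_dirichlet_from_ranges(params.control_mrs_dist)
        assert fit.mean() == pytest.approx(CONTROL_DIST, abs=1e-9)

    def test_uniform_input_gives_symmetric_concentration(self):
        dist = MRSDistribution((1 / 7,) * 7)
        ranges = [(1 / 7 - 0.05, 1 / 7 + 0.05)] * 7
        fit = fit_dirichlet_from_ranges(dist, ranges)
        assert np.ptp(fit.params) == pytest.approx(0.0, abs=1e-12)


@given(
    m=st.floats(0.02, 0.98),
    half=st.floats(0.001, 0.4),
)
@settings(max_examples=60, deadline=None)
def test_beta_fit_recovers_mean_and_sd(m, half):
    """Moment matching preserves the source point and range-implied sd to 1%."""
    lo, hi = max(0.0, m - half), min(1.0, m + half)
    sd = (hi - lo) / 3.92
    if sd**2 >= m * (1 - m):
        return
    fit = fit_beta_from_summary(m, lo, hi)
    assert fit.mean() == pytest.approx(m, rel=0.01)
    assert fit.sd() == pytest.approx(sd, rel=0.01)


@given(m=st.floats(10, 1e5), rel_half=st.floats(0.01, 0.9))
@settings(max_examples=60, deadline=None)
def test_gamma_fit_recovers_mean_and_sd(m, rel_half):
    lo, hi = m * (1 - rel_half), m * (1 + rel_half)
    fit = fit_gamma_from_summary(m, lo, hi)
    assert fit.mean() == pytest.approx(m, rel=0.01)
    assert fit.sd() == pytest.approx((hi - lo) / 3.92, rel=0.01)


def test_sample_means_match_analytic_means(params):
    """50,000 seeded draws from every fitted family land within 3 standard
    errors of the analytic mean."""
    rng = np.random.default_rng(20240917)
    n = 50_000
    fits = psa_distributions(params)
    for name, fit in fits.items():
        draws = fit.rvs(rng, size=n)
        if fit.family == "dirichlet":
            se = np.asarray(fit.sd()) / math.sqrt(n)
            np.testing.assert_array_less(
                np.abs(draws.mean(axis=0) - fit.mean()), 3 * se + 1e-12,
                err_msg=name)
        elif fit.family == "point":
            assert np.all(draws == fit.params[0])
        else:
            se = fit.sd() / math.sqrt(n)
            assert abs(draws.mean() - fit.mean()) < 3 * se + 1e-12, name


class TestScalarRegistry:
    def test_every_named_scalar_is_readable(self, params):
        for name in scalar_parameter_names():
            q = get_scalar(params, name)
            assert q.low <= q.value <= q.high, name

    def test_set_scalar_round_trip(self, params):
        ps = set_scalar(params, "rr_mrs6", 1.3)
        assert get_scalar(ps, "rr_mrs6").value == 1.3
        assert params.rr.point[6] == 0.64  # original untouched
        ps = set_scalar(params, "cost_drug_price_per_mg", 25.5)
        assert ps.costs.drug_price_per_mg.value == 25.5

    def test_unknown_name_raises(self, params):
        with pytest.raises(KeyError):
            get_scalar(params, "nope")


def test_quantity_range_must_bracket_point():
    with pytest.raises(ValidationError):
        Quantity(0.5, 0.6, 0.7)
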