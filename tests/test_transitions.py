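"""Rate conversions, background-mortality lookup, and transition-matrix
structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecea._validate import ValidationError
from strokecea.params import Quantity
from strokecea.transitions import (
    annual_rate_to_cycle_prob,
    background_annual_mortality,
    build_transition_matrix,
    nonstroke_death_cycle_prob,
    recurrence_redistribution,
)


class TestRateConversion:
    @pytest.mark.parametrize("annual", [0.112, 0.21, 0.0, 0.5])
    def test_matches_closed_form(self, annual):
        # oracle: r = -ln(1-R)/4, p = 1 - exp(-r)
        r = -math.log(1 - annual) / 4 if annual else 0.0
        assert annual_rate_to_cycle_prob(annual) == pytest.approx(
            1 - math.exp(-r), abs=1e-12)

    def test_published_footnote_value(self):
        # frozen from the closed-form oracle above
        assert annual_rate_to_cycle_prob(0.112) == pytest.approx(0.0292593, abs=1e-7)
        assert annual_rate_to_cycle_prob(0.21) == pytest.approx(0.0572278, abs=1e-7)

    @given(st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        # non-strict: below float resolution distinct inputs can map equal
        pa, pb = annual_rate_to_cycle_prob(a), annual_rate_to_cycle_prob(b)
        assert 0.0 <= pa <= a
        if a < b:
            assert pa <= pb

    def test_strictly_increasing_at_macroscopic_incidences(self):
        ps = [annual_rate_to_cycle_prob(r) for r in (0.01, 0.112, 0.21, 0.5, 0.9)]
        assert all(x < y for x, y in zip(ps, ps[1:]))

    def test_certain_event_rejected(self):
        with pytest.raises(ValidationError):
            annual_rate_to_cycle_prob(1.0)


class TestBackgroundMortality:
    @pytest.mark.parametrize("age, expected", [
        (66, 0.01266), (69.99, 0.01266), (70, 0.02159), (84.99, 0.0634),
        (85, 0.1512), (120, 0.1512),
    ])
    def test_band_lookup(self, params, age, expected):
        assert background_annual_mortality(age, params.mortality) == expected

    def test_age_below_table_rejected(self, params):
        with pytest.raises(ValidationError):
            background_annual_mortality(50, params.mortality)


class TestNonStrokeDeath:
    def test_hr_applied_on_rate_scale(self, params):
        # oracle: annual prob -> rate, x HR, /4, back-transform
        expected = 1 - math.exp(-(-math.log(1 - 0.01266)) * 2.37 / 4)
        assert nonstroke_death_cycle_prob(66, 5, params.mortality, params.hr) == \
            pytest.approx(expected, abs=1e-7)
        assert expected == pytest.approx(0.0075207, abs=1e-6)

    def test_unit_hazard_ratio(self, params):
        got = nonstroke_death_cycle_prob(66, 0, params.mortality, params.hr)
        assert got == pytest.approx(0.0031802, abs=1e-6)

    def test_monotone_in_age_band_and_hr(self, params):
        by_age = [nonstroke_death_cycle_prob(a, 3, params.mortality, params.hr)
                  for a in (66, 70, 75, 80, 85)]
        assert all(x < y for x, y in zip(by_age, by_age[1:]))
        by_state = [nonstroke_death_cycle_prob(66, s, params.mortality, params.hr)
                    for s in range(6)]
        assert all(x <= y for x, y in zip(by_state, by_state[1:]))


class TestRedistribution:
    def test_uniform_over_same_or_worse(self):
        assert recurrence_redistribution(4).tolist() == [0, 0, 0, 0, 0.5, 0.5, 0]
        assert recurrence_redistribution(5).tolist() == [0, 0, 0, 0, 0, 1.0, 0]
        np.testing.assert_allclose(recurrence_redistribution(0)[:6], 1 / 6)

    def test_dead_origin_rejected(self):
        with pytest.raises(ValidationError):
            recurrence_redistribution(6)


class TestTransitionMatrix:
    @pytest.mark.parametrize("age", range(66, 97, 5))
    def test_row_stochastic_and_structured(self, params, age):
        M = build_transition_matrix(age, params)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0) and np.all(M <= 1)
        assert M[6].tolist() == [0, 0, 0, 0, 0, 0, 1]
        # no improvement: entries below the diagonal (alive states) are zero
        for j in range(1, 6):
            assert np.all(M[j, :j] == 0)

    def test_death_entry_composes_both_pathways(self, params):
        # oracle: hand-composition of recurrence deaths and non-stroke deaths
        p_rec = annual_rate_to_cycle_prob(0.112)
        p_ns = 1 - math.exp(-(-math.log(1 - 0.01266)) * 2.37 / 4)
        expected = p_rec * 0.21 + (1 - p_rec) * p_ns
        M = build_transition_matrix(66, params)
        assert M[5, 6] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0134449, abs=1e-6)

    def test_identity_under_zero_hazards(self, params):
        quiet = params.replace(
            annual_recurrence=Quantity(0.0, 0.0, 0.0),
            mortality=params.mortality.__class__(
                tuple(b.__class__(b.age_low, b.age_high, 0.0)
                      for b in params.mortality.bands)),
        )
        np.testing.assert_allclose(build_transition_matrix(70, quiet), np.eye(7),
                                   atol=1e-15)

    def test_zero_case_fatality_isolates_nonstroke_deaths(self, params):
        ps = params.replace(recurrence_case_fatality=Quantity(0.0, 0.0, 0.0))
        M = build_transition_matrix(66, ps)
        p_rec = annual_rate_to_cycle_prob(ps.annual_recurrence.value)
        for j in range(6):
            p_ns = nonstroke_death_cycle_prob(66, j, ps.mortality, ps.hr)
            assert M[j, 6] == pytest.approx((1 - p_rec) * p_ns, abs=1e-15)

    def test_death_entry_monotone_in_hr(self, params):
        scaled = params.replace(hr=params.hr.__class__(
            tuple(h * 1.5 for h in params.hr.point),
            tuple(h * 1.5 for h in params.hr.low),
            tuple(h * 1.5 for h in params.hr.high)))
        M0 = build_transition_matrix(66, params)
        M1 = build_transition_matrix(66, scaled)
        for j in range(6):
            assert M1[j, 6] > M0[j, 6]


def test_cohort_propagation_matches_microsimulation(params):
    """Repeated matrix application agrees with a seeded 100,000-walker
    individual-level simulation within 3 binomial standard errors."""
    from conftest import microsimulate

    n_walkers, k = 100_000, 20
    x = params.control_mrs_dist.as_array()
    occ_micro = microsimulate(x, params, k, n_walkers, seed=11)
    for t in range(1, k + 1):
        M = build_transition_matrix(params.start_age + 0.25 * t, params)
        x = x @ M
    se = np.sqrt(x * (1 - x) / n_walkers)
    # 3.6 SE: Bonferroni-adjusted for the 7 simultaneous per-state checks at
    # the same family-wise level as a single 3-SE comparison
    np.testing.assert_array_less(np.abs(occ_micro[-1] - x), 3.6 * se + 1e-9)
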