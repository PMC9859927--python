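"""Supply schedules, policy algebra, feasibility and the policy swap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxalloc import (SupplySchedule, VaccinationPolicy, VulnerableScenario,
                      build_tilde_policy, chi_rate, cumulative, is_feasible,
                      prioritized_policy, two_group_example)


def unit_rate_group2_policy():
    """Group 2 vaccinated at unit rate on [0, 1], nothing else."""
    return VaccinationPolicy([0.0, 1.0], [[0.0, 1.0]])


class TestChiRate:
    def test_uncapped_linear_supply_gives_full_rate(self):
        # A = 1, B = max(t, 1): the supply cap never binds
        sched = SupplySchedule([0.0], [1.0], [0.0, 1.0], [1.0, 1.0],
                               b_final_slope=1.0)
        for t in [0.0, 0.5, 1.0, 3.0]:
            assert chi_rate(sched, t) == pytest.approx(1.0)

    def test_constant_supply_exhausts(self):
        eps = 0.25
        sched = SupplySchedule.constant(rate=1.0, supply=eps)
        assert chi_rate(sched, 0.1) == pytest.approx(1.0)   # t < eps
        assert chi_rate(sched, 0.5) == pytest.approx(0.0)   # supply gone

    def test_rate_limited_supply_runs_until_cap(self, capped_unit_schedule):
        assert chi_rate(capped_unit_schedule, 0.5) == pytest.approx(1.0)
        assert chi_rate(capped_unit_schedule, 1.5) == pytest.approx(0.0)

    def test_int_chi_matches_segments(self, capped_unit_schedule):
        assert capped_unit_schedule.int_chi(0.7) == pytest.approx(0.7)
        assert capped_unit_schedule.int_chi(5.0) == pytest.approx(1.0)


class TestCumulative:
    def test_zero_at_time_zero(self):
        pol = unit_rate_group2_policy()
        np.testing.assert_array_equal(cumulative(pol, 0.0), [0.0, 0.0])

    def test_halfway_through_unit_rate(self):
        pol = unit_rate_group2_policy()
        np.testing.assert_allclose(cumulative(pol, 0.5), [0.0, 0.5])

    def test_two_phase_swap_policy(self):
        # vulnerable-first policy with eps = 0.3: W(1) = (0.3, 0.7)
        pol = VaccinationPolicy([0.0, 0.3, 1.0],
                                [[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(cumulative(pol, 1.0), [0.3, 0.7])

    @settings(deadline=None, derandomize=True)
    @given(t1=st.floats(0.01, 5.0), t2=st.floats(0.01, 5.0),
           r1=st.floats(0, 2), r2=st.floats(0, 2))
    def test_nondecreasing_and_piecewise_linear(self, t1, t2, r1, r2):
        pol = VaccinationPolicy([0.0, t1, t1 + t2], [[r1], [r2]])
        ts = np.linspace(0, t1 + t2 + 1, 57)
        W = pol.cumulative(ts)
        assert np.all(np.diff(W[:, 0]) >= -1e-12)
        # exact linearity inside the first interval
        mid = pol.cumulative(0.5 * t1)[0]
        assert mid == pytest.approx(0.5 * t1 * r1, abs=1e-12)


class TestFeasibility:
    def test_zero_policy_feasible(self, capped_unit_schedule, two_group_default):
        ok, report = is_feasible(VaccinationPolicy.zero(2),
                                 capped_unit_schedule, two_group_default.params)
        assert ok and report == []

    def test_printed_policy_feasible(self, capped_unit_schedule,
                                     two_group_default):
        ok, _ = is_feasible(unit_rate_group2_policy(), capped_unit_schedule,
                            two_group_default.params)
        assert ok

    def test_rate_cap_violation_detected_at_start(self, two_group_default):
        sched = SupplySchedule.rate_limited(rate=0.5, total_supply=1.0)
        ok, report = is_feasible(unit_rate_group2_policy(), sched,
                                 two_group_default.params)
        assert not ok
        assert "rate constraint" in report[0] and "t=0" in report[0]

    def test_supply_cap_violation_detected(self, two_group_default):
        sched = SupplySchedule.constant(rate=2.0, supply=0.5)
        ok, report = is_feasible(unit_rate_group2_policy(), sched,
                                 two_group_default.params)
        assert not ok and "supply constraint" in report[0]

    def test_over_vaccinating_a_group_detected(self, capped_unit_schedule,
                                               two_group_default):
        pol = VaccinationPolicy([0.0, 1.0], [[1.0, 0.0]])   # 1 > N_1 = 0.3
        ok, report = is_feasible(pol, capped_unit_schedule,
                                 two_group_default.params)
        assert not ok and "over-vaccinated" in report[0]


class TestTildePolicy:
    def test_swap_of_printed_policy_matches_closed_form(self):
        # redirecting the infectious-first policy gives exactly the
        # two-phase vulnerable-first policy
        eps = 0.3
        pol = build_tilde_policy(unit_rate_group2_policy(), eps)
        np.testing.assert_allclose(pol.breakpoints, [0.0, 0.3, 1.0])
        np.testing.assert_allclose(pol.rates, [[1.0, 0.0], [0.0, 1.0]])

    def test_zero_policy_stays_zero(self):
        pol = build_tilde_policy(VaccinationPolicy.zero(2), 0.5)
        assert pol.support_end == 0.0

    def test_epsilon_zero_silences_group_one_only(self):
        pol = build_tilde_policy(unit_rate_group2_policy(), 0.0)
        np.testing.assert_allclose(pol.cumulative(1.0), [0.0, 1.0])

    def test_epsilon_beyond_group_size_rejected(self):
        with pytest.raises(ValueError, match="over-vaccinate"):
            build_tilde_policy(unit_rate_group2_policy(), 0.5, group_size=0.3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(eps=st.floats(0.01, 0.9), r1=st.floats(0.0, 1.0),
           r2=st.floats(0.1, 1.0))
    def test_swap_never_exceeds_original_total_doses(self, eps, r1, r2):
        pol = VaccinationPolicy([0.0, 0.5, 1.2], [[r1, r2], [0.0, r2]])
        tilde = build_tilde_policy(pol, eps)
        for t in np.linspace(0, 1.5, 31):
            assert tilde.cumulative(t).sum() <= pol.cumulative(t).sum() + 1e-9
            # total instantaneous rate never increased
            assert tilde.rate_at(t).sum() <= pol.rate_at(t).sum() + 1e-12


class TestVulnerableScenario:
    def test_witness_condition_for_infectious_first_policy(self):
        # by tau = 1 the infectious-first policy has given no doses to
        # group 1 but a full unit in total
        scen = VulnerableScenario(epsilon=0.3, alpha=0.5, tau=1.0, w=0.5)
        assert scen.condition_holds(unit_rate_group2_policy())
        assert not scen.condition_holds(VaccinationPolicy.zero(2))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            VulnerableScenario(epsilon=0.0)
        with pytest.raises(ValueError):
            VulnerableScenario(epsilon=0.1, sigma=1.5)


class TestPrioritizedPolicy:
    def test_infectious_first_order_reproduces_printed_policy(
            self, capped_unit_schedule, two_group_default):
        pol = prioritized_policy([1, 0], capped_unit_schedule,
                                 two_group_default.params,
                                 per_group_caps=[0.3, 1.0])
        np.testing.assert_allclose(pol.breakpoints, [0.0, 1.0])
        np.testing.assert_allclose(pol.rates, [[0.0, 1.0]])

    def test_vulnerable_first_order_reproduces_swap_policy(
            self, capped_unit_schedule, two_group_default):
        pol = prioritized_policy([0, 1], capped_unit_schedule,
                                 two_group_default.params,
                                 per_group_caps=[0.3, 1.0])
        np.testing.assert_allclose(pol.breakpoints, [0.0, 0.3, 1.0])
        np.testing.assert_allclose(pol.rates, [[1.0, 0.0], [0.0, 1.0]])

    def test_zero_caps_give_zero_policy(self, capped_unit_schedule,
                                        two_group_default):
        pol = prioritized_policy([0, 1], capped_unit_schedule,
                                 two_group_default.params,
                                 per_group_caps=[0.0, 0.0])
        assert pol.support_end == 0.0

    def test_cumulative_total_is_supply_identity(self, capped_unit_schedule,
                                                 two_group_default):
        # sum_i W_i(t) = min(int_0^t chi, total caps)
        caps = [0.3, 1.0]
        pol = prioritized_policy([0, 1], capped_unit_schedule,
                                 two_group_default.params, per_group_caps=caps)
        for t in [0.2, 0.5, 1.0, 2.0]:
            expected = min(capped_unit_schedule.int_chi(t), sum(caps))
            assert pol.cumulative(t).sum() == pytest.approx(expected, abs=1e-9)

    def test_output_always_feasible(self, two_group_default, rng):
        for _ in range(5):
            rate = rng.uniform(0.2, 2.0)
            supply = rng.uniform(0.1, 1.3)
            sched = SupplySchedule.rate_limited(rate, supply)
            caps = rng.uniform(0, 1) * two_group_default.params.N
            pol = prioritized_policy([1, 0], sched, two_group_default.params,
                                     per_group_caps=caps)
            ok, report = is_feasible(pol, sched, two_group_default.params)
            assert ok, report
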