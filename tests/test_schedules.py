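"""Delivery schedules: construction rules, dose-day accounting, equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import custress as cs
from custress.errors import IncompatibleScheduleError, InvalidParameterError
from custress.schedules import dose_days_from_conc


class TestGradual:
    def test_linear_ramp_values(self):
        sched = cs.build_gradual_schedule(1.0, 9)
        assert sched.conc == tuple(i / 9 for i in range(1, 10))
        assert sched.final_conc == 1.0
        assert sched.n_days == 9

    def test_single_day_ramp_equals_abrupt_step(self):
        ramp = cs.build_gradual_schedule(1.0, 1)
        step = cs.build_abrupt_schedule(1.0, 1, 1)
        assert ramp.conc == step.conc == (1.0,)

    @pytest.mark.parametrize("final,days", [(0.0, 9), (-1.0, 9), (1.0, 0)])
    def test_invalid_parameters(self, final, days):
        with pytest.raises(InvalidParameterError):
            cs.build_gradual_schedule(final, days)


class TestAbrupt:
    def test_step_on_day_five(self):
        sched = cs.build_abrupt_schedule(1.0, 9, 5)
        assert sched.conc[:4] == (0.0,) * 4
        assert sched.conc[4:] == (1.0,) * 5

    def test_step_at_start_is_constant(self):
        assert cs.build_abrupt_schedule(1.0, 9, 1).conc == (1.0,) * 9

    @pytest.mark.parametrize("step", [0, 10])
    def test_step_day_out_of_range(self, step):
        with pytest.raises(InvalidParameterError):
            cs.build_abrupt_schedule(1.0, 9, step)


class TestDoseDays:
    def test_control_is_zero(self):
        assert cs.dose_days(cs.build_control_schedule(9)).value == 0.0

    def test_default_pair_is_five_exactly(self):
        # brute-force daily sums: sum(i/9) = 5 and 5 x 1 mM = 5
        grad = cs.dose_days(cs.build_gradual_schedule(1.0, 9)).value
        abr = cs.dose_days(cs.build_abrupt_schedule(1.0, 9, 5)).value
        assert grad == pytest.approx(5.0, abs=1e-12)
        assert abr == 5.0
        assert grad == abr

    @given(c=st.floats(min_value=1e-3, max_value=100.0), n=st.integers(1, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_closed_forms(self, c, n):
        # ramp: c(n+1)/2; step at s: c(n-s+1); the default (n=9, s=5) ties.
        grad = cs.dose_days(cs.build_gradual_schedule(c, n)).value
        assert grad == pytest.approx(c * (n + 1) / 2, rel=1e-12)
        s = min(5, n)
        abr = cs.dose_days(cs.build_abrupt_schedule(c, n, s)).value
        assert abr == pytest.approx(c * (n - s + 1), rel=1e-12)

    @given(c=st.floats(min_value=1e-3, max_value=100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_default_pairing_equal_for_any_concentration(self, c):
        grad = cs.dose_days(cs.build_gradual_schedule(c, 9))
        abr = cs.dose_days(cs.build_abrupt_schedule(c, 9, 5))
        assert grad.value == pytest.approx(abr.value, rel=1e-12)
        assert cs.build_gradual_schedule(c, 9).final_conc == cs.build_abrupt_schedule(c, 9, 5).final_conc

    @given(
        a=st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=12),
        b=st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additive_over_concatenation(self, a, b):
        total = dose_days_from_conc(a + b)
        assert total == pytest.approx(
            dose_days_from_conc(a) + dose_days_from_conc(b), rel=1e-12, abs=1e-12
        )


class TestEquivalence:
    def test_default_pair_equivalent(self, default_schedules):
        rep = cs.check_equivalence(default_schedules["gradual"], default_schedules["abrupt"])
        assert rep.equivalent
        assert rep.dose_days_a == pytest.approx(5.0)

    def test_gradual_vs_control_not_equivalent(self, default_schedules):
        rep = cs.check_equivalence(default_schedules["gradual"], default_schedules["control"])
        assert not rep.equivalent

    def test_self_equivalence(self, default_schedules):
        for sched in default_schedules.values():
            assert cs.check_equivalence(sched, sched).equivalent

    def test_unequal_lengths_rejected(self):
        with pytest.raises(IncompatibleScheduleError):
            cs.check_equivalence(
                cs.build_gradual_schedule(1.0, 9), cs.build_gradual_schedule(1.0, 8)
            )


class TestScheduleType:
    def test_concentrations_must_not_decrease(self):
        with pytest.raises(InvalidParameterError):
            cs.TreatmentSchedule("gradual", (0.5, 0.4))

    def test_control_must_be_zero(self):
        with pytest.raises(InvalidParameterError):
            cs.TreatmentSchedule("control", (0.0, 0.1))

    def test_roundtrip_serialization(self, tmp_path, default_schedules):
        path = tmp_path / "sched.tsv"
        for sched in default_schedules.values():
            cs.schedules.write_schedule(sched, path)
            back = cs.schedules.read_schedule(path, sched.label)
            assert back == sched
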