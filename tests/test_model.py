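"""Unit and property tests for the model right-hand sides."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagodyn import (
    N_STATES,
    ModelParameters,
    PerturbationSchedule,
    StepFunction,
    derivatives,
    mast_cell_source,
    reference_parameters,
)

REF = reference_parameters()


class TestMastCellSource:
    def test_zero_before_onset(self):
        assert mast_cell_source(REF.t1 - 0.1, REF) == 0.0
        assert mast_cell_source(0.0, REF) == 0.0

    def test_value_at_onset_is_twice_amplitude(self):
        # envelope = k_e0, exp(0) = 1, cos(0) = 1 at the onset instant
        assert mast_cell_source(REF.t1, REF) == pytest.approx(2 * REF.k_e0, rel=1e-12)
        assert mast_cell_source(3.5, REF) == pytest.approx(22.4928, abs=1e-10)

    def test_rejects_nonfinite_time(self):
        with pytest.raises(ValueError):
            mast_cell_source(math.nan, REF)

    @given(st.floats(0.0, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_twice_envelope(self, t):
        """|U - A(t)| <= A(t): the oscillation never exceeds the envelope."""
        u = mast_cell_source(t, REF)
        if t < REF.t1:
            assert u == 0.0
        else:
            a = REF.k_e0 * math.exp(-REF.k_k1 * (t - REF.t1))
            assert abs(u - a) <= a * (1 + 1e-12)
            assert u >= 0.0

    def test_continuous_after_onset(self):
        ts = np.linspace(REF.t1, 36.0, 4001)
        us = np.array([mast_cell_source(t, REF) for t in ts])
        assert np.max(np.abs(np.diff(us))) < 0.5  # no jumps on a fine grid


class TestDerivatives:
    def test_zero_state_before_onset_is_stationary(self):
        d = derivatives(1.0, np.zeros(N_STATES), REF)
        assert np.all(d == 0.0)

    def test_residual_histamine_transfer(self):
        """Histamine gains exactly what residual histamine loses (I_mc = 1)."""
        y = np.zeros(N_STATES)
        y[0] = 1.0
        d = derivatives(1.0, y, REF)
        assert d[0] == pytest.approx(-REF.k_rhch)
        assert d[1] == pytest.approx(REF.k_rhch)
        assert np.all(d[2:] == 0.0)

    def test_histamine_drives_receptors_and_selectins(self):
        y = np.zeros(N_STATES)
        y[1] = 1.0
        sched = PerturbationSchedule(I_mc=StepFunction.constant(0.0))
        d = derivatives(1.0, y, REF, sched)
        assert d[1] == pytest.approx(-REF.k_hs)
        assert d[2] == pytest.approx(REF.k_hchrt / (REF.k_hchrb + 1.0))
        assert d[3] == pytest.approx(REF.k_hcst / (REF.k_hcsb + 1.0))

    def test_all_ones_schedule_is_bitwise_unperturbed(self):
        y = np.linspace(0.1, 0.8, N_STATES)
        explicit = PerturbationSchedule()
        for t in (0.0, 2.0, 5.0, 12.0):
            d0 = derivatives(t, y, REF, None)
            d1 = derivatives(t, y, REF, explicit)
            assert np.array_equal(d0, d1)

    def test_source_enters_only_residual_histamine(self):
        """The source contributes additively to dC_rh and nowhere else."""
        y = np.linspace(0.1, 0.8, N_STATES)
        before = derivatives(REF.t1 - 0.5, y, REF)
        after = derivatives(REF.t1 + 0.0, y, REF)
        u = mast_cell_source(REF.t1, REF)
        assert after[0] - before[0] == pytest.approx(u)
        assert np.allclose(after[1:], before[1:])

    def test_rejects_nonfinite_state(self):
        y = np.zeros(N_STATES)
        y[3] = np.inf
        with pytest.raises(ValueError):
            derivatives(0.0, y, REF)

    @given(
        st.lists(st.floats(0.0, 5.0), min_size=N_STATES, max_size=N_STATES),
        st.floats(0.0, 30.0),
        st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
    )
    @settings(max_examples=80, deadline=None)
    def test_nonneg_orthant_is_invariant(self, y, t, levels):
        """Any zero component has derivative >= 0: trajectories cannot
        analytically exit the non-negative orthant."""
        y = np.array(y)
        y[0] = 0.0  # always test at least one active zero
        sched = PerturbationSchedule(*[StepFunction.constant(lv) for lv in levels])
        d = derivatives(t, y, REF, sched)
        for i in range(N_STATES):
            if y[i] == 0.0:
                assert d[i] >= 0.0


class TestStepFunction:
    def test_right_continuous_at_breakpoint(self):
        f = StepFunction.step(20.0, 0.0)
        assert f(19.999) == 1.0
        assert f(20.0) == 0.0
        assert f(25.0) == 0.0

    def test_validates_levels_and_breakpoints(self):
        with pytest.raises(ValueError):
            StepFunction((1.0, 1.0), (1.0, 0.5, 0.0))
        with pytest.raises(ValueError):
            StepFunction((1.0,), (1.0, 1.5))


class TestModelParameters:
    def test_reference_values_round_trip(self, tmp_path):
        path = tmp_path / "params.txt"
        REF.to_file(path)
        again = ModelParameters.from_file(path)
        assert again == REF

    def test_rejects_invalid_beta_and_negatives(self):
        with pytest.raises(ValueError):
            REF.with_updates(beta=1.0)
        with pytest.raises(ValueError):
            REF.with_updates(k_rhch=-0.1)
        with pytest.raises(ValueError):
            REF.with_updates(k_hchrb=0.0)

    def test_array_round_trip_preserves_order(self):
        x = REF.to_array()
        assert x.shape == (22,)
        assert ModelParameters.from_array(x) == REF
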