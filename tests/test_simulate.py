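"""Simulator tests: closed forms, scenarios, solver robustness."""

import numpy as np
import pytest

from phagodyn import (
    PerturbationSchedule,
    Scenario,
    StepFunction,
    default_initial_state,
    run_scenario,
    simulate,
)


def two_compartment(t, c0, k1, k2):
    """C_h(t) for dC_rh = -k1 C_rh, dC_h = k1 C_rh - k2 C_h, C_h(0)=0."""
    return c0 * k1 * (np.exp(-k2 * t) - np.exp(-k1 * t)) / (k1 - k2)


class TestClosedForms:
    def test_pure_decay_without_source(self, ref_params):
        """With the source amplitude zeroed, residual histamine is a plain
        exponential decay and histamine follows the two-compartment form."""
        p = ref_params.with_updates(k_e0=0.0, k_hchrt=0.0, k_hcst=0.0)
        c0 = 2.0
        y0 = default_initial_state(c0)
        grid = np.linspace(0.0, 16.0, 33)
        traj = simulate(p, None, grid, y0)
        expected_rh = c0 * np.exp(-p.k_rhch * grid)
        assert np.allclose(traj.state("C_rh"), expected_rh, rtol=1e-5)
        expected_h = two_compartment(grid, c0, p.k_rhch, p.k_hs)
        assert np.allclose(traj.state("C_h"), expected_h, rtol=1e-5, atol=1e-8)
        # downstream production disabled, so everything else stays at zero
        for name in ("C_hr", "C_s", "C_pmnp", "C_mpp", "C_pmn", "C_mp"):
            assert np.allclose(traj.state(name), 0.0, atol=1e-9)

    def test_grid_refinement_stability(self, ref_params, halfhour_grid):
        a = simulate(ref_params, None, halfhour_grid)
        b = simulate(ref_params, None, halfhour_grid, rtol=5e-7, atol=5e-10)
        scale = np.abs(a.states).max(axis=0) + 1e-12
        assert np.max(np.abs(a.states - b.states) / scale) < 1e-4


class TestQualitativeDynamics:
    def test_residual_histamine_decays_then_oscillates(self, ref_params, halfhour_grid):
        traj = simulate(ref_params, None, halfhour_grid)
        c_rh = traj.state("C_rh")
        early = c_rh[halfhour_grid <= 2.0]
        assert np.all(np.diff(early) < 0)  # strict decay before onset
        late = c_rh[halfhour_grid >= 3.5]
        assert np.any(np.diff(late) > 0) and np.any(np.diff(late) < 0)  # non-monotone

    def test_phagocytes_accumulate(self, ref_params, halfhour_grid):
        traj = simulate(ref_params, None, halfhour_grid)
        for name in ("C_pmn", "C_mp"):
            vals = traj.state(name)
            assert np.all(np.diff(vals) >= -1e-10)
            assert vals[-1] > vals[0] > -1e-12

    def test_states_never_go_negative(self, ref_params):
        grid = np.linspace(0.0, 36.0, 145)
        traj = simulate(ref_params, None, grid)
        assert traj.states.min() >= -1e-8


class TestSchedules:
    def test_constant_one_schedule_matches_default(self, ref_params, halfhour_grid):
        explicit = PerturbationSchedule(
            *[StepFunction.constant(1.0) for _ in range(5)]
        )
        a = simulate(ref_params, None, halfhour_grid)
        b = simulate(ref_params, explicit, halfhour_grid)
        assert np.array_equal(a.states, b.states)

    def test_lowering_indicators_never_increases_recruitment(self, ref_params):
        grid = np.linspace(0.0, 24.0, 49)
        rng = np.random.default_rng(11)
        full = simulate(ref_params, None, grid)
        for _ in range(3):
            levels = rng.uniform(0.0, 1.0, size=5)
            sched = PerturbationSchedule(*[StepFunction.constant(lv) for lv in levels])
            low = simulate(ref_params, sched, grid)
            assert np.all(low.state("C_pmn") <= full.state("C_pmn") + 1e-8)
            assert np.all(low.state("C_mp") <= full.state("C_mp") + 1e-8)


class TestScenarios:
    def test_control_scenario_is_identity(self, ref_params):
        perturbed, control = run_scenario(Scenario("control"), ref_params, dt=1.0)
        assert np.array_equal(perturbed.states, control.states)

    def test_receptor_block_cuts_pmn_after_switch(self, ref_params):
        scn = Scenario("receptor_ko_after", switch_time=20.0, horizon=36.0)
        perturbed, control = run_scenario(scn, ref_params, dt=0.5)
        pre = perturbed.times <= 20.0
        assert np.allclose(
            perturbed.state("C_pmn")[pre], control.state("C_pmn")[pre], rtol=1e-6
        )
        post = perturbed.times >= 22.0
        assert np.all(
            perturbed.state("C_pmn")[post] < control.state("C_pmn")[post]
        )
        tail = perturbed.state("C_pmn")[perturbed.times >= 30.0]
        assert np.all(np.diff(tail) < 0)  # recruitment eventually decays

    def test_full_mastcell_block_silences_cascade(self, ref_params):
        scn = Scenario("mastcell_ko", ko_level=0.0, horizon=16.0)
        perturbed, _ = run_scenario(scn, ref_params, dt=0.5)
        for name in ("C_h", "C_hr", "C_s", "C_pmnp", "C_pmn"):
            assert np.allclose(perturbed.state(name), 0.0, atol=1e-9)

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="control"):
            Scenario("typo")


class TestPlumbing:
    def test_rejects_bad_grid_and_state(self, ref_params):
        with pytest.raises(ValueError):
            simulate(ref_params, None, [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            simulate(ref_params, None, [0.0, 1.0], y0=-np.ones(8))

    def test_trajectory_csv_round_trip(self, ref_params, tmp_path):
        from phagodyn.simulate import trajectory_from_csv

        traj = simulate(ref_params, None, np.linspace(0, 4, 5))
        path = tmp_path / "traj.csv"
        traj.to_csv(path, scenario="control", run_id="r1")
        df = trajectory_from_csv(path)
        assert len(df) == 5 * 8
        c_rh = df[df["variable"] == "C_rh"]["value"].to_numpy()
        assert np.allclose(c_rh, traj.state("C_rh"))
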