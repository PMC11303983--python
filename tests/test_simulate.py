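import numpy as np
import pytest

from symtip import (
    Direction,
    SimulationSettings,
    SystemState,
    integrate_step,
    make_driver_sequence,
    make_temporal_pattern,
    mirror_state,
    run_direction,
    run_temporal,
)


def test_settings_validation():
    with pytest.raises(ValueError, match="multiple"):
        SimulationSettings(step_duration=1500.0, immigration_interval=1000.0)
    with pytest.raises(ValueError):
        SimulationSettings(solver_rel_tol=0.0)
    with pytest.raises(ValueError):
        SimulationSettings(immigration_amount=-1.0)
    assert SimulationSettings().n_chunks == 1000


def test_bacteria_free_relaxation_matches_closed_form(params):
    """Without bacteria and oxidation the substrates relax linearly toward
    background; the integrator must match O(t) = O_b + (O_0-O_b)exp(-a_O t)."""
    p = params.with_overrides(c=0.0)
    settings = SimulationSettings(
        step_duration=4000.0, immigration_amount=0.0, early_exit=False
    )
    state0 = SystemState(0.0, 0.0, 20.0, 80.0, 3.0)
    a_O, a_S = 0.5, 0.002
    out = integrate_step(state0, p, a_O, a_S, settings).state
    t = settings.step_duration
    assert out.O == pytest.approx(100 + (20 - 100) * np.exp(-a_O * t), rel=1e-6)
    assert out.S == pytest.approx(100 + (80 - 100) * np.exp(-a_S * t), rel=1e-6)
    assert out.P == pytest.approx(10 + (3 - 10) * np.exp(-p.alpha_P * t), rel=1e-6)
    assert out.N_CB == 0.0 and out.N_SB == 0.0


def test_integrate_step_mirror_symmetry(params, fast_settings):
    """For symmetric parameters, mirroring the state and swapping the drivers
    mirrors the entire trajectory."""
    settings = fast_settings.replace(step_duration=10_000.0)
    state0 = SystemState(3e4, 2e8, 5.0, 60.0, 1.0)
    a_O, a_S = 0.03, 0.4
    fwd = integrate_step(state0, params, a_O, a_S, settings).state
    mir = integrate_step(mirror_state(state0), params, a_S, a_O, settings).state
    assert mir.as_array() == pytest.approx(mirror_state(fwd).as_array(), rel=1e-6, abs=1e-7)


def test_immigration_keeps_both_groups_positive(params, fast_settings):
    """Even at the anoxic extreme the suppressed group never reaches zero."""
    settings = fast_settings.replace(step_duration=20_000.0)
    out = integrate_step(
        SystemState(1e5, 1e5, 20, 20, 10), params, 0.01, 1.0, settings
    ).state
    assert out.N_CB > 1e-10
    assert out.N_SB > 1e8  # dominant group established


def test_early_exit_agrees_with_full_protocol(params):
    """The convergence-gated early exit must reproduce the full-length
    protocol's recorded states on converged steps."""
    drivers = make_driver_sequence(3, 1.0, Direction.TOWARD_OXIC)
    full = SimulationSettings(step_duration=1e6, early_exit=False)
    fast = SimulationSettings(step_duration=1e6, early_exit=True)
    run_full = run_direction(params, drivers, full)
    run_fast = run_direction(params, drivers, fast)
    for a, b in zip(run_full.states, run_fast.states):
        assert b.as_array() == pytest.approx(a.as_array(), rel=1e-5, abs=1e-8)


def test_run_direction_establishes_anoxic_state_first(params, fast_settings):
    run = run_direction(
        params, make_driver_sequence(5, 1.0, Direction.TOWARD_OXIC), fast_settings
    )
    first = run.states[0]
    assert first.S > 50 * first.O        # sulfide-dominated
    assert first.N_SB > 1e6 * max(first.N_CB, 1.0)
    assert len(run.states) == 5 and len(run.residuals) == 5
    df = run.to_dataframe()
    assert list(df.columns) == [
        "direction", "step_index", "a_O", "a_S", "N_CB", "N_SB", "O", "S", "P", "residual",
    ]


def test_run_temporal_empty_schedule(params):
    from symtip import DriverSequence

    empty = DriverSequence(np.array([]), np.array([]), Direction.TOWARD_OXIC,
                           time_h=np.array([]))
    traj = run_temporal(params, empty)
    assert len(traj) == 0
    assert traj.to_dataframe().empty


def test_run_temporal_requires_time_index(params):
    seq = make_driver_sequence(5)
    with pytest.raises(ValueError, match="time-indexed"):
        run_temporal(params, seq)


def test_run_temporal_records_monotone_time(params, fast_settings):
    pat = make_temporal_pattern((4000, 4000, 4000), 5)
    traj = run_temporal(params, pat, fast_settings, record_every=500.0)
    assert np.all(np.diff(traj.time_h) > 0)
    assert traj.time_h[-1] == pytest.approx(12_000.0)
    assert np.all(np.isfinite(traj.states))
    # drivers recorded alongside the trajectory follow the schedule extremes
    assert traj.a_O.min() == pytest.approx(1e-2) and traj.a_O.max() == pytest.approx(1e0)


def test_integrate_step_rejects_bad_inputs(params, fast_settings):
    with pytest.raises(ValueError):
        integrate_step(SystemState(1, 1, 1, 1, 1), params, -0.1, 0.1, fast_settings)
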