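"""Simulator contracts: mass conservation, fixed point, seeding, observation."""

import dataclasses

import numpy as np
import pytest

from pevkactin import kinetics as K


def replace(obj, **kw):
    return dataclasses.replace(obj, **kw)


# --------------------------------------------------------------------------
# simulate_polymerization
# --------------------------------------------------------------------------

def test_no_material_means_no_polymer(grid_2000):
    state = K.simulate_polymerization(K.KineticParams(actin_total=0.0), grid_2000)
    assert np.all(state.c_f == 0.0)
    assert np.all(state.N == 0.0)


def test_no_nucleation_pathway_means_no_assembly(grid_2000):
    params = K.KineticParams(k_nuc=0.0, k_seed=0.0)
    state = K.simulate_polymerization(params, grid_2000)
    np.testing.assert_allclose(state.m, params.actin_total, rtol=1e-9)
    assert np.all(state.c_f <= 1e-9)


def test_monomer_converges_to_critical_concentration():
    params = K.KineticParams()  # k_plus 11.6, k_minus 1.4 -> Cc ~ 0.1207 µM
    grid = np.linspace(0.0, 20000.0, 200)
    state = K.simulate_polymerization(params, grid)
    assert abs(state.m[-1] - params.critical_concentration) < 1e-4


@pytest.mark.parametrize("kwargs", [
    {},
    {"nucleator_conc": 32.5},
    {"k_nuc": 1e-7, "n_c": 4},
    {"actin_total": 0.5, "nucleator_conc": 60.0},
    {"k_minus": 2.8, "actin_total": 1.0, "nucleator_conc": 60.0},
])
def test_mass_conservation(kwargs, grid_2000):
    params = K.KineticParams(**kwargs)
    state = K.simulate_polymerization(params, grid_2000)
    np.testing.assert_allclose(state.m + state.c_f, params.actin_total,
                               atol=1e-8, rtol=1e-8)
    assert np.all(state.m >= 0) and np.all(state.c_f >= 0) and np.all(state.N >= 0)
    assert np.all(np.diff(state.N) >= -1e-12)  # no filament-removing events


def test_doubled_nucleator_never_slows_assembly(grid_2000):
    base = K.KineticParams(nucleator_conc=10.0)
    lo = K.simulate_polymerization(base, grid_2000)
    hi = K.simulate_polymerization(replace(base, nucleator_conc=20.0), grid_2000)
    # pre-steady-state comparison: up to where the slower run saturates
    rise = lo.c_f < 0.95 * (base.actin_total - base.critical_concentration)
    assert np.all(hi.c_f[rise] >= lo.c_f[rise] - 1e-9)


def test_event_at_zero_equals_nucleator_from_start(grid_2000):
    with_event = K.simulate_polymerization(
        K.KineticParams(), grid_2000, [K.AdditionEvent(0.0, 125.0)])
    from_start = K.simulate_polymerization(
        K.KineticParams(nucleator_conc=125.0), grid_2000)
    np.testing.assert_allclose(with_event.c_f, from_start.c_f, rtol=1e-7, atol=1e-9)


def test_mid_run_addition_boosts_assembly(grid_2000):
    control = K.simulate_polymerization(K.KineticParams(), grid_2000)
    kicked = K.simulate_polymerization(K.KineticParams(), grid_2000,
                                       [K.AdditionEvent(500.0, 125.0)])
    np.testing.assert_allclose(kicked.c_f[:500], control.c_f[:500],
                               rtol=1e-7, atol=1e-9)
    assert kicked.c_f[700] > control.c_f[700]


@pytest.mark.parametrize("bad", [
    {"k_plus": -1.0}, {"k_nuc": -1e-9}, {"n_c": 1}, {"s_c": 0},
    {"labeled_fraction": 1.5}, {"actin_total": -4.0},
])
def test_invalid_params_raise(bad):
    with pytest.raises(K.ValidationError):
        K.KineticParams(**bad)


def test_bad_grid_and_events_raise():
    p = K.KineticParams()
    with pytest.raises(K.ValidationError):
        K.simulate_polymerization(p, [1.0, 2.0, 3.0])  # does not start at 0
    with pytest.raises(K.ValidationError):
        K.simulate_polymerization(p, [0.0, 1.0, 1.0])  # not strictly increasing
    with pytest.raises(K.ValidationError):
        K.simulate_polymerization(p, [0.0, 1.0, 2.0],
                                  [K.AdditionEvent(5.0, 1.0),
                                   K.AdditionEvent(1.0, 1.0)])


# --------------------------------------------------------------------------
# observe_fluorescence
# --------------------------------------------------------------------------

def test_identity_observation_proportional_to_polymer(control_state, noiseless_obs):
    trace = K.observe_fluorescence(control_state, noiseless_obs)
    expected = noiseless_obs.baseline + noiseless_obs.gain * \
        control_state.params.labeled_fraction * control_state.c_f
    np.testing.assert_allclose(trace.F, expected, rtol=1e-12)


def test_constant_polymer_bleaches_exponentially(control_params):
    t = np.arange(0.0, 1000.0, 10.0)
    state = K.KineticState(t=t, m=np.zeros_like(t), c_f=np.full_like(t, 2.0),
                           N=np.full_like(t, 1e-3), params=control_params)
    obs = K.ObservationParams(baseline=3.0, k_bleach=2e-3, noise_sd=0.0)
    trace = K.observe_fluorescence(state, obs)
    expected = obs.gain * control_params.labeled_fraction * 2.0 * np.exp(-2e-3 * t)
    np.testing.assert_allclose(trace.F - 3.0, expected, rtol=1e-12)


def test_intermittent_bleaches_less_than_continuous(control_state):
    cont = K.ObservationParams(k_bleach=5e-4, noise_sd=0.0)
    inter = K.ObservationParams(
        k_bleach=5e-4, noise_sd=0.0,
        schedule=K.IlluminationSchedule("intermittent", 10.0, 600.0))
    tr_c = K.observe_fluorescence(control_state, cont)
    tr_i = K.observe_fluorescence(control_state, inter)
    shared = np.isin(tr_c.t, tr_i.t)
    assert np.all(tr_i.F >= tr_c.F[shared] - 1e-12)


def test_intermittent_emits_only_illuminated_samples(control_state):
    sched = K.IlluminationSchedule("intermittent", 10.0, 600.0)
    trace = K.observe_fluorescence(
        control_state, K.ObservationParams(schedule=sched))
    assert np.all(sched.illuminated(trace.t))
    assert trace.t.size < control_state.t.size


def test_observation_deterministic_under_seed(control_state):
    obs = K.ObservationParams(noise_sd=1.0, rng_seed=42)
    a = K.observe_fluorescence(control_state, obs)
    b = K.observe_fluorescence(control_state, obs)
    np.testing.assert_array_equal(a.F, b.F)


def test_bad_schedule_raises():
    with pytest.raises(K.ValidationError):
        K.IlluminationSchedule("intermittent", window_s=600.0, period_s=600.0)


# --------------------------------------------------------------------------
# dose and concentration series
# --------------------------------------------------------------------------

def test_zero_dose_matches_control(control_state, grid_2000, noiseless_obs):
    traces = K.simulate_dose_series(K.KineticParams(), [0.0], grid_2000,
                                    noiseless_obs)
    control = K.observe_fluorescence(control_state, noiseless_obs)
    np.testing.assert_allclose(traces[0].F, control.F, rtol=1e-12)


def test_dose_series_initial_slope_monotone(grid_2000, noiseless_obs):
    concs = [3.25, 6.5, 16.25, 32.5]
    traces = K.simulate_dose_series(K.KineticParams(), concs, grid_2000,
                                    noiseless_obs)
    slopes = [np.polyfit(tr.t[:41], tr.F[:41], 1)[0] for tr in traces]
    assert np.all(np.diff(slopes) >= 0)


def test_dose_series_reproducible(grid_2000):
    obs = K.ObservationParams(noise_sd=0.5, rng_seed=3)
    t = grid_2000[:201]
    a = K.simulate_dose_series(K.KineticParams(), [0.0, 10.0], t, obs)
    b = K.simulate_dose_series(K.KineticParams(), [0.0, 10.0], t, obs)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.F, tb.F)


def test_empty_dose_list_raises(grid_2000, noiseless_obs):
    with pytest.raises(K.ValidationError):
        K.simulate_dose_series(K.KineticParams(), [], grid_2000, noiseless_obs)


def test_cc_series_below_critical_is_baseline(noiseless_obs):
    base = K.KineticParams(nucleator_conc=60.0)
    cc = base.critical_concentration
    series = K.simulate_cc_series(base, [cc / 4, cc / 2, 0.9 * cc], 8000.0,
                                  noiseless_obs)
    np.testing.assert_allclose(series.intensity, noiseless_obs.baseline, atol=0.02)


def test_cc_series_affine_above_critical(noiseless_obs):
    base = K.KineticParams(nucleator_conc=60.0)
    concs = [0.5, 1.0, 1.5, 2.0, 3.0]
    series = K.simulate_cc_series(base, concs, 8000.0, noiseless_obs)
    slope, intercept = np.polyfit(series.actin_conc,
                                  series.intensity - noiseless_obs.baseline, 1)
    x_intercept = -intercept / slope
    assert abs(x_intercept - base.critical_concentration) < 5e-3


def test_cc_series_negative_concentration_raises(noiseless_obs):
    with pytest.raises(K.ValidationError):
        K.simulate_cc_series(K.KineticParams(), [0.5, -0.1], 8000.0, noiseless_obs)


def test_cc_series_unreached_steady_state_names_concentration(noiseless_obs):
    base = K.KineticParams(nucleator_conc=60.0)
    with pytest.raises(K.SteadyStateError, match="0.4"):
        K.simulate_cc_series(base, [0.4], 50.0, noiseless_obs)


# --------------------------------------------------------------------------
# trace I/O
# --------------------------------------------------------------------------

def test_trace_csv_roundtrip(tmp_path, control_state):
    sched = K.IlluminationSchedule("intermittent", 10.0, 600.0)
    traces = [
        K.observe_fluorescence(control_state, K.ObservationParams(), "ctrl"),
        K.observe_fluorescence(control_state,
                               K.ObservationParams(schedule=sched), "pevk"),
    ]
    path = tmp_path / "traces.csv"
    K.write_traces(traces, path)
    back = K.read_traces(path)
    assert [tr.condition for tr in back] == ["ctrl", "pevk"]
    for orig, rt in zip(traces, back):
        np.testing.assert_allclose(rt.t, orig.t)
        np.testing.assert_allclose(rt.F, orig.F)
        assert rt.schedule.mode == orig.schedule.mode
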