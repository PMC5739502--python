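import dataclasses

import numpy as np
import pytest

import thalamica as th
from thalamica.currents import tc_t_gates
from thalamica.engine import detect_spikes


def test_initialize_state_is_seeded_and_jitter_controls_spread():
    cfg = th.baseline(n_TC=6, n_RE=6)
    a = th.initialize_state(cfg, seed=42)
    b = th.initialize_state(cfg, seed=42)
    np.testing.assert_array_equal(a.pack(), b.pack())
    c = th.initialize_state(cfg, seed=43)
    assert not np.array_equal(a.V_tc, c.V_tc)
    flat = th.initialize_state(cfg, seed=1,
                               integ=th.IntegratorConfig(init_jitter=0.0))
    assert np.ptp(flat.V_tc) == 0.0 and np.ptp(flat.V_re) == 0.0


def test_initial_hT_at_steady_state_of_initial_voltage():
    cfg = th.baseline(n_TC=3, n_RE=3)
    integ = th.IntegratorConfig(init_v_tc=-74.0, init_jitter=0.0)
    state = th.initialize_state(cfg, seed=0, integ=integ)
    _, hT_inf, _ = tc_t_gates(-74.0)
    np.testing.assert_allclose(state.hT_tc, hT_inf, rtol=1e-12)


def test_zero_conductance_cell_follows_linear_closed_form():
    cfg = th.baseline(n_TC=1, n_RE=1, background_excitation_TC=0.5)
    cfg.tc = dataclasses.replace(cfg.tc, g_Na=0.0, g_K=0.0, g_leak=0.0,
                                 g_KL=0.0, g_T=0.0, g_H=0.0)
    cfg.syn = dataclasses.replace(cfg.syn, g_AMPA_TC_to_RE=0.0,
                                  g_GABAA_RE_to_TC=0.0, g_GABAA_RE_to_RE=0.0,
                                  g_GABAB_RE_to_TC=0.0, g_ctx_AMPA=0.0)
    integ = th.IntegratorConfig(total_duration=100.0, settle_discard=0.0,
                                init_v_tc=-70.0, init_jitter=0.0)
    res = th.simulate(cfg, integ, seed=0)
    expected = -70.0 + 0.5 * res.t / cfg.tc.membrane_capacitance
    np.testing.assert_allclose(res.V_tc[:, 0], expected, atol=1e-9)


def test_reruns_are_bit_identical():
    cfg = th.high_dose(n_TC=4, n_RE=4, background_excitation_TC=0.4)
    integ = th.IntegratorConfig(total_duration=600.0, settle_discard=0.0)
    a = th.simulate(cfg, integ, seed=9)
    b = th.simulate(cfg, integ, seed=9)
    np.testing.assert_array_equal(a.V_tc, b.V_tc)
    np.testing.assert_array_equal(a.spikes_tc, b.spikes_tc)
    np.testing.assert_array_equal(a.final_state.pack(), b.final_state.pack())
    a.final_state.validate()   # gates in [0,1], Ca >= 0 along the trajectory


def test_convergence_under_dt_halving_smooth_trajectory():
    # silent (non-spiking) network: trajectories are smooth, so halving dt
    # must leave the voltage path essentially unchanged
    cfg = th.baseline(n_TC=2, n_RE=2, background_excitation_TC=-0.2)
    base = th.IntegratorConfig(total_duration=1000.0, settle_discard=0.0,
                               record_stride_ms=1.0)
    v1 = th.simulate(cfg, base, seed=2).V_tc
    v2 = th.simulate(cfg, dataclasses.replace(base, dt=0.005), seed=2).V_tc
    assert np.max(np.abs(v1 - v2)) < 0.5


def test_rk4_order_against_exponential_closed_form():
    # passive leak-only cell: V(t) = E + (V0 - E) exp(-g t / C)
    cfg = th.baseline(n_TC=1, n_RE=1)
    cfg.tc = dataclasses.replace(cfg.tc, g_Na=0.0, g_K=0.0, g_KL=0.0,
                                 g_T=0.0, g_H=0.0, g_leak=0.1)
    cfg.re = dataclasses.replace(cfg.re, g_Na=0.0, g_K=0.0, g_T=0.0)
    cfg.syn = dataclasses.replace(cfg.syn, g_AMPA_TC_to_RE=0.0,
                                  g_GABAA_RE_to_TC=0.0, g_GABAA_RE_to_RE=0.0,
                                  g_GABAB_RE_to_TC=0.0, g_ctx_AMPA=0.0)

    def err(dt):
        integ = th.IntegratorConfig(dt=dt, total_duration=50.0,
                                    settle_discard=0.0, init_v_tc=-40.0,
                                    init_jitter=0.0, record_stride_ms=50.0)
        res = th.simulate(cfg, integ, seed=0)
        exact = cfg.tc.E_leak + (-40.0 - cfg.tc.E_leak) * np.exp(
            -cfg.tc.g_leak * 50.0 / cfg.tc.membrane_capacitance)
        return abs(res.V_tc[-1, 0] - exact)

    e1, e2 = err(0.4), err(0.2)
    assert e1 / max(e2, 1e-15) > 8.0  # ~16x for a 4th-order scheme


def test_energy_sanity_without_inward_currents():
    # with Na, T, H, and excitatory synapses disabled, V can never exceed
    # the most depolarized reversal of the remaining (outward) currents
    cfg = th.baseline(n_TC=2, n_RE=2, background_excitation_TC=0.0)
    cfg.tc = dataclasses.replace(cfg.tc, g_Na=0.0, g_T=0.0, g_H=0.0)
    cfg.syn = dataclasses.replace(cfg.syn, g_AMPA_TC_to_RE=0.0, g_ctx_AMPA=0.0)
    integ = th.IntegratorConfig(total_duration=500.0, settle_discard=0.0,
                                init_v_tc=-90.0)
    res = th.simulate(cfg, integ, seed=0)
    assert res.V_tc.max() <= max(cfg.tc.E_leak, cfg.tc.E_K) + 1e-6


def test_detect_spikes_constant_and_sawtooth():
    t = np.arange(0.0, 100.0, 0.1)
    quiet = np.full((t.size, 1), -70.0)
    assert detect_spikes(t, quiet).shape == (0, 2)
    # sawtooth crossing 0 mV ten times
    saw = (20.0 * ((t / 10.0) % 1.0) - 10.0).reshape(-1, 1)
    spikes = detect_spikes(t, saw, threshold=0.0, dead_time=2.0)
    assert len(spikes) == 10


def test_spike_count_invariant_to_threshold_for_clean_bursts(alpha_reference):
    counts = {thr: len(detect_spikes(alpha_reference.t, alpha_reference.V_tc,
                                     threshold=thr, dead_time=2.0))
              for thr in (-20.0, -10.0, 0.0)}
    vals = list(counts.values())
    assert max(vals) - min(vals) <= 0.02 * max(vals)


def test_simulation_result_roundtrip(tmp_path, spindle_reference):
    spindle_reference.save(tmp_path / "run")
    back = th.SimulationResult.load(tmp_path / "run")
    np.testing.assert_allclose(back.V_tc, spindle_reference.V_tc)
    np.testing.assert_allclose(back.spikes_tc, spindle_reference.spikes_tc,
                               atol=5e-4)
    assert back.provenance["network"] == spindle_reference.provenance["network"]


def test_integrator_config_validation():
    with pytest.raises(ValueError):
        th.IntegratorConfig(dt=0.0).validate()
    with pytest.raises(ValueError):
        th.IntegratorConfig(total_duration=100.0, settle_discard=200.0).validate()
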