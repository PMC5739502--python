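import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

import thalamica as th
from thalamica import _kernel as K
from thalamica.currents import k_rates, na_rates
from thalamica.network import NetworkState, network_derivatives


def _passive_tc_config(**kw):
    """Single TC + single RE with T, H, and synapses silenced."""
    cfg = th.baseline(n_TC=1, n_RE=1, **kw)
    cfg.tc = dataclasses.replace(cfg.tc, g_T=0.0, g_H=0.0)
    cfg.syn = dataclasses.replace(cfg.syn, g_AMPA_TC_to_RE=0.0,
                                  g_GABAA_RE_to_TC=0.0, g_GABAA_RE_to_RE=0.0,
                                  g_GABAB_RE_to_TC=0.0, g_ctx_AMPA=0.0)
    return cfg


def test_forced_identity_all_conductances_zero():
    cfg = _passive_tc_config(background_excitation_TC=0.7)
    cfg.tc = dataclasses.replace(cfg.tc, g_Na=0.0, g_K=0.0, g_leak=0.0, g_KL=0.0)
    state = th.initialize_state(cfg, seed=0,
                                integ=th.IntegratorConfig(init_jitter=0.0))
    d = network_derivatives(state, 0.0, cfg)
    assert d.V_tc[0] == pytest.approx(0.7 / cfg.tc.membrane_capacitance)


def _tc_resting_potential(cfg):
    """Root-solver oracle for the passive TC fixed point."""
    tc = cfg.tc

    def f(v):
        am, bm, ah, bh = na_rates(v, tc.v_shift_Na)
        an, bn = k_rates(v, tc.v_shift_K)
        m, h, n = am / (am + bm), ah / (ah + bh), an / (an + bn)
        return (-tc.g_Na * m ** 3 * h * (v - tc.E_Na)
                - tc.g_K * n ** 4 * (v - tc.E_K)
                - tc.g_leak * (v - tc.E_leak)
                - tc.g_KL * (v - tc.E_KL)
                + cfg.background_excitation_TC)

    return brentq(f, -99.0, -55.0, xtol=1e-10)


def test_fixed_point_derivatives_vanish_and_integration_converges():
    cfg = _passive_tc_config()
    v_rest = _tc_resting_potential(cfg)
    # derivatives at the root-solved fixed point are ~0
    integ = th.IntegratorConfig(init_v_tc=v_rest, init_jitter=0.0,
                                total_duration=2000.0, settle_discard=0.0)
    state = th.initialize_state(cfg, seed=0, integ=integ)
    d = network_derivatives(state, 0.0, cfg)
    assert abs(d.V_tc[0]) < 1e-6
    # integration from elsewhere converges to the same resting potential
    integ2 = dataclasses.replace(integ, init_v_tc=v_rest - 6.0)
    res = th.simulate(cfg, integ2, seed=0)
    assert res.V_tc[-1, 0] == pytest.approx(v_rest, abs=0.1)


def test_kernel_matches_numpy_reference_rhs():
    """The compiled kernel and the numpy right-hand side are the same math."""
    cfg = th.high_dose(n_TC=4, n_RE=3, background_excitation_TC=0.4)
    rng = np.random.default_rng(7)
    state = th.initialize_state(cfg, seed=5)
    # scatter the state away from steady state to probe every term
    state.V_tc += rng.uniform(-20, 20, 4)
    state.V_re += rng.uniform(-20, 20, 3)
    for f in ("m_tc", "h_tc", "n_tc", "hT_tc", "O_h", "P1_h", "OL_h", "s_ampa",
              "s_ctx_tc"):
        setattr(state, f, rng.uniform(0.05, 0.9, 4))
    for f in ("m_re", "h_re", "n_re", "hT_re", "s_gabaa", "R_gabab", "s_ctx_re"):
        setattr(state, f, rng.uniform(0.05, 0.9, 3))
    state.G_gabab = rng.uniform(0.0, 5.0, 3)
    state.Ca_tc = rng.uniform(1e-4, 5e-3, 4)

    d_ref = network_derivatives(state, 0.0, cfg).pack()
    y = state.pack()
    dy = np.zeros_like(y)
    K._rhs(y, dy, 4, 3, K.pack_params(cfg), cfg.background_excitation_TC,
           cfg.background_excitation_RE, cfg.propofol.multiplier)
    np.testing.assert_allclose(dy, d_ref, rtol=1e-10, atol=1e-12)


def test_permutation_symmetry():
    cfg = th.baseline(n_TC=5, n_RE=5, background_excitation_TC=0.4)
    state = th.initialize_state(cfg, seed=0,
                                integ=th.IntegratorConfig(init_jitter=0.0))
    d = network_derivatives(state, 0.0, cfg)
    for f in ("V_tc", "hT_tc", "V_re"):
        arr = getattr(d, f)
        assert np.ptp(arr) < 1e-12  # identical cells -> identical derivatives


def test_gabaa_decay_halflife_scales_with_multiplier():
    cfg2 = th.low_dose(n_TC=1, n_RE=1)
    cfg1 = th.baseline(n_TC=1, n_RE=1)
    state = th.initialize_state(cfg1, seed=0,
                                integ=th.IntegratorConfig(init_jitter=0.0))
    state.V_re = np.array([-90.0])      # presynaptically silent
    state.s_gabaa = np.array([0.8])
    r1 = network_derivatives(state, 0.0, cfg1).s_gabaa[0]
    r2 = network_derivatives(state, 0.0, cfg2).s_gabaa[0]
    assert r1 == pytest.approx(-0.8 / cfg1.syn.tau_GABAA, rel=1e-6)
    assert r2 == pytest.approx(r1 / 2.0, rel=1e-6)  # doubled tau halves the rate


def test_state_validation_catches_corruption():
    cfg = th.baseline(n_TC=2, n_RE=2)
    state = th.initialize_state(cfg, seed=0)
    state.validate()
    state.hT_tc[0] = 1.7
    with pytest.raises(ValueError, match="hT_tc"):
        state.validate()
    state.hT_tc[0] = 0.5
    state.Ca_tc[0] = -1e-3
    with pytest.raises(ValueError, match="Ca"):
        state.validate()


def test_nonfinite_current_is_diagnosed_with_term_name():
    cfg = th.baseline(n_TC=1, n_RE=1)
    state = th.initialize_state(cfg, seed=0)
    state.m_tc = np.array([np.inf])
    with pytest.raises(FloatingPointError, match="I_Na"):
        network_derivatives(state, 0.0, cfg)


def test_pack_unpack_roundtrip():
    cfg = th.baseline(n_TC=3, n_RE=2)
    state = th.initialize_state(cfg, seed=11)
    back = NetworkState.unpack(state.pack(), 3, 2)
    for f in NetworkState._TC_FIELDS + NetworkState._RE_FIELDS:
        np.testing.assert_array_equal(getattr(back, f), getattr(state, f))
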