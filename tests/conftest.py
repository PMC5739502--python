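import dataclasses

import numpy as np
import pytest

import thalamica as th

# Desk-scale study conditions used throughout the suite: reduced network with
# synapses normalized by presynaptic count, so regimes carry over from the
# full-size network.
N_SMALL = 5          # cells per population for fast unit-level runs
N_DESK = 10          # cells per population for reference simulations


@pytest.fixture(scope="session")
def desk_integ():
    return th.IntegratorConfig(total_duration=4000.0, settle_discard=1000.0)


@pytest.fixture(scope="session")
def short_integ():
    return th.IntegratorConfig(total_duration=500.0, settle_discard=0.0)


@pytest.fixture(scope="session")
def baseline_cfg():
    return th.baseline(n_TC=N_DESK, n_RE=N_DESK)


@pytest.fixture(scope="session")
def high_dose_cfg():
    return th.high_dose(n_TC=N_DESK, n_RE=N_DESK)


def make_config(mult=1.0, n=N_DESK, g_H=0.01, excitation=0.0, **tc_overrides):
    cfg = th.NetworkConfig(n_TC=n, n_RE=n,
                           background_excitation_TC=excitation,
                           propofol=th.PropofolCondition(mult))
    cfg.tc = dataclasses.replace(cfg.tc, g_H=g_H, **tc_overrides)
    return cfg


@pytest.fixture(scope="session")
def spindle_reference(desk_integ):
    """Baseline simulation at the spindling reference point."""
    cfg = make_config(mult=1.0, excitation=0.3)
    return th.simulate(cfg, desk_integ, seed=3)


@pytest.fixture(scope="session")
def alpha_reference(desk_integ):
    """High-dose simulation at the sustained-alpha reference point."""
    cfg = make_config(mult=3.0, excitation=0.4)
    return th.simulate(cfg, desk_integ, seed=3)
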