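"""Gating functions and current densities for TC and RE cells.

These are the readable reference implementations; the integrator kernel in
``_kernel`` re-expresses the same right-hand sides in compiled scalar form,
and the test suite cross-checks the two.

Rate functions are Traub-style alpha/beta pairs for the spike currents; the
T current uses instantaneous steady-state activation (mT) with a slow
de-inactivation gate (hT) whose steady-state curve overlaps mT in the
hyperpolarized "T window" (roughly -80 to -72 mV), the overlap that permits
rebound bursting. The H current uses a two-state (open / calcium-locked)
scheme: intracellular calcium binds a regulating factor which locks open
channels into a higher-conductance state — the up-regulation that lets
baseline spindles wane.
"""

from __future__ import annotations

import numpy as np

from .params import RECellParams, SynapseParams, TCCellParams

__all__ = [
    "steady_state_gates",
    "t_current",
    "h_current",
    "re_t_current",
    "transmitter",
    "synaptic_currents",
]

_TEMP_PHI_H = 3.73  # 3**((36-24)/10): T-current h gate Q10 correction


def _vtrap(x: np.ndarray | float, y: float) -> np.ndarray | float:
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    denom = np.expm1(np.clip(x / y, -500, 500))
    out = np.where(small, y * (1.0 - x / (2.0 * y)),
                   x / np.where(small, 1.0, denom))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Spike-current rate functions (Traub-style, voltage-shifted)
# ---------------------------------------------------------------------------

def na_rates(V, shift):
    v2 = np.asarray(V, dtype=float) + shift
    am = 0.32 * _vtrap(13.0 - v2, 4.0)
    bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
    ah = 0.128 * np.exp(np.clip((17.0 - v2) / 18.0, -500, 500))
    bh = 4.0 / (1.0 + np.exp(np.clip((40.0 - v2) / 5.0, -500, 500)))
    return am, bm, ah, bh


def k_rates(V, shift):
    v2 = np.asarray(V, dtype=float) + shift
    an = 0.032 * _vtrap(15.0 - v2, 5.0)
    bn = 0.5 * np.exp(np.clip((10.0 - v2) / 40.0, -500, 500))
    return an, bn


# ---------------------------------------------------------------------------
# T current gates
# ---------------------------------------------------------------------------

def tc_t_gates(V, phi_hT: float = _TEMP_PHI_H):
    """TC T current: (mT_inf, hT_inf, tau_hT). mT is instantaneous."""
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(np.clip(-(V + 57.0) / 6.2, -500, 500)))
    h_inf = 1.0 / (1.0 + np.exp(np.clip((V + 81.0) / 4.0, -500, 500)))
    tau_h = (30.8 + (211.4 + np.exp(np.clip((V + 113.2) / 5.0, -500, 500)))
             / (1.0 + np.exp(np.clip((V + 84.0) / 3.2, -500, 500)))) / phi_hT
    return m_inf, h_inf, tau_h


def re_t_gates(V):
    """RE T current: (mT_inf, hT_inf, tau_hT). mT treated as instantaneous."""
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(np.clip(-(V + 52.0) / 7.4, -500, 500)))
    h_inf = 1.0 / (1.0 + np.exp(np.clip((V + 80.0) / 5.0, -500, 500)))
    tau_h = (85.0 + 1.0 / (np.exp(np.clip((V + 48.0) / 4.0, -500, 500))
                           + np.exp(np.clip(-(V + 407.0) / 50.0, -500, 500)))) / _TEMP_PHI_H
    return m_inf, h_inf, tau_h


# ---------------------------------------------------------------------------
# H current voltage gating
# ---------------------------------------------------------------------------

def h_gates(V):
    """H current: (open_inf, tau_open) of the voltage-dependent C<->O step."""
    V = np.asarray(V, dtype=float)
    o_inf = 1.0 / (1.0 + np.exp(np.clip((V + 75.0) / 5.5, -500, 500)))
    tau = 20.0 + 1000.0 / (np.exp(np.clip((V + 71.5) / 14.2, -500, 500))
                           + np.exp(np.clip(-(V + 89.0) / 11.6, -500, 500)))
    return o_inf, tau


def steady_state_gates(V, cell_kind: str = "TC") -> dict[str, float]:
    """All steady-state gate values and time constants at membrane potential V.

    Returns a dict with, per gate, ``<gate>_inf`` in [0, 1] and ``tau_<gate>``
    in ms (> 0). ``mT`` carries no time constant: it is instantaneous
    (always at steady state). Raises ValueError on non-finite V.
    """
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    if cell_kind.upper() == "TC":
        shift_na, shift_k = TCCellParams.v_shift_Na, TCCellParams.v_shift_K
        am, bm, ah, bh = na_rates(V, shift_na)
        an, bn = k_rates(V, shift_k)
        mT, hT, tau_hT = tc_t_gates(V)
        oH, tau_oH = h_gates(V)
        return {
            "m_inf": am / (am + bm), "tau_m": 1.0 / (am + bm),
            "h_inf": ah / (ah + bh), "tau_h": 1.0 / (ah + bh),
            "n_inf": an / (an + bn), "tau_n": 1.0 / (an + bn),
            "mT_inf": mT,
            "hT_inf": hT, "tau_hT": tau_hT,
            "oH_inf": oH, "tau_oH": tau_oH,
        }
    elif cell_kind.upper() == "RE":
        shift = RECellParams.v_shift_Na
        am, bm, ah, bh = na_rates(V, shift)
        an, bn = k_rates(V, RECellParams.v_shift_K)
        mT, hT, tau_hT = re_t_gates(V)
        return {
            "m_inf": am / (am + bm), "tau_m": 1.0 / (am + bm),
            "h_inf": ah / (ah + bh), "tau_h": 1.0 / (ah + bh),
            "n_inf": an / (an + bn), "tau_n": 1.0 / (an + bn),
            "mT_inf": mT,
            "hT_inf": hT, "tau_hT": tau_hT,
        }
    raise ValueError(f"unknown cell kind {cell_kind!r}")


# ---------------------------------------------------------------------------
# Current densities
# ---------------------------------------------------------------------------

def ca_reversal(Ca, p: TCCellParams):
    """Nernst Ca reversal (mV) from intracellular Ca (mM), floored at 1 nM."""
    Ca = np.maximum(np.asarray(Ca, dtype=float), 1e-6)
    return p.nernst_factor * np.log(p.Ca_o / Ca)


def t_current(V, hT, p: TCCellParams, Ca=None):
    """TC T-current density (uA/cm^2), positive = outward.

    Inward (negative) whenever mT_inf * hT > 0 and V is below the Ca
    reversal; identically zero when g_T = 0.
    """
    if p.g_T < 0:
        raise ValueError("g_T must be >= 0")
    hT = np.asarray(hT, dtype=float)
    if np.any(hT < 0) or np.any(hT > 1):
        raise ValueError("hT must lie in [0, 1]")
    m_inf, _, _ = tc_t_gates(V)
    E_Ca = ca_reversal(p.Ca_rest if Ca is None else Ca, p)
    return p.g_T * m_inf ** 2 * hT * (np.asarray(V, dtype=float) - E_Ca)


def re_t_current(V, hT, p: RECellParams):
    """RE T-current density (uA/cm^2) with fixed Ca reversal."""
    m_inf, _, _ = re_t_gates(V)
    return p.g_T * m_inf ** 2 * np.asarray(hT, dtype=float) * (np.asarray(V) - p.E_Ca)


def h_current(V, open_fraction, locked_fraction, p: TCCellParams, Ca=None, P1=None):
    """H-current density plus state derivatives.

    Returns ``(I_H, dO, dP1, dOL)`` where P1 is the fraction of Ca-bound
    regulating factor and OL the locked-open channel fraction. Raising
    intracellular Ca raises the equilibrium locked fraction — the
    up-regulation that terminates baseline spindles. If ``P1`` is omitted it
    is taken at its equilibrium for the given (clamped) Ca.
    """
    O = np.asarray(open_fraction, dtype=float)
    OL = np.asarray(locked_fraction, dtype=float)
    if np.any(O < 0) or np.any(O > 1) or np.any(OL < 0) or np.any(OL > 1):
        raise ValueError("H-current state fractions must lie in [0, 1]")
    Ca = np.asarray(p.Ca_rest if Ca is None else Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("Ca must be >= 0")
    if P1 is None:
        bind = p.ca_bind_rate * Ca ** 4
        P1 = bind / (bind + p.ca_unbind_rate)
    P1 = np.asarray(P1, dtype=float)
    I_H = p.g_H * (O + p.locked_gain * OL) * (np.asarray(V, dtype=float) - p.E_H)
    dO, dP1, dOL = h_state_derivs(V, O, P1, OL, Ca, p)
    return I_H, dO, dP1, dOL


def h_state_derivs(V, O, P1, OL, Ca, p: TCCellParams):
    """Full H-current state derivatives given the Ca-bound factor P1."""
    o_inf, tau = h_gates(V)
    alpha = o_inf / tau
    beta = (1.0 - o_inf) / tau
    dO = alpha * (1.0 - O - OL) - beta * O - p.lock_rate * P1 * O + p.unlock_rate * OL
    dP1 = p.ca_bind_rate * np.asarray(Ca) ** 4 * (1.0 - P1) - p.ca_unbind_rate * P1
    dOL = p.lock_rate * P1 * O - p.unlock_rate * OL
    return dO, dP1, dOL


def transmitter(V_pre):
    """Smooth presynaptic transmitter-release function in [0, 1]."""
    return 0.5 * (1.0 + np.tanh(np.asarray(V_pre, dtype=float) / 4.0))


def synaptic_currents(s_ampa, s_gabaa, G_gabab, V_post_tc, V_post_re,
                      syn: SynapseParams, n_tc: int, n_re: int):
    """Per-target synaptic current densities from mean presynaptic gates.

    ``s_ampa``: TC presynaptic AMPA gates; ``s_gabaa``: RE presynaptic
    GABA_A gates; ``G_gabab``: RE presynaptic G-protein concentrations.
    All-to-all with conductance normalized by presynaptic count. Returns
    ``(I_syn_TC, I_syn_RE)`` with positive = outward (hyperpolarizing).
    """
    s_ampa = np.asarray(s_ampa, dtype=float)
    s_gabaa = np.asarray(s_gabaa, dtype=float)
    G = np.asarray(G_gabab, dtype=float)
    gb = G ** 4 / (G ** 4 + syn.gb_Kd)
    mean_ampa = s_ampa.mean() if s_ampa.size else 0.0
    mean_gabaa = s_gabaa.mean() if s_gabaa.size else 0.0
    mean_gb = gb.mean() if gb.size else 0.0
    I_tc = (syn.g_GABAA_RE_to_TC * mean_gabaa * (V_post_tc - syn.E_GABAA_TC)
            + syn.g_GABAB_RE_to_TC * mean_gb * (V_post_tc - syn.E_GABAB))
    I_re = (syn.g_AMPA_TC_to_RE * mean_ampa * (V_post_re - syn.E_AMPA)
            + syn.g_GABAA_RE_to_RE * mean_gabaa * (V_post_re - syn.E_GABAA_RE))
    return I_tc, I_re
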