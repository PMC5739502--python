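"""Network state container and the reference right-hand side.

``network_derivatives`` is the plain-numpy statement of the model equations:
per cell,  C dV/dt = -(sum of intrinsic currents) - (sum of synaptic
currents) + background excitation + external drive.  The compiled kernel in
``_kernel`` implements the identical mathematics; the test suite checks the
two against each other, so either can be read as the definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .currents import (h_gates, k_rates, na_rates, re_t_gates, tc_t_gates,
                       transmitter)
from .params import NetworkConfig


@dataclass
class NetworkState:
    """Per-cell dynamic variables. All gating/activation variables in [0,1];
    Ca >= 0 (mM); V finite (mV)."""

    # TC block
    V_tc: np.ndarray
    m_tc: np.ndarray
    h_tc: np.ndarray
    n_tc: np.ndarray
    hT_tc: np.ndarray
    Ca_tc: np.ndarray
    O_h: np.ndarray          # H-channel open fraction
    P1_h: np.ndarray         # Ca-bound regulating factor
    OL_h: np.ndarray         # locked-open H-channel fraction
    s_ampa: np.ndarray       # TC presynaptic AMPA gate
    s_ctx_tc: np.ndarray     # cortical-input AMPA gate on TC
    # RE block
    V_re: np.ndarray
    m_re: np.ndarray
    h_re: np.ndarray
    n_re: np.ndarray
    hT_re: np.ndarray
    s_gabaa: np.ndarray      # RE presynaptic GABA_A gate
    R_gabab: np.ndarray      # GABA_B bound-receptor fraction
    G_gabab: np.ndarray      # GABA_B G-protein concentration
    s_ctx_re: np.ndarray

    _TC_FIELDS = ("V_tc", "m_tc", "h_tc", "n_tc", "hT_tc", "Ca_tc",
                  "O_h", "P1_h", "OL_h", "s_ampa", "s_ctx_tc")
    _RE_FIELDS = ("V_re", "m_re", "h_re", "n_re", "hT_re",
                  "s_gabaa", "R_gabab", "G_gabab", "s_ctx_re")

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [getattr(self, f) for f in self._TC_FIELDS]
            + [getattr(self, f) for f in self._RE_FIELDS])

    @classmethod
    def unpack(cls, y: np.ndarray, n_tc: int, n_re: int) -> "NetworkState":
        parts = {}
        off = 0
        for f in cls._TC_FIELDS:
            parts[f] = np.asarray(y[off:off + n_tc], dtype=float).copy()
            off += n_tc
        for f in cls._RE_FIELDS:
            parts[f] = np.asarray(y[off:off + n_re], dtype=float).copy()
            off += n_re
        return cls(**parts)

    def validate(self) -> None:
        for f in self._TC_FIELDS + self._RE_FIELDS:
            arr = getattr(self, f)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {f}")
        for f in ("m_tc", "h_tc", "n_tc", "hT_tc", "O_h", "P1_h", "OL_h",
                  "s_ampa", "s_ctx_tc", "m_re", "h_re", "n_re", "hT_re",
                  "s_gabaa", "R_gabab", "s_ctx_re"):
            arr = getattr(self, f)
            if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
                raise ValueError(f"{f} outside [0, 1]")
        if np.any(self.Ca_tc < 0):
            raise ValueError("Ca must be >= 0")


def network_derivatives(state: NetworkState, t: float, config: NetworkConfig,
                        drive_tc: float = 0.0, drive_re: float = 0.0,
                        multiplier: float | None = None) -> NetworkState:
    """Time derivative of every state variable (numpy reference).

    ``drive_*`` are additional applied current densities (uA/cm^2) active at
    time ``t`` (e.g. an UP-state excitation step); the propofol multiplier
    defaults to the one in ``config``. Raises with the name of the offending
    term if any current evaluates non-finite.
    """
    s = state
    tc, re, syn = config.tc, config.re, config.syn
    mult = config.propofol.multiplier if multiplier is None else multiplier
    n_tc, n_re = config.n_TC, config.n_RE

    g_gabaa_tc = syn.g_GABAA_RE_to_TC * mult / n_re
    g_gabaa_re = syn.g_GABAA_RE_to_RE * mult / n_re
    tau_gabaa = syn.tau_GABAA * mult
    g_ampa = syn.g_AMPA_TC_to_RE / n_tc
    g_gabab = syn.g_GABAB_RE_to_TC / n_re

    s_ampa_sum = s.s_ampa.sum()
    s_gabaa_sum = s.s_gabaa.sum()
    g4 = s.G_gabab ** 4
    gb_sum = (g4 / (g4 + syn.gb_Kd)).sum()

    # ---- TC cells -----------------------------------------------------
    V = s.V_tc
    am, bm, ah, bh = na_rates(V, tc.v_shift_Na)
    an, bn = k_rates(V, tc.v_shift_K)
    i_na = tc.g_Na * s.m_tc ** 3 * s.h_tc * (V - tc.E_Na)
    i_k = tc.g_K * s.n_tc ** 4 * (V - tc.E_K)
    i_l = tc.g_leak * (V - tc.E_leak)
    i_kl = tc.g_KL * (V - tc.E_KL)
    mT, hT_inf, tau_hT = tc_t_gates(V)
    E_Ca = tc.nernst_factor * np.log(tc.Ca_o / np.maximum(s.Ca_tc, 1e-6))
    i_t = tc.g_T * mT ** 2 * s.hT_tc * (V - E_Ca)
    o_inf, tau_o = h_gates(V)
    a_h, b_h = o_inf / tau_o, (1 - o_inf) / tau_o
    i_h = tc.g_H * (s.O_h + tc.locked_gain * s.OL_h) * (V - tc.E_H)
    i_syn_tc = (g_gabaa_tc * s_gabaa_sum * (V - syn.E_GABAA_TC)
                + g_gabab * gb_sum * (V - syn.E_GABAB)
                + syn.g_ctx_AMPA * s.s_ctx_tc * (V - syn.E_AMPA))
    for name, term in (("I_Na(TC)", i_na), ("I_K(TC)", i_k), ("I_T(TC)", i_t),
                       ("I_H(TC)", i_h), ("I_syn(TC)", i_syn_tc)):
        if not np.all(np.isfinite(term)):
            raise FloatingPointError(f"non-finite current term {name}")
    iapp_tc = config.background_excitation_TC + drive_tc
    dV_tc = (-i_na - i_k - i_l - i_kl - i_t - i_h - i_syn_tc + iapp_tc) \
        / tc.membrane_capacitance
    ca4 = np.maximum(s.Ca_tc, 1e-6) ** 4
    ft_tc = transmitter(V)

    # ---- RE cells -----------------------------------------------------
    Vr = s.V_re
    amr, bmr, ahr, bhr = na_rates(Vr, re.v_shift_Na)
    anr, bnr = k_rates(Vr, re.v_shift_K)
    i_na_r = re.g_Na * s.m_re ** 3 * s.h_re * (Vr - re.E_Na)
    i_k_r = re.g_K * s.n_re ** 4 * (Vr - re.E_K)
    i_l_r = re.g_leak * (Vr - re.E_leak)
    i_kl_r = re.g_KL * (Vr - re.E_KL)
    mTr, hT_inf_r, tau_hT_r = re_t_gates(Vr)
    i_t_r = re.g_T * mTr ** 2 * s.hT_re * (Vr - re.E_Ca)
    i_syn_re = (g_ampa * s_ampa_sum * (Vr - syn.E_AMPA)
                + g_gabaa_re * s_gabaa_sum * (Vr - syn.E_GABAA_RE)
                + syn.g_ctx_AMPA * s.s_ctx_re * (Vr - syn.E_AMPA))
    for name, term in (("I_Na(RE)", i_na_r), ("I_K(RE)", i_k_r),
                       ("I_T(RE)", i_t_r), ("I_syn(RE)", i_syn_re)):
        if not np.all(np.isfinite(term)):
            raise FloatingPointError(f"non-finite current term {name}")
    iapp_re = config.background_excitation_RE + drive_re
    dV_re = (-i_na_r - i_k_r - i_l_r - i_kl_r - i_t_r - i_syn_re + iapp_re) \
        / re.membrane_capacitance
    ft_re = transmitter(Vr)

    return NetworkState(
        V_tc=dV_tc,
        m_tc=am * (1 - s.m_tc) - bm * s.m_tc,
        h_tc=ah * (1 - s.h_tc) - bh * s.h_tc,
        n_tc=an * (1 - s.n_tc) - bn * s.n_tc,
        hT_tc=(hT_inf - s.hT_tc) / tau_hT,
        Ca_tc=-tc.Ca_influx * i_t + (tc.Ca_rest - s.Ca_tc) / tc.Ca_tau,
        O_h=(a_h * (1 - s.O_h - s.OL_h) - b_h * s.O_h
             - tc.lock_rate * s.P1_h * s.O_h + tc.unlock_rate * s.OL_h),
        P1_h=tc.ca_bind_rate * ca4 * (1 - s.P1_h) - tc.ca_unbind_rate * s.P1_h,
        OL_h=tc.lock_rate * s.P1_h * s.O_h - tc.unlock_rate * s.OL_h,
        s_ampa=syn.open_rate_AMPA * ft_tc * (1 - s.s_ampa) - s.s_ampa / syn.tau_AMPA,
        s_ctx_tc=-s.s_ctx_tc / syn.tau_AMPA,
        V_re=dV_re,
        m_re=amr * (1 - s.m_re) - bmr * s.m_re,
        h_re=ahr * (1 - s.h_re) - bhr * s.h_re,
        n_re=anr * (1 - s.n_re) - bnr * s.n_re,
        hT_re=(hT_inf_r - s.hT_re) / tau_hT_r,
        s_gabaa=(syn.open_rate_GABAA * ft_re * (1 - s.s_gabaa)
                 - s.s_gabaa / tau_gabaa),
        R_gabab=syn.gb_K1 * ft_re * (1 - s.R_gabab) - syn.gb_K2 * s.R_gabab,
        G_gabab=syn.gb_K3 * s.R_gabab - syn.gb_K4 * s.G_gabab,
        s_ctx_re=-s.s_ctx_re / syn.tau_AMPA,
    )


def pack_params(config: NetworkConfig) -> np.ndarray:
    """Kernel parameter vector for ``config`` (see ``_kernel``)."""
    return K.pack_params(config)
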