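"""Compiled fixed-step RK4 integrator for the TC-RE network.

State layout (structure-of-arrays, one flat float64 vector):

  TC block: V, m, h, n, hT, Ca, O, P1, OL, sAMPA, sCtx   (11 x n_TC)
  RE block: V, m, h, n, hT, sGABAA, R, G, sCtx           (9 x n_RE)

Parameters travel as a flat float64 vector ``P`` indexed by the module
constants below; the per-interval dose multiplier and background-excitation
steps arrive as segment arrays so a single continuous run can switch dose
and drive mid-simulation (slow-wave UP/DOWN composites).

The same right-hand side exists in readable numpy form in ``network.py``;
the two are cross-checked by the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NV_TC = 11
NV_RE = 9

# TC variable slots
TC_V, TC_M, TC_H, TC_N, TC_HT, TC_CA, TC_O, TC_P1, TC_OL, TC_SA, TC_SC = range(11)
# RE variable slots
RE_V, RE_M, RE_H, RE_N, RE_HT, RE_SG, RE_R, RE_G, RE_SC = range(9)

# parameter vector indices
(P_C_TC, P_GNA_TC, P_ENA_TC, P_GK_TC, P_EK_TC, P_GL_TC, P_EL_TC, P_GKL_TC,
 P_EKL_TC, P_GT_TC, P_CAO, P_CAREST, P_CATAU, P_CAINFLUX, P_NERNST,
 P_GH, P_EH, P_GINC, P_K1, P_K2, P_K3, P_K4, P_VSNA_TC, P_VSK_TC,
 P_C_RE, P_GNA_RE, P_ENA_RE, P_GK_RE, P_EK_RE, P_GL_RE, P_EL_RE, P_GKL_RE,
 P_EKL_RE, P_GT_RE, P_ECA_RE, P_VSNA_RE, P_VSK_RE,
 P_GAMPA, P_EAMPA, P_TAUAMPA, P_AAMPA,
 P_GGABAA_TC, P_EGABAA_TC, P_GGABAA_RE, P_EGABAA_RE, P_TAUGABAA, P_AGABAA,
 P_GGABAB, P_EGABAB, P_K1B, P_K2B, P_K3B, P_K4B, P_KDB,
 P_GCTX, P_IAPP_TC, P_IAPP_RE, P_PHIHT) = range(58)

N_PARAMS = 58


def pack_params(config) -> np.ndarray:
    """Flatten a NetworkConfig into the kernel parameter vector.

    Dose multipliers are NOT applied here — the kernel applies the segment's
    multiplier to g_GABAA and tau_GABAA at run time.
    """
    tc, re, syn = config.tc, config.re, config.syn
    P = np.zeros(N_PARAMS)
    P[P_C_TC] = tc.membrane_capacitance
    P[P_GNA_TC], P[P_ENA_TC] = tc.g_Na, tc.E_Na
    P[P_GK_TC], P[P_EK_TC] = tc.g_K, tc.E_K
    P[P_GL_TC], P[P_EL_TC] = tc.g_leak, tc.E_leak
    P[P_GKL_TC], P[P_EKL_TC] = tc.g_KL, tc.E_KL
    P[P_GT_TC] = tc.g_T
    P[P_CAO], P[P_CAREST], P[P_CATAU] = tc.Ca_o, tc.Ca_rest, tc.Ca_tau
    P[P_CAINFLUX], P[P_NERNST] = tc.Ca_influx, tc.nernst_factor
    P[P_GH], P[P_EH], P[P_GINC] = tc.g_H, tc.E_H, tc.locked_gain
    P[P_K1], P[P_K2] = tc.ca_bind_rate, tc.ca_unbind_rate
    P[P_K3], P[P_K4] = tc.lock_rate, tc.unlock_rate
    P[P_VSNA_TC], P[P_VSK_TC] = tc.v_shift_Na, tc.v_shift_K
    P[P_C_RE] = re.membrane_capacitance
    P[P_GNA_RE], P[P_ENA_RE] = re.g_Na, re.E_Na
    P[P_GK_RE], P[P_EK_RE] = re.g_K, re.E_K
    P[P_GL_RE], P[P_EL_RE] = re.g_leak, re.E_leak
    P[P_GKL_RE], P[P_EKL_RE] = re.g_KL, re.E_KL
    P[P_GT_RE], P[P_ECA_RE] = re.g_T, re.E_Ca
    P[P_VSNA_RE], P[P_VSK_RE] = re.v_shift_Na, re.v_shift_K
    P[P_GAMPA], P[P_EAMPA] = syn.g_AMPA_TC_to_RE, syn.E_AMPA
    P[P_TAUAMPA], P[P_AAMPA] = syn.tau_AMPA, syn.open_rate_AMPA
    P[P_GGABAA_TC], P[P_EGABAA_TC] = syn.g_GABAA_RE_to_TC, syn.E_GABAA_TC
    P[P_GGABAA_RE], P[P_EGABAA_RE] = syn.g_GABAA_RE_to_RE, syn.E_GABAA_RE
    P[P_TAUGABAA], P[P_AGABAA] = syn.tau_GABAA, syn.open_rate_GABAA
    P[P_GGABAB], P[P_EGABAB] = syn.g_GABAB_RE_to_TC, syn.E_GABAB
    P[P_K1B], P[P_K2B], P[P_K3B], P[P_K4B], P[P_KDB] = (
        syn.gb_K1, syn.gb_K2, syn.gb_K3, syn.gb_K4, syn.gb_Kd)
    P[P_GCTX] = syn.g_ctx_AMPA
    P[P_IAPP_TC] = config.background_excitation_TC
    P[P_IAPP_RE] = config.background_excitation_RE
    P[P_PHIHT] = tc.phi_hT
    return P


@njit(cache=True, fastmath=True, error_model="numpy")
def _vtrap(x, y):
    r = x / y
    if abs(r) < 1e-6:
        return y * (1.0 - 0.5 * r)
    return x / (math.exp(r) - 1.0)


@njit(cache=True, fastmath=True, error_model="numpy")
def _rhs(y, dy, n_tc, n_re, P, iapp_tc, iapp_re, mult):
    """dy <- f(y). Currents follow the sign convention I>0 = outward."""
    g_gabaa_tc = P[P_GGABAA_TC] * mult / n_re
    g_gabaa_re = P[P_GGABAA_RE] * mult / n_re
    tau_gabaa = P[P_TAUGABAA] * mult
    g_ampa = P[P_GAMPA] / n_tc
    g_gabab = P[P_GGABAB] / n_re

    tc0 = 0
    re0 = NV_TC * n_tc

    # population sums of presynaptic gates
    s_ampa_sum = 0.0
    for i in range(n_tc):
        s_ampa_sum += y[tc0 + TC_SA * n_tc + i]
    s_gabaa_sum = 0.0
    gb_sum = 0.0
    for j in range(n_re):
        s_gabaa_sum += y[re0 + RE_SG * n_re + j]
        G = y[re0 + RE_G * n_re + j]
        g4 = G * G * G * G
        gb_sum += g4 / (g4 + P[P_KDB])

    # ---- TC cells -----------------------------------------------------
    for i in range(n_tc):
        V = y[tc0 + TC_V * n_tc + i]
        m = y[tc0 + TC_M * n_tc + i]
        h = y[tc0 + TC_H * n_tc + i]
        n = y[tc0 + TC_N * n_tc + i]
        hT = y[tc0 + TC_HT * n_tc + i]
        Ca = y[tc0 + TC_CA * n_tc + i]
        O = y[tc0 + TC_O * n_tc + i]
        P1 = y[tc0 + TC_P1 * n_tc + i]
        OL = y[tc0 + TC_OL * n_tc + i]
        sA = y[tc0 + TC_SA * n_tc + i]
        sC = y[tc0 + TC_SC * n_tc + i]

        v2 = V + P[P_VSNA_TC]
        am = 0.32 * _vtrap(13.0 - v2, 4.0)
        bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
        ah = 0.128 * math.exp((17.0 - v2) / 18.0)
        bh = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
        vk = V + P[P_VSK_TC]
        an = 0.032 * _vtrap(15.0 - vk, 5.0)
        bn = 0.5 * math.exp((10.0 - vk) / 40.0)

        i_na = P[P_GNA_TC] * m * m * m * h * (V - P[P_ENA_TC])
        i_k = P[P_GK_TC] * n * n * n * n * (V - P[P_EK_TC])
        i_l = P[P_GL_TC] * (V - P[P_EL_TC])
        i_kl = P[P_GKL_TC] * (V - P[P_EKL_TC])

        mT = 1.0 / (1.0 + math.exp(-(V + 57.0) / 6.2))
        hT_inf = 1.0 / (1.0 + math.exp((V + 81.0) / 4.0))
        tau_hT = (30.8 + (211.4 + math.exp((V + 113.2) / 5.0))
                  / (1.0 + math.exp((V + 84.0) / 3.2))) / P[P_PHIHT]
        ca_eff = Ca if Ca > 1e-6 else 1e-6
        E_Ca = P[P_NERNST] * math.log(P[P_CAO] / ca_eff)
        i_t = P[P_GT_TC] * mT * mT * hT * (V - E_Ca)

        o_inf = 1.0 / (1.0 + math.exp((V + 75.0) / 5.5))
        tau_o = 20.0 + 1000.0 / (math.exp((V + 71.5) / 14.2)
                                 + math.exp(-(V + 89.0) / 11.6))
        a_h = o_inf / tau_o
        b_h = (1.0 - o_inf) / tau_o
        i_h = P[P_GH] * (O + P[P_GINC] * OL) * (V - P[P_EH])

        i_syn = (g_gabaa_tc * s_gabaa_sum * (V - P[P_EGABAA_TC])
                 + g_gabab * gb_sum * (V - P[P_EGABAB])
                 + P[P_GCTX] * sC * (V - P[P_EAMPA]))

        dy[tc0 + TC_V * n_tc + i] = (-i_na - i_k - i_l - i_kl - i_t - i_h
                                     - i_syn + iapp_tc) / P[P_C_TC]
        dy[tc0 + TC_M * n_tc + i] = am * (1.0 - m) - bm * m
        dy[tc0 + TC_H * n_tc + i] = ah * (1.0 - h) - bh * h
        dy[tc0 + TC_N * n_tc + i] = an * (1.0 - n) - bn * n
        dy[tc0 + TC_HT * n_tc + i] = (hT_inf - hT) / tau_hT
        dy[tc0 + TC_CA * n_tc + i] = (-P[P_CAINFLUX] * i_t
                                      + (P[P_CAREST] - Ca) / P[P_CATAU])
        ca4 = ca_eff * ca_eff * ca_eff * ca_eff
        dy[tc0 + TC_O * n_tc + i] = (a_h * (1.0 - O - OL) - b_h * O
                                     - P[P_K3] * P1 * O + P[P_K4] * OL)
        dy[tc0 + TC_P1 * n_tc + i] = P[P_K1] * ca4 * (1.0 - P1) - P[P_K2] * P1
        dy[tc0 + TC_OL * n_tc + i] = P[P_K3] * P1 * O - P[P_K4] * OL
        ft = 0.5 * (1.0 + math.tanh(V / 4.0))
        dy[tc0 + TC_SA * n_tc + i] = P[P_AAMPA] * ft * (1.0 - sA) - sA / P[P_TAUAMPA]
        dy[tc0 + TC_SC * n_tc + i] = -sC / P[P_TAUAMPA]

    # ---- RE cells -----------------------------------------------------
    for j in range(n_re):
        V = y[re0 + RE_V * n_re + j]
        m = y[re0 + RE_M * n_re + j]
        h = y[re0 + RE_H * n_re + j]
        n = y[re0 + RE_N * n_re + j]
        hT = y[re0 + RE_HT * n_re + j]
        sG = y[re0 + RE_SG * n_re + j]
        R = y[re0 + RE_R * n_re + j]
        G = y[re0 + RE_G * n_re + j]
        sC = y[re0 + RE_SC * n_re + j]

        v2 = V + P[P_VSNA_RE]
        am = 0.32 * _vtrap(13.0 - v2, 4.0)
        bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
        ah = 0.128 * math.exp((17.0 - v2) / 18.0)
        bh = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
        vk = V + P[P_VSK_RE]
        an = 0.032 * _vtrap(15.0 - vk, 5.0)
        bn = 0.5 * math.exp((10.0 - vk) / 40.0)

        i_na = P[P_GNA_RE] * m * m * m * h * (V - P[P_ENA_RE])
        i_k = P[P_GK_RE] * n * n * n * n * (V - P[P_EK_RE])
        i_l = P[P_GL_RE] * (V - P[P_EL_RE])
        i_kl = P[P_GKL_RE] * (V - P[P_EKL_RE])

        mT = 1.0 / (1.0 + math.exp(-(V + 52.0) / 7.4))
        hT_inf = 1.0 / (1.0 + math.exp((V + 80.0) / 5.0))
        tau_hT = (85.0 + 1.0 / (math.exp((V + 48.0) / 4.0)
                                + math.exp(-(V + 407.0) / 50.0))) / 3.73
        i_t = P[P_GT_RE] * mT * mT * hT * (V - P[P_ECA_RE])

        i_syn = (g_ampa * s_ampa_sum * (V - P[P_EAMPA])
                 + g_gabaa_re * s_gabaa_sum * (V - P[P_EGABAA_RE])
                 + P[P_GCTX] * sC * (V - P[P_EAMPA]))

        dy[re0 + RE_V * n_re + j] = (-i_na - i_k - i_l - i_kl - i_t
                                     - i_syn + iapp_re) / P[P_C_RE]
        dy[re0 + RE_M * n_re + j] = am * (1.0 - m) - bm * m
        dy[re0 + RE_H * n_re + j] = ah * (1.0 - h) - bh * h
        dy[re0 + RE_N * n_re + j] = an * (1.0 - n) - bn * n
        dy[re0 + RE_HT * n_re + j] = (hT_inf - hT) / tau_hT
        ft = 0.5 * (1.0 + math.tanh(V / 4.0))
        dy[re0 + RE_SG * n_re + j] = (P[P_AGABAA] * ft * (1.0 - sG)
                                      - sG / tau_gabaa)
        dy[re0 + RE_R * n_re + j] = P[P_K1B] * ft * (1.0 - R) - P[P_K2B] * R
        dy[re0 + RE_G * n_re + j] = P[P_K3B] * R - P[P_K4B] * G
        dy[re0 + RE_SC * n_re + j] = -sC / P[P_TAUAMPA]


@njit(cache=True, fastmath=True, error_model="numpy")
def _clamp_state(y, n_tc, n_re):
    """Keep gating/activation variables in [0,1] and Ca positive."""
    re0 = NV_TC * n_tc
    for slot in (TC_M, TC_H, TC_N, TC_HT, TC_O, TC_P1, TC_OL, TC_SA, TC_SC):
        for i in range(n_tc):
            v = y[slot * n_tc + i]
            if v < 0.0:
                y[slot * n_tc + i] = 0.0
            elif v > 1.0:
                y[slot * n_tc + i] = 1.0
    for i in range(n_tc):
        if y[TC_CA * n_tc + i] < 1e-9:
            y[TC_CA * n_tc + i] = 1e-9
    for slot in (RE_M, RE_H, RE_N, RE_HT, RE_SG, RE_R, RE_SC):
        for j in range(n_re):
            v = y[re0 + slot * n_re + j]
            if v < 0.0:
                y[re0 + slot * n_re + j] = 0.0
            elif v > 1.0:
                y[re0 + slot * n_re + j] = 1.0
    for j in range(n_re):
        if y[re0 + RE_G * n_re + j] < 0.0:
            y[re0 + RE_G * n_re + j] = 0.0


@njit(cache=True, fastmath=True, error_model="numpy")
def integrate_kernel(y0, n_tc, n_re, P, dt, n_steps, rec_stride,
                     seg_ends, seg_iapp_tc, seg_iapp_re, seg_mult,
                     sp_times, sp_targets, ctx_jump):
    """Fixed-step RK4 with per-segment dose/drive and event-driven cortical
    AMPA jumps. Returns (status, fail_time, t_rec, vtc, vre, ht, ca, ih).

    status 0 = ok, 1 = non-finite state encountered at fail_time.
    """
    n = y0.size
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)

    n_rec = n_steps // rec_stride + 1
    t_rec = np.empty(n_rec)
    vtc = np.empty((n_rec, n_tc))
    vre = np.empty((n_rec, n_re))
    ht = np.empty((n_rec, n_tc))
    ca = np.empty((n_rec, n_tc))
    ih = np.empty((n_rec, n_tc))

    seg = 0
    sp = 0
    rec = 0
    status = 0
    fail_t = -1.0
    re0 = NV_TC * n_tc

    for step in range(n_steps + 1):
        t = step * dt
        while seg < seg_ends.size - 1 and t >= seg_ends[seg]:
            seg += 1
        iapp_tc = P[P_IAPP_TC] + seg_iapp_tc[seg]
        iapp_re = P[P_IAPP_RE] + seg_iapp_re[seg]
        mult = seg_mult[seg]

        if step % rec_stride == 0:
            t_rec[rec] = t
            ok = True
            for i in range(n_tc):
                V = y[TC_V * n_tc + i]
                if not math.isfinite(V):
                    ok = False
                vtc[rec, i] = V
                ht[rec, i] = y[TC_HT * n_tc + i]
                ca[rec, i] = y[TC_CA * n_tc + i]
                ih[rec, i] = (P[P_GH] * (y[TC_O * n_tc + i]
                                         + P[P_GINC] * y[TC_OL * n_tc + i])
                              * (V - P[P_EH]))
            for j in range(n_re):
                V = y[re0 + RE_V * n_re + j]
                if not math.isfinite(V):
                    ok = False
                vre[rec, j] = V
            rec += 1
            if not ok:
                status = 1
                fail_t = t
                break
        if step == n_steps:
            break

        # cortical spike events scheduled within [t, t + dt)
        while sp < sp_times.size and sp_times[sp] < t + dt:
            tgt = sp_targets[sp]
            if tgt < n_tc:
                idx = TC_SC * n_tc + tgt
            else:
                idx = re0 + RE_SC * n_re + (tgt - n_tc)
            y[idx] += (1.0 - y[idx]) * ctx_jump
            sp += 1

        _rhs(y, k1, n_tc, n_re, P, iapp_tc, iapp_re, mult)
        for q in range(n):
            yt[q] = y[q] + 0.5 * dt * k1[q]
        _rhs(yt, k2, n_tc, n_re, P, iapp_tc, iapp_re, mult)
        for q in range(n):
            yt[q] = y[q] + 0.5 * dt * k2[q]
        _rhs(yt, k3, n_tc, n_re, P, iapp_tc, iapp_re, mult)
        for q in range(n):
            yt[q] = y[q] + dt * k3[q]
        _rhs(yt, k4, n_tc, n_re, P, iapp_tc, iapp_re, mult)
        for q in range(n):
            y[q] += dt / 6.0 * (k1[q] + 2.0 * k2[q] + 2.0 * k3[q] + k4[q])
        _clamp_state(y, n_tc, n_re)

    return status, fail_t, t_rec[:rec], vtc[:rec], vre[:rec], ht[:rec], ca[:rec], ih[:rec], y
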