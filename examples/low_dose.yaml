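n_TC: 10
n_RE: 10
all_to_all: true
background_excitation_TC: 0.0
background_excitation_RE: 0.0
tc:
  membrane_capacitance: 1.0
  g_Na: 90.0
  E_Na: 50.0
  g_K: 10.0
  E_K: -100.0
  g_leak: 0.01
  E_leak: -70.0
  g_KL: 0.024
  E_KL: -100.0
  g_T: 2.5
  Ca_o: 2.0
  Ca_rest: 0.00024
  Ca_tau: 5.0
  Ca_influx: 5.18e-05
  nernst_factor: 13.31
  phi_hT: 3.73
  g_H: 0.01
  E_H: -40.0
  locked_gain: 3.0
  ca_bind_rate: 25000000.0
  ca_unbind_rate: 0.0004
  lock_rate: 0.1
  unlock_rate: 0.001
  v_shift_Na: 35.0
  v_shift_K: 25.0
re:
  membrane_capacitance: 1.0
  g_Na: 100.0
  E_Na: 50.0
  g_K: 10.0
  E_K: -100.0
  g_leak: 0.05
  E_leak: -77.0
  g_KL: 0.01
  E_KL: -100.0
  g_T: 2.3
  E_Ca: 120.0
  v_shift_Na: 55.0
  v_shift_K: 55.0
syn:
  g_AMPA_TC_to_RE: 0.04
  E_AMPA: 1.0
  tau_AMPA: 2.0
  open_rate_AMPA: 10.0
  g_GABAA_RE_to_TC: 0.1
  E_GABAA_TC: -78.0
  g_GABAA_RE_to_RE: 0.06
  E_GABAA_RE: -75.0
  tau_GABAA: 9.0
  open_rate_GABAA: 10.0
  g_GABAB_RE_to_TC: 0.015
  E_GABAB: -95.0
  gb_K1: 0.26
  gb_K2: 0.0013
  gb_K3: 0.098
  gb_K4: 0.033
  gb_Kd: 100.0
  g_ctx_AMPA: 0.08
propofol:
  multiplier: 2.0
  scale_gabab: false
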