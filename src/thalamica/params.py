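"""Parameter containers for the thalamic TC–RE network.

Units throughout the package: mV, ms, mS/cm**2, uA/cm**2, uF/cm**2, mM.
Sign convention: positive applied current depolarizes, so the membrane
equation reads  C dV/dt = -(intrinsic) - (synaptic) + I_applied + I_drive.

The biophysics follows the Destexhe-lineage thalamic slice models: a
thalamocortical (TC) relay cell carrying the low-threshold T-type calcium
current (instantaneous activation mT, slow de-inactivation hT) and the
calcium-regulated hyperpolarization-activated H current, and a reticular
(RE) cell carrying its own T current; RE cells inhibit TC cells through
GABA_A (strong) and GABA_B (weak) synapses and each other through GABA_A,
while TC cells excite RE cells through AMPA. Every constant is exposed here
so alternative parameterizations can be dropped in from configuration
without code changes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "TCCellParams",
    "RECellParams",
    "SynapseParams",
    "PropofolCondition",
    "NetworkConfig",
    "baseline",
    "low_dose",
    "high_dose",
    "PRESETS",
]


class ConfigError(ValueError):
    """Raised when a parameter block violates its invariants."""


@dataclass
class TCCellParams:
    """Thalamocortical relay cell: HH spike currents, leaks, T and H currents.

    The H current carries the calcium-dependent up-regulation that
    terminates spindles: intracellular Ca (entering through the T current)
    binds a regulating factor which locks open H channels into a state with
    ``locked_gain``-fold conductance.
    """

    membrane_capacitance: float = 1.0      # uF/cm^2
    g_Na: float = 90.0                     # mS/cm^2
    E_Na: float = 50.0                     # mV
    g_K: float = 10.0
    E_K: float = -100.0
    g_leak: float = 0.01
    E_leak: float = -70.0
    g_KL: float = 0.024                    # high K-leak: hyperpolarized thalamus
    E_KL: float = -100.0
    # T-type calcium current (activation instantaneous at steady state)
    g_T: float = 2.5
    Ca_o: float = 2.0                      # mM extracellular
    Ca_rest: float = 2.4e-4                # mM resting intracellular
    Ca_tau: float = 5.0                    # ms removal time constant
    Ca_influx: float = 5.18e-5             # mM cm^2 / (uA ms): 10/(2 F d), d = 1 um
    nernst_factor: float = 13.31           # RT/2F in mV at ~36 C
    phi_hT: float = 3.73                   # Q10 speed-up of the hT time constant
    # H current with Ca-dependent up-regulation
    g_H: float = 0.01
    E_H: float = -40.0
    locked_gain: float = 3.0               # conductance gain of Ca-locked channels
    ca_bind_rate: float = 2.5e7            # k1, mM^-4 ms^-1 (half act. 2e-3 mM)
    ca_unbind_rate: float = 4.0e-4         # k2, ms^-1
    lock_rate: float = 0.1                 # k3, ms^-1
    unlock_rate: float = 1.0e-3            # k4, ms^-1
    # Traub-style rate-function voltage shifts
    v_shift_Na: float = 35.0
    v_shift_K: float = 25.0

    def validate(self) -> None:
        for name in ("g_Na", "g_K", "g_leak", "g_KL", "g_T", "g_H"):
            if getattr(self, name) < 0:
                raise ConfigError(f"TCCellParams.{name} must be >= 0")
        if self.membrane_capacitance <= 0:
            raise ConfigError("membrane_capacitance must be > 0")
        if not (self.E_K < self.E_leak < self.E_Na):
            raise ConfigError("expected E_K < E_leak < E_Na")
        if self.Ca_rest <= 0 or self.Ca_tau <= 0:
            raise ConfigError("Ca constants must be positive")


@dataclass
class RECellParams:
    """Thalamic reticular cell: HH spike currents, leaks, RE-type T current."""

    membrane_capacitance: float = 1.0
    g_Na: float = 100.0
    E_Na: float = 50.0
    g_K: float = 10.0
    E_K: float = -100.0
    g_leak: float = 0.05
    E_leak: float = -77.0
    g_KL: float = 0.01
    E_KL: float = -100.0
    g_T: float = 2.3
    E_Ca: float = 120.0                    # fixed Ca reversal for the RE T current
    v_shift_Na: float = 55.0
    v_shift_K: float = 55.0

    def validate(self) -> None:
        for name in ("g_Na", "g_K", "g_leak", "g_KL", "g_T"):
            if getattr(self, name) < 0:
                raise ConfigError(f"RECellParams.{name} must be >= 0")
        if self.membrane_capacitance <= 0:
            raise ConfigError("membrane_capacitance must be > 0")


@dataclass
class SynapseParams:
    """Synaptic conductances and kinetics.

    Maximal conductances are *post-normalization* totals: each postsynaptic
    cell divides the listed conductance by the number of presynaptic cells,
    so total drive is invariant to network size (enabling reduced-size runs
    that preserve regimes).

    Activation gates follow first-order transmitter kinetics driven by a
    smooth sigmoidal function of presynaptic voltage; after presynaptic
    silence GABA_A activation decays as exp(-t / tau_GABAA).
    """

    g_AMPA_TC_to_RE: float = 0.04
    E_AMPA: float = 1.0
    tau_AMPA: float = 2.0                  # ms decay
    open_rate_AMPA: float = 10.0           # ms^-1 peak opening rate

    g_GABAA_RE_to_TC: float = 0.1
    E_GABAA_TC: float = -78.0
    g_GABAA_RE_to_RE: float = 0.06
    E_GABAA_RE: float = -75.0
    tau_GABAA: float = 9.0                 # ms decay; scaled by the dose multiplier
    open_rate_GABAA: float = 10.0

    # weak RE->TC GABA_B: two-stage (receptor -> G protein) kinetics with a
    # 4th-power G-protein activation of a K conductance
    g_GABAB_RE_to_TC: float = 0.015
    E_GABAB: float = -95.0
    gb_K1: float = 0.26                    # mM^-1 ms^-1 (x Tmax 0.5 mM folded in)
    gb_K2: float = 0.0013                  # ms^-1
    gb_K3: float = 0.098                   # ms^-1
    gb_K4: float = 0.033                   # ms^-1
    gb_Kd: float = 100.0
    # cortical AMPAergic input gates (event-driven, same AMPA kinetics)
    g_ctx_AMPA: float = 0.08

    def validate(self) -> None:
        for name in (
            "g_AMPA_TC_to_RE",
            "g_GABAA_RE_to_TC",
            "g_GABAA_RE_to_RE",
            "g_GABAB_RE_to_TC",
            "g_ctx_AMPA",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"SynapseParams.{name} must be >= 0")
        if self.tau_GABAA <= 0 or self.tau_AMPA <= 0:
            raise ConfigError("synaptic time constants must be > 0")
        if self.g_GABAB_RE_to_TC > self.g_GABAA_RE_to_TC:
            raise ConfigError("GABA_B must stay weak relative to GABA_A")


@dataclass(frozen=True)
class PropofolCondition:
    """Propofol dose as a joint multiplier on g_GABAA and tau_GABAA.

    multiplier 1 = baseline (identity), 2 = low dose (200% of baseline),
    3 = high dose (300% of baseline). GABA_B is unaffected by default.
    """

    multiplier: float = 1.0
    scale_gabab: bool = False

    def __post_init__(self) -> None:
        if self.multiplier < 1.0:
            raise ConfigError("propofol multiplier must be >= 1")


def apply_propofol(syn: SynapseParams, condition: PropofolCondition) -> SynapseParams:
    """Return a new SynapseParams with all GABA_A conductances and the GABA_A
    decay time constant scaled by the dose multiplier.

    tau_GABAA scales exactly linearly (the dose is defined by the decay time
    constant); everything non-GABA_A is untouched unless ``scale_gabab``.
    """
    m = condition.multiplier
    if m < 1.0:
        raise ConfigError("propofol multiplier must be >= 1")
    out = dataclasses.replace(
        syn,
        g_GABAA_RE_to_TC=syn.g_GABAA_RE_to_TC * m,
        g_GABAA_RE_to_RE=syn.g_GABAA_RE_to_RE * m,
        tau_GABAA=syn.tau_GABAA * m,
    )
    if condition.scale_gabab:
        out = dataclasses.replace(out, g_GABAB_RE_to_TC=syn.g_GABAB_RE_to_TC * m)
    return out


@dataclass
class NetworkConfig:
    """Full network description: cell counts, all-to-all wiring, tonic drive.

    ``background_excitation_TC``/``_RE`` are voltage-invariant applied
    current densities (uA/cm^2); negative values model tonic
    hyperpolarization (loss of brainstem excitation). The TC term is the
    quantity swept in the regime-plane analyses.
    """

    n_TC: int = 10
    n_RE: int = 10
    all_to_all: bool = True
    background_excitation_TC: float = 0.0
    background_excitation_RE: float = 0.0
    tc: TCCellParams = field(default_factory=TCCellParams)
    re: RECellParams = field(default_factory=RECellParams)
    syn: SynapseParams = field(default_factory=SynapseParams)
    propofol: PropofolCondition = field(default_factory=PropofolCondition)

    def validate(self) -> None:
        if self.n_TC < 1 or self.n_RE < 1:
            raise ConfigError("need at least one cell of each type")
        for v in (self.background_excitation_TC, self.background_excitation_RE):
            if not (v == v and abs(v) < 1e6):
                raise ConfigError("background excitation must be finite")
        self.tc.validate()
        self.re.validate()
        self.syn.validate()

    @property
    def effective_syn(self) -> SynapseParams:
        """Synaptic block after the propofol dose transformation."""
        return apply_propofol(self.syn, self.propofol)

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NetworkConfig":
        d = dict(d)
        tc = TCCellParams(**d.pop("tc", {}))
        re = RECellParams(**d.pop("re", {}))
        syn = SynapseParams(**d.pop("syn", {}))
        prop = PropofolCondition(**d.pop("propofol", {}))
        cfg = cls(tc=tc, re=re, syn=syn, propofol=prop, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(text))


def baseline(**overrides: Any) -> NetworkConfig:
    """No-propofol preset (multiplier 1)."""
    return NetworkConfig(propofol=PropofolCondition(1.0), **overrides)


def low_dose(**overrides: Any) -> NetworkConfig:
    """Low-dose propofol preset: g_GABAA and tau_GABAA at 200% of baseline."""
    return NetworkConfig(propofol=PropofolCondition(2.0), **overrides)


def high_dose(**overrides: Any) -> NetworkConfig:
    """High-dose propofol preset: g_GABAA and tau_GABAA at 300% of baseline."""
    return NetworkConfig(propofol=PropofolCondition(3.0), **overrides)


PRESETS = {"baseline": baseline, "low": low_dose, "high": high_dose,
           "low_dose": low_dose, "high_dose": high_dose}
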