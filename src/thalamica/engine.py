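"""Fixed-step network integration, spike extraction, result persistence.

The integrator is a deterministic 4th-order Runge-Kutta scheme with a
default step of 0.01 ms; given identical configuration and seed, reruns are
bit-identical. Traces are recorded on a decimated grid (default every
0.1 ms), dense enough that every sodium spike is sampled several times.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import _kernel as K
from .currents import h_gates, k_rates, na_rates, re_t_gates, tc_t_gates
from .network import NetworkState
from .params import NetworkConfig

__all__ = [
    "IntegratorConfig",
    "SimulationResult",
    "initialize_state",
    "integrate",
    "detect_spikes",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the state diverges; carries the failure time in ms."""

    def __init__(self, message: str, time_ms: float):
        super().__init__(f"{message} at t = {time_ms:.3f} ms")
        self.time_ms = time_ms


@dataclass
class IntegratorConfig:
    dt: float = 0.01                  # ms
    total_duration: float = 4000.0    # ms
    settle_discard: float = 1000.0    # ms dropped before any analysis
    scheme: str = "rk4"
    seed: int = 0
    record_stride_ms: float = 0.1     # trace sampling interval
    init_v_tc: float = -75.0          # mV, pre-jitter initial voltage
    init_v_re: float = -80.0
    init_jitter: float = 1.0          # mV uniform jitter half-width
    spike_threshold: float = 0.0      # mV upward crossing
    spike_dead_time: float = 2.0      # ms refractory guard

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.total_duration >= self.settle_discard >= 0):
            raise ValueError("need total_duration >= settle_discard >= 0")
        if self.scheme != "rk4":
            raise ValueError("only the fixed-step rk4 scheme is provided")


@dataclass
class SimulationResult:
    """Time grid, per-cell traces, spike raster, and full provenance."""

    t: np.ndarray                       # ms, recorded grid
    V_tc: np.ndarray                    # (n_rec, n_TC) mV
    V_re: np.ndarray
    hT_tc: np.ndarray                   # T-current de-inactivation traces
    Ca_tc: np.ndarray                   # mM
    I_h_tc: np.ndarray                  # H-current magnitude traces, uA/cm^2
    spikes_tc: np.ndarray               # (n_spk, 2): cell id, time ms
    spikes_re: np.ndarray
    provenance: dict[str, Any]
    final_state: Optional[NetworkState] = None

    @property
    def n_tc(self) -> int:
        return self.V_tc.shape[1]

    def window(self, t0: float, t1: float | None = None) -> "SimulationResult":
        """Restrict traces and rasters to t in [t0, t1)."""
        t1 = self.t[-1] + 1.0 if t1 is None else t1
        sel = (self.t >= t0) & (self.t < t1)
        def cut(r):
            if r.size == 0:
                return r.reshape(0, 2)
            m = (r[:, 1] >= t0) & (r[:, 1] < t1)
            return r[m]
        return SimulationResult(
            t=self.t[sel], V_tc=self.V_tc[sel], V_re=self.V_re[sel],
            hT_tc=self.hT_tc[sel], Ca_tc=self.Ca_tc[sel],
            I_h_tc=self.I_h_tc[sel], spikes_tc=cut(self.spikes_tc),
            spikes_re=cut(self.spikes_re), provenance=self.provenance)

    # ---- persistence ---------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        import h5py

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with h5py.File(out / "traces.h5", "w") as f:
            for name in ("t", "V_tc", "V_re", "hT_tc", "Ca_tc", "I_h_tc"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["provenance"] = json.dumps(self.provenance)
        for name in ("spikes_tc", "spikes_re"):
            arr = getattr(self, name)
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write("cell_id\ttime_ms\n")
                for cid, tms in arr:
                    fh.write(f"{int(cid)}\t{tms:.3f}\n")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "SimulationResult":
        import h5py

        out = Path(out_dir)
        with h5py.File(out / "traces.h5", "r") as f:
            kw = {name: f[name][...] for name in
                  ("t", "V_tc", "V_re", "hT_tc", "Ca_tc", "I_h_tc")}
            prov = json.loads(f.attrs["provenance"])
        spikes = {}
        for name in ("spikes_tc", "spikes_re"):
            text = (out / f"{name}.tsv").read_text().splitlines()[1:]
            rows = [tuple(map(float, ln.split("\t"))) for ln in text if ln]
            spikes[name] = np.array(rows, dtype=float).reshape(-1, 2)
        return cls(provenance=prov, **kw, **spikes)


def initialize_state(config: NetworkConfig, seed: int = 0,
                     integ: IntegratorConfig | None = None) -> NetworkState:
    """Seeded initial state: gates at their steady states for the initial
    voltage, voltages drawn from a small uniform jitter around the
    configured values, synaptic gates at zero."""
    integ = integ or IntegratorConfig()
    rng = np.random.default_rng(seed)
    n_tc, n_re = config.n_TC, config.n_RE
    v_tc = integ.init_v_tc + integ.init_jitter * (2 * rng.random(n_tc) - 1)
    v_re = integ.init_v_re + integ.init_jitter * (2 * rng.random(n_re) - 1)

    am, bm, ah, bh = na_rates(v_tc, config.tc.v_shift_Na)
    an, bn = k_rates(v_tc, config.tc.v_shift_K)
    _, hT_inf, _ = tc_t_gates(v_tc)
    o_inf, _ = h_gates(v_tc)
    ca = np.full(n_tc, config.tc.Ca_rest)
    bind = config.tc.ca_bind_rate * ca ** 4
    p1 = bind / (bind + config.tc.ca_unbind_rate)

    amr, bmr, ahr, bhr = na_rates(v_re, config.re.v_shift_Na)
    anr, bnr = k_rates(v_re, config.re.v_shift_K)
    _, hT_inf_r, _ = re_t_gates(v_re)

    z_tc = np.zeros(n_tc)
    z_re = np.zeros(n_re)
    return NetworkState(
        V_tc=v_tc, m_tc=am / (am + bm), h_tc=ah / (ah + bh),
        n_tc=an / (an + bn), hT_tc=np.asarray(hT_inf), Ca_tc=ca,
        O_h=np.asarray(o_inf) * 0.0, P1_h=p1, OL_h=z_tc.copy(),
        s_ampa=z_tc.copy(), s_ctx_tc=z_tc.copy(),
        V_re=v_re, m_re=amr / (amr + bmr), h_re=ahr / (ahr + bhr),
        n_re=anr / (anr + bnr), hT_re=np.asarray(hT_inf_r),
        s_gabaa=z_re.copy(), R_gabab=z_re.copy(), G_gabab=z_re.copy(),
        s_ctx_re=z_re.copy(),
    )


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = 0.0,
                  dead_time: float = 2.0) -> np.ndarray:
    """Upward threshold crossings per cell with a refractory guard.

    ``V`` has shape (n_samples, n_cells). Returns an array of
    (cell_id, time_ms) rows sorted by time.
    """
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage traces must be finite")
    rows = []
    above = V >= threshold
    for c in range(V.shape[1]):
        idx = np.flatnonzero(~above[:-1, c] & above[1:, c]) + 1
        if idx.size == 0:
            continue
        times = t[idx]
        keep = [times[0]]
        for tm in times[1:]:
            if tm - keep[-1] >= dead_time:
                keep.append(tm)
        rows.extend((c, tm) for tm in keep)
    if not rows:
        return np.empty((0, 2))
    arr = np.array(rows, dtype=float)
    return arr[np.argsort(arr[:, 1], kind="stable")]


def integrate(state: NetworkState, integ: IntegratorConfig,
              config: NetworkConfig, drive=None) -> SimulationResult:
    """Run the network forward and extract traces and spike rasters.

    ``drive`` is an optional ``thalamica.drive.CompiledDrive`` carrying
    UP/DOWN segment steps, per-segment dose multipliers, and cortical
    Poisson spike events. Raises :class:`SimulationError` on divergence.
    """
    integ.validate()
    config.validate()
    P = K.pack_params(config)
    dt = integ.dt
    n_steps = int(round(integ.total_duration / dt))
    rec_stride = max(1, int(round(integ.record_stride_ms / dt)))

    if drive is None:
        seg_ends = np.array([integ.total_duration + dt])
        seg_iapp_tc = np.zeros(1)
        seg_iapp_re = np.zeros(1)
        seg_mult = np.array([config.propofol.multiplier])
        sp_times = np.empty(0)
        sp_targets = np.empty(0, dtype=np.int64)
        ctx_jump = 0.9
        drive_prov: dict[str, Any] = {}
    else:
        seg_ends = drive.seg_ends
        seg_iapp_tc = drive.seg_iapp_tc
        seg_iapp_re = drive.seg_iapp_re
        seg_mult = drive.seg_mult
        sp_times = drive.spike_times
        sp_targets = drive.spike_targets
        ctx_jump = drive.ctx_jump
        drive_prov = drive.provenance

    out = K.integrate_kernel(
        state.pack(), config.n_TC, config.n_RE, P, dt, n_steps, rec_stride,
        seg_ends, seg_iapp_tc, seg_iapp_re, seg_mult,
        sp_times, sp_targets, ctx_jump)
    status, fail_t, t, vtc, vre, ht, ca, ih, y_final = out
    if status != 0:
        raise SimulationError("non-finite membrane potential", fail_t)

    spikes_tc = detect_spikes(t, vtc, integ.spike_threshold, integ.spike_dead_time)
    spikes_re = detect_spikes(t, vre, integ.spike_threshold, integ.spike_dead_time)
    provenance = {
        "network": config.to_dict(),
        "integrator": dataclasses.asdict(integ),
        "drive": drive_prov,
    }
    return SimulationResult(
        t=t, V_tc=vtc, V_re=vre, hT_tc=ht, Ca_tc=ca, I_h_tc=ih,
        spikes_tc=spikes_tc, spikes_re=spikes_re, provenance=provenance,
        final_state=NetworkState.unpack(y_final, config.n_TC, config.n_RE))


def simulate(config: NetworkConfig, integ: IntegratorConfig | None = None,
             drive=None, seed: int | None = None) -> SimulationResult:
    """Convenience wrapper: initialize (seeded) and integrate."""
    integ = integ or IntegratorConfig()
    if seed is not None:
        integ = dataclasses.replace(integ, seed=seed)
    state = initialize_state(config, seed=integ.seed, integ=integ)
    return integrate(state, integ, config, drive=drive)
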