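"""Synthetic corticothalamic drive: Poisson UP-state firing and UP/DOWN
slow-wave schedules.

The cortex is not modeled mechanistically. A corticothalamic UP state has
two effects on the thalamus: AMPAergic cortical firing drawn from a Poisson
process (default 12 Hz per target cell) and a tonic step in background
excitation. A DOWN state is the absence of both. Schedules list contiguous
UP/DOWN intervals, each with its own dose multiplier and excitation level,
so a single continuous run can traverse a slow-wave cycle and a dose switch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .params import ConfigError, NetworkConfig

__all__ = [
    "DriveConfig",
    "Interval",
    "UpDownSchedule",
    "generate_poisson_spikes",
    "drive_at",
    "CompiledDrive",
    "compile_drive",
    "export_spike_trains",
]


@dataclass
class DriveConfig:
    """Corticothalamic UP-state drive description.

    ``poisson_rate`` is the per-target spike rate (Hz); the AMPA input
    conductance lives in ``SynapseParams.g_ctx_AMPA``. ``targets`` selects
    which populations receive the spiking (TC by default; the RE share of
    corticothalamic drive is a configuration flag).
    """

    poisson_rate: float = 12.0          # Hz
    up_excitation_step: float = 0.4     # uA/cm^2 added during UP states
    targets: tuple[str, ...] = ("TC",)
    seed: int = 0

    def validate(self) -> None:
        if self.poisson_rate < 0:
            raise ConfigError("poisson_rate must be >= 0")
        if not np.isfinite(self.up_excitation_step):
            raise ConfigError("up_excitation_step must be finite")
        for t in self.targets:
            if t.upper() not in ("TC", "RE"):
                raise ConfigError(f"unknown drive target {t!r}")


@dataclass(frozen=True)
class Interval:
    state: str                    # "UP" | "DOWN"
    duration: float               # ms
    dose_multiplier: float = 1.0
    background_excitation: float = 0.0   # uA/cm^2 added to the config baseline

    def __post_init__(self) -> None:
        if self.state.upper() not in ("UP", "DOWN"):
            raise ConfigError("interval state must be UP or DOWN")
        if self.duration <= 0:
            raise ConfigError("interval durations must be > 0")
        if self.dose_multiplier < 1:
            raise ConfigError("dose multiplier must be >= 1")


@dataclass
class UpDownSchedule:
    """Ordered, contiguous UP/DOWN intervals starting at t = 0."""

    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        self.intervals = tuple(self.intervals)
        if not self.intervals:
            raise ConfigError("schedule needs at least one interval")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative interval end times (ms); partition time exactly."""
        return np.cumsum([iv.duration for iv in self.intervals])

    @property
    def total_duration(self) -> float:
        return float(self.boundaries[-1])

    @classmethod
    def alternating(cls, n_cycles: int, up_ms: float = 500.0,
                    down_ms: float = 500.0, dose_multiplier: float = 1.0,
                    up_excitation: float = 0.0, down_excitation: float = 0.0,
                    start: str = "DOWN") -> "UpDownSchedule":
        """A slow-wave-like alternation (default 500 ms UP / 500 ms DOWN,
        i.e. a ~1 Hz slow oscillation)."""
        ivs = []
        order = ("DOWN", "UP") if start.upper() == "DOWN" else ("UP", "DOWN")
        for _ in range(n_cycles):
            for st in order:
                ivs.append(Interval(
                    st, up_ms if st == "UP" else down_ms, dose_multiplier,
                    up_excitation if st == "UP" else down_excitation))
        return cls(tuple(ivs))


def generate_poisson_spikes(rate: float, duration: float, n_targets: int,
                            seed: int = 0, t_offset: float = 0.0) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per target.

    ``rate`` in Hz, ``duration`` in ms. Inter-spike intervals are
    exponential; trains are reproducible per seed and independent across
    targets. Returns a list of sorted spike-time arrays (ms).
    """
    if rate < 0:
        raise ConfigError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    for _ in range(n_targets):
        if rate == 0:
            trains.append(np.empty(0))
            continue
        mean_isi = 1000.0 / rate
        n_guess = max(16, int(duration / mean_isi * 2 + 10 * np.sqrt(duration / mean_isi)))
        times = np.cumsum(rng.exponential(mean_isi, size=n_guess))
        while times.size and times[-1] < duration:
            times = np.concatenate(
                [times, times[-1] + np.cumsum(rng.exponential(mean_isi, size=n_guess))])
        trains.append(times[times < duration] + t_offset)
    return trains


def drive_at(t: float, schedule: UpDownSchedule, drive: DriveConfig):
    """(poisson rate active, tonic UP step, dose multiplier) at time t (ms).

    DOWN intervals return zero spiking and zero step; UP intervals return
    the configured Poisson rate and excitation step. (The per-interval
    background-excitation level is separate and applies in both states.)
    Raises if t is outside the schedule span.
    """
    ends = schedule.boundaries
    if t < 0 or t >= ends[-1]:
        raise ValueError(f"t = {t} ms outside schedule span [0, {ends[-1]})")
    k = int(np.searchsorted(ends, t, side="right"))
    iv = schedule.intervals[k]
    if iv.state.upper() == "UP":
        return drive.poisson_rate, drive.up_excitation_step, iv.dose_multiplier
    return 0.0, 0.0, iv.dose_multiplier


@dataclass
class CompiledDrive:
    """Kernel-ready drive: segment arrays plus a merged cortical event list."""

    seg_ends: np.ndarray
    seg_iapp_tc: np.ndarray
    seg_iapp_re: np.ndarray
    seg_mult: np.ndarray
    spike_times: np.ndarray
    spike_targets: np.ndarray
    ctx_jump: float = 0.9
    provenance: dict[str, Any] = field(default_factory=dict)


def compile_drive(schedule: UpDownSchedule, drive: DriveConfig,
                  config: NetworkConfig) -> CompiledDrive:
    """Realize a schedule as segment arrays and seeded Poisson events.

    UP intervals contribute their excitation step to the populations named
    in ``drive.targets`` for spiking and to the TC background-excitation
    term for the tonic step; DOWN intervals contribute neither. The
    per-interval dose multiplier is passed through to the kernel, which
    scales g_GABAA and tau_GABAA segment by segment.
    """
    drive.validate()
    ends = schedule.boundaries.astype(float)
    n_seg = len(schedule.intervals)
    seg_iapp_tc = np.zeros(n_seg)
    seg_iapp_re = np.zeros(n_seg)
    seg_mult = np.ones(n_seg)

    n_tc, n_re = config.n_TC, config.n_RE
    want_tc = any(t.upper() == "TC" for t in drive.targets)
    want_re = any(t.upper() == "RE" for t in drive.targets)

    all_times: list[np.ndarray] = []
    all_targets: list[np.ndarray] = []
    t0 = 0.0
    for k, iv in enumerate(schedule.intervals):
        seg_mult[k] = iv.dose_multiplier
        if iv.state.upper() == "UP":
            seg_iapp_tc[k] = iv.background_excitation + drive.up_excitation_step
            seg_iapp_re[k] = 0.0
            n_targets = (n_tc if want_tc else 0) + (n_re if want_re else 0)
            trains = generate_poisson_spikes(
                drive.poisson_rate, iv.duration, n_targets,
                seed=drive.seed + 7919 * k, t_offset=t0)
            tgt_ids = ([i for i in range(n_tc)] if want_tc else []) \
                + ([n_tc + j for j in range(n_re)] if want_re else [])
            for tid, tr in zip(tgt_ids, trains):
                if tr.size:
                    all_times.append(tr)
                    all_targets.append(np.full(tr.size, tid, dtype=np.int64))
        else:
            seg_iapp_tc[k] = iv.background_excitation
        t0 = float(ends[k])

    if all_times:
        times = np.concatenate(all_times)
        targets = np.concatenate(all_targets)
        order = np.argsort(times, kind="stable")
        times, targets = times[order], targets[order]
    else:
        times = np.empty(0)
        targets = np.empty(0, dtype=np.int64)

    prov = {
        "drive": dataclasses.asdict(drive) | {"targets": list(drive.targets)},
        "schedule": [dataclasses.asdict(iv) for iv in schedule.intervals],
    }
    return CompiledDrive(
        seg_ends=ends, seg_iapp_tc=seg_iapp_tc, seg_iapp_re=seg_iapp_re,
        seg_mult=seg_mult, spike_times=times, spike_targets=targets,
        provenance=prov)


def export_spike_trains(drive: CompiledDrive, path) -> None:
    """Write the compiled cortical spike events as TSV (target_id, time_ms)."""
    from pathlib import Path

    lines = ["target_id\ttime_ms"]
    lines += [f"{int(tgt)}\t{t:.3f}"
              for tgt, t in zip(drive.spike_targets, drive.spike_times)]
    Path(path).write_text("\n".join(lines) + "\n")
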