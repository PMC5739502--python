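"""Six-way behavior-regime classification of simulated TC activity.

The taxonomy (matching the regime-map colorings of hyperpolarized-thalamus
studies): nonphysiological, silent/hyperpolarized, transients/spindles,
sub-alpha oscillations, (sustained) alpha oscillations, silent/depolarized.

The published criteria were applied by hand; this module codifies them as an
automatic rule with explicit precedence:

1. nonphysiological — population-mean TC potential below -100 mV or above
   -50 mV, or pathologically rapid sustained firing (persistent single-spike
   firing above ``rapid_rate_hz`` under depolarization).
2. silent classes — too few network bursts after the settle discard: mean V
   below the T window -> silent/hyperpolarized, above -> silent/depolarized
   (a silent mean V inside the window is grouped with hyperpolarized: the
   boundary goes to the lower band).
3. oscillatory classes — waxing-and-waning or early-terminating bursting ->
   transients/spindles; persistent bursting is labeled by its network burst
   frequency: alpha band [8, 13] Hz -> alpha, below -> sub_alpha (slow /
   delta / theta reported as a diagnostic). Persistent bursting above the
   alpha band does not occur in the calibrated model; it is grouped with
   nonphysiological rapid firing for totality.

Band boundaries follow the convention that a boundary value belongs to the
lower band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .engine import SimulationResult

__all__ = [
    "Regime",
    "ClassifierConfig",
    "RegimeLabel",
    "BurstAnalysis",
    "detect_bursts",
    "is_waxing_waning",
    "classify",
]


class Regime(str, Enum):
    NONPHYSIOLOGICAL = "nonphysiological"
    SILENT_HYPERPOLARIZED = "silent_hyperpolarized"
    TRANSIENTS_SPINDLES = "transients_spindles"
    SUB_ALPHA = "sub_alpha"
    ALPHA = "alpha"
    SILENT_DEPOLARIZED = "silent_depolarized"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: classes that count as intrinsic thalamic oscillation
OSCILLATORY = (Regime.TRANSIENTS_SPINDLES, Regime.SUB_ALPHA, Regime.ALPHA)


@dataclass
class ClassifierConfig:
    v_nonphys_low: float = -100.0    # mV
    v_nonphys_high: float = -50.0
    t_window: tuple[float, float] = (-80.0, -72.0)
    # frequency band edges (Hz): slow / delta / theta / alpha
    slow_band: tuple[float, float] = (0.1, 1.5)
    delta_band: tuple[float, float] = (1.5, 4.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    burst_gap: float = 30.0          # ms: spikes closer than this share a burst
    episode_gap_factor: float = 2.5  # silences > factor x median IBI split episodes
    min_silence: float = 250.0       # ms: never split on gaps shorter than this
    sustained_fraction: float = 0.95 # coverage needed for "entire duration"
    min_bursts: int = 3              # fewer network bursts -> silent classes
    rapid_rate_hz: float = 20.0      # tonic-firing cutoff for nonphysiological
    settle_discard: float | None = None  # ms; None -> take from provenance

    def validate(self) -> None:
        bands = (self.slow_band, self.delta_band, self.theta_band,
                 self.alpha_band)
        if not all(lo < hi for lo, hi in bands):
            raise ValueError("band edges must increase")
        if not all(a[1] <= b[0] for a, b in zip(bands, bands[1:])):
            raise ValueError("bands must be ordered and non-overlapping")
        if not self.t_window[0] < self.t_window[1]:
            raise ValueError("T window bounds must be ordered")
        if not (self.v_nonphys_low < self.t_window[0]
                and self.t_window[1] < self.v_nonphys_high):
            raise ValueError("T window must sit inside physiological bounds")


@dataclass
class BurstAnalysis:
    """Per-cell burst times and population-level burst statistics."""

    per_cell: dict[int, np.ndarray]
    network_times: np.ndarray        # population-averaged burst times (ms)
    frequency_hz: float              # 1000 / median inter-burst interval; 0 if < 2 bursts
    median_ibi: float                # ms; nan if < 2 bursts
    mean_burst_size: float           # spikes per per-cell burst

    @property
    def n_network_bursts(self) -> int:
        return int(self.network_times.size)


def detect_bursts(raster: np.ndarray, gap: float = 30.0) -> BurstAnalysis:
    """Group a (cell_id, time_ms) raster into bursts.

    Spikes of one cell separated by less than ``gap`` belong to one burst.
    Per-cell burst times are then pooled and clustered with the same gap to
    form network burst events; the network burst frequency is the reciprocal
    of the median inter-event interval. An empty raster yields zero bursts
    and frequency 0.
    """
    raster = np.asarray(raster, dtype=float).reshape(-1, 2)
    per_cell: dict[int, np.ndarray] = {}
    sizes: list[int] = []
    for cid in np.unique(raster[:, 0]).astype(int) if raster.size else []:
        ts = np.sort(raster[raster[:, 0] == cid, 1])
        groups = np.split(ts, np.flatnonzero(np.diff(ts) >= gap) + 1)
        per_cell[cid] = np.array([g[0] for g in groups])
        sizes.extend(len(g) for g in groups)
    if per_cell:
        pooled = np.sort(np.concatenate(list(per_cell.values())))
        clusters = np.split(pooled, np.flatnonzero(np.diff(pooled) >= gap) + 1)
        network = np.array([c.mean() for c in clusters])
    else:
        network = np.empty(0)
    if network.size >= 2:
        ibi = float(np.median(np.diff(network)))
        freq = 1000.0 / ibi
    else:
        ibi, freq = float("nan"), 0.0
    return BurstAnalysis(per_cell=per_cell, network_times=network,
                         frequency_hz=freq, median_ibi=ibi,
                         mean_burst_size=float(np.mean(sizes)) if sizes else 0.0)


def burst_coverage(bursts: BurstAnalysis, t0: float, t1: float,
                   cfg: ClassifierConfig) -> tuple[float, int]:
    """(fraction of [t0, t1] covered by uninterrupted bursting, n episodes).

    Bursting is interrupted wherever the inter-burst silence exceeds
    ``max(episode_gap_factor x median IBI, min_silence)``; leading and
    trailing silences count against coverage.
    """
    bt = bursts.network_times
    if bt.size < 2:
        return 0.0, int(bt.size > 0)
    med = bursts.median_ibi
    cut = max(cfg.episode_gap_factor * med, cfg.min_silence)
    gaps = np.diff(bt)
    episodes = np.split(bt, np.flatnonzero(gaps > cut) + 1)
    active = sum(e[-1] - e[0] + med for e in episodes)
    return float(min(1.0, active / max(t1 - t0, 1e-9))), len(episodes)


def is_waxing_waning(bursts: BurstAnalysis, t0: float, t1: float,
                     cfg: ClassifierConfig | None = None) -> bool:
    """True when bursting comes in episodes separated by silent epochs, or
    terminates well before the record ends (spindles and long transients);
    False for uninterrupted bursting spanning the whole record."""
    cfg = cfg or ClassifierConfig()
    cov, n_ep = burst_coverage(bursts, t0, t1, cfg)
    return n_ep != 1 or cov < cfg.sustained_fraction


def _band_name(freq: float, cfg: ClassifierConfig) -> str:
    for name, (lo, hi) in (("slow", cfg.slow_band), ("delta", cfg.delta_band),
                           ("theta", cfg.theta_band), ("alpha", cfg.alpha_band)):
        if lo < freq <= hi:
            return name
    return "sub_slow" if freq <= cfg.slow_band[0] else "supra_alpha"


@dataclass
class RegimeLabel:
    """Classification verdict plus the diagnostics that drove it."""

    regime: Regime
    mean_v: float                   # population-mean TC potential, mV
    frequency_hz: float             # network burst frequency
    coverage: float                 # fraction of record covered by bursting
    n_network_bursts: int
    band: str = ""                  # slow/delta/theta/alpha of the frequency
    n_episodes: int = 0
    failed: bool = False            # simulation failure stand-in flag

    def __str__(self) -> str:  # pragma: no cover
        return (f"{self.regime.value} (V={self.mean_v:.1f} mV, "
                f"f={self.frequency_hz:.1f} Hz, cov={self.coverage:.2f})")


def classify(result: SimulationResult,
             config: ClassifierConfig | None = None) -> RegimeLabel:
    """Assign exactly one behavior regime to a simulation.

    Precedence: nonphysiological first; silent classes (by mean TC potential
    relative to the T window) when there are too few bursts; otherwise the
    oscillatory classes by persistence and network burst frequency. The
    analysis starts after the settle discard recorded in the result's
    provenance (or ``config.settle_discard``).
    """
    cfg = config or ClassifierConfig()
    cfg.validate()
    if result.V_tc.size == 0:
        raise ValueError("result carries no TC voltage traces")
    discard = cfg.settle_discard
    if discard is None:
        discard = result.provenance.get("integrator", {}).get("settle_discard", 0.0)
    if result.t[-1] <= discard:
        raise ValueError("record shorter than the settle discard")
    w = result.window(discard)
    t0, t1 = float(w.t[0]), float(w.t[-1])
    mean_v = float(w.V_tc.mean())
    bursts = detect_bursts(w.spikes_tc, cfg.burst_gap)
    cov, n_ep = burst_coverage(bursts, t0, t1, cfg)
    diag = dict(mean_v=mean_v, frequency_hz=bursts.frequency_hz, coverage=cov,
                n_network_bursts=bursts.n_network_bursts,
                band=_band_name(bursts.frequency_hz, cfg), n_episodes=n_ep)

    if mean_v < cfg.v_nonphys_low or mean_v > cfg.v_nonphys_high:
        return RegimeLabel(Regime.NONPHYSIOLOGICAL, **diag)
    persistent = (n_ep == 1 and cov >= cfg.sustained_fraction
                  and bursts.n_network_bursts >= cfg.min_bursts)
    # pathologically rapid: persistent single-spike (tonic) firing above the
    # rate cutoff, or persistent bursting faster than the alpha band
    if persistent and bursts.frequency_hz > cfg.alpha_band[1] * (1 + 1e-9):
        return RegimeLabel(Regime.NONPHYSIOLOGICAL, **diag)
    if bursts.n_network_bursts < cfg.min_bursts:
        if mean_v <= cfg.t_window[1]:
            return RegimeLabel(Regime.SILENT_HYPERPOLARIZED, **diag)
        return RegimeLabel(Regime.SILENT_DEPOLARIZED, **diag)
    if not persistent:
        return RegimeLabel(Regime.TRANSIENTS_SPINDLES, **diag)
    lo, hi = cfg.alpha_band
    if lo < bursts.frequency_hz <= hi * (1 + 1e-9):
        return RegimeLabel(Regime.ALPHA, **diag)
    return RegimeLabel(Regime.SUB_ALPHA, **diag)


def intra_spindle_frequency(result: SimulationResult,
                            config: ClassifierConfig | None = None) -> float:
    """Median burst frequency measured *within* detected bursting episodes.

    For waxing-and-waning records this excludes the silent epochs between
    spindles, giving the intra-spindle oscillation frequency (Hz).
    """
    cfg = config or ClassifierConfig()
    discard = cfg.settle_discard
    if discard is None:
        discard = result.provenance.get("integrator", {}).get("settle_discard", 0.0)
    w = result.window(discard)
    bursts = detect_bursts(w.spikes_tc, cfg.burst_gap)
    bt = bursts.network_times
    if bt.size < 2:
        return 0.0
    med = bursts.median_ibi
    cut = max(cfg.episode_gap_factor * med, cfg.min_silence)
    episodes = np.split(bt, np.flatnonzero(np.diff(bt) > cut) + 1)
    ibis = np.concatenate([np.diff(e) for e in episodes if e.size >= 2])
    if ibis.size == 0:
        return 0.0
    return float(1000.0 / np.median(ibis))
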