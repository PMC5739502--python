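"""Regime maps over the g_H x background-excitation plane.

Each grid point is an independent simulation classified into a behavior
regime; maps are computed per dose multiplier and per cortical-firing (CF /
NCF) condition. Derived quantities: the sustained-alpha area, the largest
g_H still supporting intrinsic oscillation, and the maximum-network-
frequency-versus-potentiation curve.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .classify import OSCILLATORY, ClassifierConfig, Regime, RegimeLabel, classify
from .drive import CompiledDrive, DriveConfig, Interval, UpDownSchedule, compile_drive
from .engine import IntegratorConfig, SimulationError, simulate
from .params import NetworkConfig, PropofolCondition

__all__ = [
    "SweepGrid",
    "RegimeMap",
    "run_plane",
    "sustained_alpha_area",
    "gH_oscillation_threshold",
    "max_frequency_scan",
]


@dataclass
class SweepGrid:
    """The sweep axes plus the dose / drive condition they are run under."""

    g_H: np.ndarray                   # mS/cm^2, ascending
    excitation: np.ndarray            # uA/cm^2, ascending (TC background)
    dose_multiplier: float = 1.0
    cortical_firing: bool = False     # CF: 12 Hz Poisson AMPA drive on
    seed: int = 0

    def __post_init__(self) -> None:
        self.g_H = np.asarray(self.g_H, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype=float)
        for ax, name in ((self.g_H, "g_H"), (self.excitation, "excitation")):
            if ax.size < 1 or not np.all(np.isfinite(ax)):
                raise ValueError(f"{name} axis must be finite and nonempty")
            if np.any(np.diff(ax) <= 0) and ax.size > 1:
                raise ValueError(f"{name} axis must be strictly ascending")

    @classmethod
    def default(cls, dose_multiplier: float = 1.0, cortical_firing: bool = False,
                n_gh: int = 8, n_ex: int = 8, seed: int = 0) -> "SweepGrid":
        """Desk-scale default plane: g_H in [0, 0.04] mS/cm^2 and excitation
        spanning tonic hyperpolarization to strong depolarization.

        Both axes are denser where the oscillatory regimes live (low g_H,
        mildly depolarizing excitation) and coarser toward the
        nonphysiological extremes, so the regime boundaries that set the
        alpha area are resolved without wasting points on silent corners.
        The g_H axis starts at 0.008 mS/cm^2, the lower edge of the
        physiological H-conductance range in this calibration: below it the
        calcium-dependent H-current regulation that terminates baseline
        oscillations becomes too weak to act (see the methods note).
        """
        gh_lo = np.linspace(0.008, 0.02, max(2, n_gh - 2))
        gh = np.unique(np.concatenate([gh_lo, [0.03, 0.04]]))
        ex_core = np.linspace(0.0, 1.4, max(2, n_ex - 4))
        ex = np.unique(np.concatenate([[-1.2, -0.8, -0.4], ex_core, [1.8]]))
        return cls(g_H=gh, excitation=ex,
                   dose_multiplier=dose_multiplier,
                   cortical_firing=cortical_firing, seed=seed)


@dataclass
class RegimeMap:
    """Grid plus one RegimeLabel per point (complete coverage by design)."""

    grid: SweepGrid
    labels: list[list[RegimeLabel]]      # [i_gh][j_ex]
    provenance: dict = field(default_factory=dict)

    def label(self, i_gh: int, j_ex: int) -> RegimeLabel:
        return self.labels[i_gh][j_ex]

    def regimes(self) -> np.ndarray:
        """(n_gh, n_ex) array of regime value strings."""
        return np.array([[lb.regime.value for lb in row] for row in self.labels])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gh in enumerate(self.grid.g_H):
            for j, ex in enumerate(self.grid.excitation):
                lb = self.labels[i][j]
                rows.append(dict(g_h=gh, i_bg=ex, label=lb.regime.value,
                                 freq_hz=lb.frequency_hz, mean_v_mv=lb.mean_v,
                                 coverage=lb.coverage, failed=lb.failed))
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = dict(dose_multiplier=self.grid.dose_multiplier,
                    cortical_firing=self.grid.cortical_firing,
                    seed=self.grid.seed, provenance=self.provenance)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def _point_config(base: NetworkConfig, gh: float, ex: float,
                  mult: float) -> NetworkConfig:
    cfg = dataclasses.replace(
        base,
        tc=dataclasses.replace(base.tc, g_H=gh),
        background_excitation_TC=ex,
        propofol=PropofolCondition(mult, base.propofol.scale_gabab),
    )
    return cfg


def _cf_drive(config: NetworkConfig, total_ms: float, seed: int) -> CompiledDrive:
    """Continuous cortical-firing condition: one UP interval spanning the run
    with Poisson spiking only (the tonic component lives on the excitation
    axis itself)."""
    schedule = UpDownSchedule((Interval("UP", total_ms,
                                        config.propofol.multiplier, 0.0),))
    drv = DriveConfig(up_excitation_step=0.0, seed=seed)
    return compile_drive(schedule, drv, config)


def run_plane(grid: SweepGrid, config: NetworkConfig | None = None,
              integ: IntegratorConfig | None = None,
              classifier: ClassifierConfig | None = None,
              cache_dir: str | Path | None = None) -> RegimeMap:
    """Simulate and classify every grid point.

    Points are independent (deterministic per point and seed) and cached as
    one JSON file per point when ``cache_dir`` is given, so an interrupted
    sweep resumes where it stopped. A point whose simulation diverges is
    recorded as nonphysiological with ``failed=True``; the sweep never
    aborts.
    """
    config = config or NetworkConfig()
    integ = integ or IntegratorConfig()
    classifier = classifier or ClassifierConfig()
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)

    labels: list[list[RegimeLabel]] = []
    for i, gh in enumerate(grid.g_H):
        row: list[RegimeLabel] = []
        for j, ex in enumerate(grid.excitation):
            key = (f"gh{gh:.6g}_ex{ex:.6g}_m{grid.dose_multiplier:g}"
                   f"_cf{int(grid.cortical_firing)}_s{grid.seed}.json")
            if cache and (cache / key).exists():
                d = json.loads((cache / key).read_text())
                d["regime"] = Regime(d["regime"])
                row.append(RegimeLabel(**d))
                continue
            cfg = _point_config(config, gh, ex, grid.dose_multiplier)
            drive = (_cf_drive(cfg, integ.total_duration, grid.seed)
                     if grid.cortical_firing else None)
            try:
                res = simulate(cfg, integ, drive=drive, seed=grid.seed)
                lb = classify(res, classifier)
            except (SimulationError, FloatingPointError, OverflowError):
                lb = RegimeLabel(Regime.NONPHYSIOLOGICAL, mean_v=float("nan"),
                                 frequency_hz=0.0, coverage=0.0,
                                 n_network_bursts=0, failed=True)
            row.append(lb)
            if cache:
                d = dataclasses.asdict(lb)
                d["regime"] = lb.regime.value
                (cache / key).write_text(json.dumps(d))
        labels.append(row)
    prov = {"network": config.to_dict(), "integrator": dataclasses.asdict(integ)}
    return RegimeMap(grid=grid, labels=labels, provenance=prov)


def sustained_alpha_area(regime_map: RegimeMap) -> float:
    """Fraction of grid points labeled (sustained) alpha, in [0, 1]."""
    reg = regime_map.regimes()
    n_pts = reg.size
    if n_pts == 0 or len(regime_map.labels) != regime_map.grid.g_H.size \
            or any(len(r) != regime_map.grid.excitation.size
                   for r in regime_map.labels):
        raise ValueError("regime map does not cover its grid")
    return float(np.mean(reg == Regime.ALPHA.value))


def gH_oscillation_threshold(regime_map: RegimeMap) -> Optional[float]:
    """Largest g_H whose row contains any intrinsic-oscillation label
    (transients/spindles, sub-alpha, or alpha); None when no point
    oscillates."""
    osc_values = {r.value for r in OSCILLATORY}
    reg = regime_map.regimes()
    best: Optional[float] = None
    for i, gh in enumerate(regime_map.grid.g_H):
        if any(v in osc_values for v in reg[i]):
            best = float(gh) if best is None else max(best, float(gh))
    return best


def max_frequency_scan(multipliers: Iterable[float],
                       config: NetworkConfig | None = None,
                       excitation: np.ndarray | None = None,
                       g_H: float = 0.01,
                       integ: IntegratorConfig | None = None,
                       classifier: ClassifierConfig | None = None,
                       seed: int = 0,
                       cache_dir: str | Path | None = None) -> pd.DataFrame:
    """Maximum persistent network burst frequency per GABA_A potentiation.

    For each multiplier, a 1-D sweep over the background-excitation axis is
    classified and the maximum network frequency among points labeled as a
    persistent oscillation (sub-alpha or alpha) is recorded; waxing-waning
    transients do not count as the network's ongoing frequency. Returns a
    DataFrame with columns multiplier, max_frequency_hz, argmax_excitation.
    """
    multipliers = list(multipliers)
    if any(m < 1 for m in multipliers):
        raise ValueError("multipliers must be >= 1")
    config = config or NetworkConfig()
    if excitation is None:
        excitation = np.arange(0.0, 1.61, 0.2)
    rows = []
    for m in multipliers:
        grid = SweepGrid(g_H=np.array([g_H]), excitation=np.asarray(excitation),
                         dose_multiplier=m, seed=seed)
        rmap = run_plane(grid, config, integ, classifier, cache_dir=cache_dir)
        best_f, best_ex = 0.0, float("nan")
        for j, ex in enumerate(grid.excitation):
            lb = rmap.label(0, j)
            if lb.regime in (Regime.SUB_ALPHA, Regime.ALPHA) \
                    and lb.frequency_hz > best_f:
                best_f, best_ex = lb.frequency_hz, float(ex)
        rows.append(dict(multiplier=m, max_frequency_hz=best_f,
                         argmax_excitation=best_ex))
    return pd.DataFrame(rows)
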