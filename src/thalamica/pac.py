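"""Phase-amplitude-coupling regime from paired UP/DOWN steady states.

The slow-wave oscillation is treated as an alternation between a cortical UP
state (cortical firing + a tonic excitation step) and a DOWN state (neither).
The thalamic behavior in each state is classified independently at steady
state; alpha appearing only in the DOWN state means thalamocortical alpha
rides the slow-wave trough (trough-max PAC), alpha only in the UP state
means it rides the peak (peak-max PAC). A composite single-run mode
(``simulate_composite``) realizes a full schedule in one continuous
simulation, including mid-run dose switches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, Regime, RegimeLabel, classify, detect_bursts
from .drive import DriveConfig, Interval, UpDownSchedule, compile_drive
from .engine import IntegratorConfig, SimulationResult, simulate
from .params import NetworkConfig
from .sweep import RegimeMap

__all__ = [
    "PACRegime",
    "SteadyStatePair",
    "classify_pac",
    "pac_over_plane",
    "simulate_composite",
]

_SILENT = (Regime.SILENT_HYPERPOLARIZED, Regime.SILENT_DEPOLARIZED)


class PACRegime(str, Enum):
    TROUGH_MAX = "trough_max"
    PEAK_MAX = "peak_max"
    NONE = "none"
    AMBIGUOUS = "ambiguous"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class SteadyStatePair:
    """DOWN (no cortical firing) and UP (cortical firing) steady-state labels
    for one (g_H, dose) context."""

    down: RegimeLabel
    up: RegimeLabel
    g_H: float = float("nan")
    dose_multiplier: float = float("nan")
    down_excitation: float = float("nan")
    up_excitation: float = float("nan")


def classify_pac(pair: SteadyStatePair) -> PACRegime:
    """PAC verdict from the two steady-state regime labels.

    Alpha only in the DOWN state (UP silent) -> trough_max; alpha only in the
    UP state (DOWN silent) -> peak_max; alpha in neither -> none; alpha in
    both -> ambiguous. A nonphysiological member is an error: no verdict is
    meaningful there.
    """
    d, u = pair.down.regime, pair.up.regime
    if Regime.NONPHYSIOLOGICAL in (d, u):
        raise ValueError("PAC verdict undefined for nonphysiological states")
    d_alpha, u_alpha = d == Regime.ALPHA, u == Regime.ALPHA
    if d_alpha and u_alpha:
        return PACRegime.AMBIGUOUS
    if d_alpha and u in _SILENT:
        return PACRegime.TROUGH_MAX
    if u_alpha and d in _SILENT:
        return PACRegime.PEAK_MAX
    if d_alpha or u_alpha:
        # alpha opposite a non-silent oscillation: amplitude is modulated but
        # not gated; grouped with the matching verdict is not defensible, so
        # report none
        return PACRegime.NONE
    return PACRegime.NONE


def pac_over_plane(plane_ncf: RegimeMap, plane_cf: RegimeMap,
                   up_excitation_offset: float) -> pd.DataFrame:
    """PAC verdict per (g_H, DOWN excitation) from two compatible planes.

    The UP state of a point at DOWN excitation x is looked up on the CF plane
    at x + ``up_excitation_offset`` (the offset must map onto the CF grid).
    Points whose UP image falls off the CF grid are skipped; pairs with a
    nonphysiological member get verdict ``none`` with ``valid=False``.
    """
    g_ncf, g_cf = plane_ncf.grid, plane_cf.grid
    if not np.allclose(g_ncf.g_H, g_cf.g_H):
        raise ValueError("planes have different g_H axes")
    if g_ncf.dose_multiplier != g_cf.dose_multiplier:
        raise ValueError("planes have different dose multipliers")
    if g_ncf.cortical_firing or not g_cf.cortical_firing:
        raise ValueError("need an NCF plane and a CF plane")
    ex_cf = g_cf.excitation
    rows = []
    for i, gh in enumerate(g_ncf.g_H):
        for j, ex in enumerate(g_ncf.excitation):
            target = ex + up_excitation_offset
            k = np.flatnonzero(np.isclose(ex_cf, target, atol=1e-9))
            if k.size == 0:
                continue
            pair = SteadyStatePair(
                down=plane_ncf.label(i, j), up=plane_cf.label(i, int(k[0])),
                g_H=float(gh), dose_multiplier=g_ncf.dose_multiplier,
                down_excitation=float(ex), up_excitation=float(target))
            try:
                verdict = classify_pac(pair)
                valid = True
            except ValueError:
                verdict, valid = PACRegime.NONE, False
            rows.append(dict(g_h=float(gh), down_excitation=float(ex),
                             up_excitation=float(target),
                             down_label=pair.down.regime.value,
                             up_label=pair.up.regime.value,
                             pac=verdict.value, valid=valid))
    return pd.DataFrame(rows)


def simulate_composite(schedule: UpDownSchedule, config: NetworkConfig,
                       integ: IntegratorConfig | None = None,
                       drive_config: DriveConfig | None = None,
                       classifier: ClassifierConfig | None = None,
                       seed: int = 0,
                       interval_discard: float = 150.0
                       ) -> tuple[SimulationResult, list[RegimeLabel]]:
    """One continuous run through an UP/DOWN schedule with per-interval labels.

    The drive, tonic step, and dose multiplier switch at interval boundaries
    within a single integration (no state reset). Each interval is then
    classified on its own restricted window, dropping ``interval_discard``
    ms after each switch; intervals shorter than two burst periods of the
    alpha band get unreliable labels (a warning is attached upstream by the
    caller if needed).
    """
    integ = integ or IntegratorConfig()
    drive_config = drive_config or DriveConfig(seed=seed)
    classifier = classifier or ClassifierConfig()
    total = schedule.total_duration
    integ = dataclasses.replace(integ, total_duration=total, seed=seed)
    drive = compile_drive(schedule, drive_config, config)
    result = simulate(config, integ, drive=drive, seed=seed)

    labels: list[RegimeLabel] = []
    t0 = 0.0
    cls = dataclasses.replace(classifier, settle_discard=0.0,
                              min_silence=min(classifier.min_silence, 200.0))
    for iv, t1 in zip(schedule.intervals, schedule.boundaries):
        w = result.window(t0 + interval_discard, float(t1))
        labels.append(classify(w, cls))
        t0 = float(t1)
    return result, labels
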