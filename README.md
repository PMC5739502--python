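# thalamica

Conductance-based simulations of how the anesthetic propofol turns the
thalamus into a sustained alpha (8–13 Hz) oscillator, and of how that alpha
couples to the slow-wave oscillation (SWO) of deeper anesthesia.

**Who this is for:** computational neuroscientists studying thalamocortical
rhythms under anesthesia, and anyone who needs a small, fast, deterministic
Hodgkin–Huxley TC–RE network with regime classification and parameter-plane
tooling.

## The science in brief

The model is an isolated hyperpolarized thalamus: `n_TC` thalamocortical
relay cells and `n_RE` reticular cells (single-compartment Hodgkin–Huxley,
all-to-all coupling). TC cells carry the low-threshold T-type calcium
current `I_T = g_T mT∞²(V) hT (V−E_Ca)` — whose activation/de-inactivation
overlap in a voltage "window" (≈ −80 to −72 mV) enables rebound bursts —
and a calcium-regulated H current whose slow up-regulation terminates
spindles. RE cells inhibit TC cells through GABA_A (and weak GABA_B);
TC cells excite RE cells through AMPA.

Propofol is modeled as a joint multiplier on the GABA_A maximal conductance
and decay time constant: ×1 baseline, ×2 low dose, ×3 high dose. The
package maps network behavior over the `g_H` × background-excitation plane
into six regimes (nonphysiological, silent/hyperpolarized,
transients/spindles, sub-alpha, alpha, silent/depolarized) and shows:

- baseline thalamus spindles but never sustains alpha;
- GABA_A potentiation converts the same parameter points into sustained
  8–13 Hz bursting, over an area that grows with dose;
- intrinsic oscillation requires `g_H` below a threshold (~0.024 mS/cm²
  in the reference calibration);
- under corticothalamic UP/DOWN (slow-wave) drive, the hyperpolarization
  level — not the dose — selects trough-max versus peak-max
  phase-amplitude coupling of alpha to the SWO.

See `docs/methods.md` for the full model description, parameter provenance,
classification rules, and limitations.

## Worked example

```python
import thalamica as th

integ = th.IntegratorConfig(total_duration=8000.0, settle_discard=1000.0)

for name, cfg in [("baseline", th.baseline(n_TC=10, n_RE=10)),
                  ("high dose", th.high_dose(n_TC=10, n_RE=10))]:
    cfg.background_excitation_TC = 0.4   # uA/cm^2
    cfg.tc.g_H = 0.01                    # mS/cm^2
    res = th.simulate(cfg, integ, seed=1)
    lb = th.classify(res)
    print(f"{name:9s}: {lb.regime.value:22s} "
          f"f = {lb.frequency_hz:5.2f} Hz  coverage = {lb.coverage:.2f}")
```

prints

```
baseline : transients_spindles    f =  6.25 Hz  coverage = 0.20
high dose: alpha                  f = 12.21 Hz  coverage = 1.00
```

Read: at the same point of the `g_H` × excitation plane, the drug-free
network produces a brief waxing-and-waning spindle (bursting covers 20% of
the record; the whole-record median inter-burst frequency of 6.25 Hz mixes
the ~8–10 Hz intra-spindle rhythm with the silences between epochs) and
then falls silent, while tripling `g_GABAA` and `tau_GABAA` yields
uninterrupted alpha-band bursting (coverage 1.0) at 12.2 Hz for the whole
simulation.

The numbered scripts under `analysis/` run the full study on desk-scale
settings and write tables under `results/`: reference traces
(`01_reference_traces.py`), three-dose regime planes and alpha areas
(`02_regime_planes.py`), the maximum-frequency-versus-potentiation curve
(`03_max_frequency.py`), PAC verdict maps (`04_pac_regimes.py`), and a
single continuous slow-wave run that traverses trough-max and then
peak-max coupling (`05_composite_swo.py`).

A CLI wraps the same operations:

```bash
thalamica simulate --dose high --seed 1 --out runs/high
thalamica classify --result runs/high
thalamica sweep --dose high --out runs/planes
```

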