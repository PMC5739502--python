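# Methods

## The model

`thalamica` simulates an isolated, hyperpolarized thalamic circuit: `n_TC`
thalamocortical relay (TC) cells and `n_RE` reticular (RE) cells, each a
single-compartment Hodgkin–Huxley neuron, connected all-to-all. The
equations follow the Destexhe-lineage thalamic slice models. Per TC cell:

    C dV/dt = −I_Na − I_K − I_leak − I_KL − I_T − I_H − I_syn + I_app + I_drive

- **Spike currents** `I_Na = g_Na m³h (V−E_Na)`, `I_K = g_K n⁴ (V−E_K)` with
  Traub-style rate functions (voltage shifts exposed as parameters).
- **Leaks**: an unspecific leak and a potassium leak `g_KL (V−E_KL)`. `g_KL`
  is set relatively high (0.024 mS/cm²) so the network represents a thalamus
  hyperpolarized away from the awake relay state, as under anesthesia.
- **T current** `I_T = g_T mT∞²(V) hT (V−E_Ca)` — the low-threshold calcium
  current that generates rebound bursts. Activation `mT` is instantaneous
  (always at steady state); de-inactivation `hT` is slow. The steady-state
  curves overlap in a hyperpolarized window (≈ −80 to −72 mV): only a
  membrane that visits this window long enough accumulates the `hT` needed
  for a burst. `E_Ca` is the Nernst potential of the dynamically tracked
  intracellular Ca (influx proportional to `I_T`, first-order removal).
- **H current** `I_H = g_H (O + g_inc·O_L)(V−E_H)` — hyperpolarization-
  activated, with calcium-dependent up-regulation: Ca⁴ binds a regulating
  factor (fraction `P1`) which locks open channels into a locked state `O_L`
  carrying `g_inc`-fold conductance. The slow unlock (1 s) makes `I_H` an
  activity integrator: repeated bursting raises Ca, locks the H current
  open, depolarizes the cell floor above the T window, and the oscillation
  wanes. This is the spindle-termination mechanism.

RE cells carry the same spike currents plus their own T current (fixed
E_Ca). Synapses: TC→RE AMPA, RE→TC GABA_A (the dose target), RE→RE GABA_A,
and a weak RE→TC GABA_B with two-stage receptor→G-protein kinetics and a
4th-power activation. Activation gates obey first-order transmitter
kinetics driven by a smooth sigmoid of presynaptic voltage; all maximal
conductances are totals normalized by the presynaptic count, so reduced
networks keep the same per-cell drive. Units: mV, ms, mS/cm², µA/cm²,
µF/cm², mM. Sign convention: positive applied current depolarizes.

**Propofol** is a single dimensionless multiplier applied jointly to every
GABA_A maximal conductance and to the GABA_A decay time constant
`tau_GABAA`: ×1 baseline, ×2 low dose, ×3 high dose. `tau_GABAA` is scaled
by dividing the closing rate, so the decay constant scales exactly
linearly. GABA_B is not scaled (a config switch exists).

**Background excitation** is a voltage-invariant applied current density to
the TC population (an independent RE field exists, default 0). It stands in
for the lumped depolarizing/hyperpolarizing influence of brainstem
neuromodulation; negative values are tonic hyperpolarization. It is the
second sweep axis next to `g_H`.

**Corticothalamic drive**: cortex is not modeled. An UP state is (a)
AMPAergic spiking from independent 12 Hz Poisson processes onto TC cells
(RE targeting is a flag) and (b) a tonic excitation step (default
0.4 µA/cm²); a DOWN state is the absence of both. UP/DOWN schedules are
lists of contiguous intervals, each with its own dose multiplier and
background-excitation level, realized inside a single continuous
integration.

## Parameter provenance and calibration

The detailed parameterization of the source model was not available, so all
constants were reconstructed from the published lineage of thalamic slice
models and exposed in `TCCellParams` / `RECellParams` / `SynapseParams`;
any alternative values can be dropped in from configuration without code
changes. Within that family, four coupling constants
(`g_AMPA_TC_to_RE = 0.04`, `g_GABAA_RE_to_TC = 0.10`, `tau_GABAA = 9 ms`,
`E_GABAA_TC = −78 mV`), the GABA_B weight (0.015) and the H-current locked
gain (3) were calibrated once so that the reduced 10+10 network reproduces
the qualitative regime structure that defines the study: waxing-and-waning
~10 Hz spindles at baseline, sustained 8–13 Hz bursting only under GABA_A
potentiation, oscillation death under strong depolarization, and loss of
all intrinsic oscillation above `g_H` ≈ 0.024 mS/cm². These defaults are
the package's study conditions; they are deliberately not per-analysis
knobs.

Mechanistically, the calibration encodes three balances. (1) TC→RE AMPA is
weak enough that only multi-spike T bursts recruit RE firing — single
tonic TC spikes cannot sustain the loop, so strong depolarization yields
silence rather than fast tonic oscillation. (2) The GABA_A reversal at
−78 mV lets potentiated inhibition pull TC cells just into the T window
without unbounded deepening; together with `tau_GABAA` it caps the maximum
loop frequency at the top of the alpha band. (3) The locked-state gain of
the H current makes the baseline spindle terminate reliably, while
potentiated inhibition out-pulls the up-regulated H current, which is why
the same point of the plane spindles at baseline and sustains alpha under
dose.

## Numerics

Fixed-step classical Runge–Kutta (RK4) at `dt = 0.01 ms`, compiled with
numba; bit-identical reruns per (config, seed). The step was chosen
conservatively: halving it changes silent-trajectory voltages by far less
than the 0.5 mV contract asserted in the tests, and a 4th-order error decay
is verified against a closed-form exponential. Gating variables are clamped
to [0,1] and Ca to positive values after each step (RK4 overshoots are
below 1e-6 in practice). Divergent parameter sets (possible at the extreme
corners of the plane) surface as a `SimulationError` at the first recorded
sample; plane sweeps record such points as nonphysiological with a failure
flag instead of aborting. Traces are recorded every 0.1 ms — several
samples per sodium spike — and spikes are upward 0 mV crossings with a 2 ms
refractory guard. Cortical Poisson events are applied between RK4 steps as
jumps of the input gate (amplitude 0.9 of the remaining headroom), which at
`dt = 0.01 ms` is indistinguishable from a continuous rise.

Initial conditions: voltages jittered ±1 mV (seeded) around −75 mV (TC) /
−80 mV (RE), gates at their steady states for that voltage, synaptic gates
at zero. The first 1000 ms of every analysis run is discarded: the
hyperpolarized start guarantees that a parameter point capable of
oscillating actually engages its oscillation, and the discard removes the
onset transient the way the original study's classification implicitly did.

## Regime classification

The six-way taxonomy is applied automatically with explicit precedence
(the original criteria were applied by hand):

1. **nonphysiological** — population-mean TC voltage < −100 mV or > −50 mV,
   or pathologically rapid firing. "Pathologically rapid" is
   operationalized as persistent single-spike (tonic) firing above 20 Hz;
   persistent bursting above the 13 Hz alpha edge is grouped here too for
   totality (it does not occur on the default grids).
2. **silent/hyperpolarized** vs **silent/depolarized** — fewer than 3
   network bursts after the discard; split by mean voltage relative to the
   T window (−80, −72 mV); a silent mean inside the window goes to the
   lower (hyperpolarized) class. The 3-burst floor distinguishes "settled
   silent" from a run whose onset transient barely outlived the discard.
3. **transients/spindles** — bursting that waxes and wanes (episodes
   separated by silences longer than max(2.5 × median inter-burst interval,
   250 ms)) or that terminates early (coverage < 95% of the post-discard
   record). Single long transients are grouped here.
4. **alpha** — uninterrupted bursting covering ≥ 95% of the record with
   network burst frequency in (8, 13] Hz; **sub_alpha** — the same with
   frequency ≤ 8 Hz (slow/delta/theta reported as a diagnostic band).

Network burst frequency is the reciprocal of the median interval between
network burst events (per-cell bursts pooled and clustered with a 30 ms
gap). Band boundaries belong to the lower band. A separate estimator,
`intra_spindle_frequency`, measures the median inter-burst interval within
bursting episodes only, i.e. the ~10 Hz rhythm inside a spindle rather than
the rate averaged over silences.

## Plane sweeps and derived quantities

The default desk-scale grid covers `g_H` ∈ [0.008, 0.04] mS/cm² and
background excitation ∈ [−1.2, +1.8] µA/cm², denser where the oscillatory
regimes live (low g_H, 0–1.4 µA/cm²) and coarse toward the
silent/nonphysiological corners, with 4 s simulations per point. The `g_H`
floor is the lower edge of the physiological H-conductance range in this
calibration: below ≈0.008 mS/cm² the calcium-dependent H-current
up-regulation that terminates baseline oscillations becomes too weak to
act, and the reconstruction can sustain baseline bursting into the alpha
band — a known limitation relative to the reference behavior (see Known
limitations). This spans all six regimes:
traversing excitation at low `g_H` passes silent/hyperpolarized →
oscillatory → silent/depolarized, with nonphysiological only at the
extremes.

- `sustained_alpha_area` — fraction of grid points labeled alpha. Dose
  comparisons are made on identical grids only, since the area is
  grid-relative.
- `gH_oscillation_threshold` — the largest `g_H` whose row contains any
  intrinsic-oscillation label. On the default conditions this lands near
  0.028 mS/cm² (the printed reference value is ~0.024; the reconstruction
  tolerance is ±30%).
- `max_frequency_scan` — per potentiation multiplier, the maximum network
  burst frequency over the excitation axis among points labeled as
  *persistent* oscillation (sub-alpha or alpha). Waxing-waning transients
  are excluded: their median-interval frequency reflects the intra-spindle
  rhythm, not an ongoing network frequency. The curve rises from baseline
  (no persistent oscillation at all) through ×2 to its peak at ×3 and falls
  for ×5 and ×8, whose long inhibition decay slows the loop below alpha.

## PAC analysis

PAC regime is determined by regime composition of paired steady states, not
by a modulation-index statistic — no EEG signal is modeled. For a (g_H,
dose) context, the DOWN state is the no-cortical-firing (NCF) simulation at
some excitation x and the UP state the cortical-firing (CF) simulation at
x + offset (default offset 0.4 µA/cm², matching the UP-state tonic step).
Alpha only in the DOWN member ⇒ trough-max; alpha only in the UP member ⇒
peak-max; in neither ⇒ none; in both ⇒ ambiguous (not observed on default
grids, but a defined verdict rather than a forced choice). Pairs with a
nonphysiological member raise in `classify_pac` and are marked invalid in
the plane table.

The composite mode (`simulate_composite`) runs one continuous simulation
through an UP/DOWN schedule, switching drive, excitation, and dose at
interval boundaries, then classifies each interval on its own window
(dropping 150 ms after each switch). Two caveats, documented because they
are properties of the dynamics, not bugs: (a) parts of the sustained-alpha
region are bistable with the silent state, so a DOWN interval entered from
a depolarized UP state re-engages its oscillation only if the downward
transition undershoots into the T window — the demonstration schedule
therefore uses a DOWN level near the hyperpolarized edge of the alpha zone
and a small `g_H` (0.004 mS/cm²), where re-engagement is reliable; (b)
interval windows of a few hundred ms contain only a handful of bursts, so
per-interval frequency estimates are noisy and labels near switches are
unreliable — interval-level claims are therefore made at
bursting-versus-silent granularity. A consequence of (a) worth stating
plainly: composite interval behavior cannot be expected to match
independent steady-state runs point-for-point, because at the operating
points where re-engagement works the steady state itself depends on the
initial condition. The test suite therefore asserts cycle-stationarity of
the composite response rather than composite/steady-state agreement.

## What the synthetic drive does and does not emulate

The Poisson UP-state input reproduces the rate (12 Hz per target) and
AMPAergic character of corticothalamic firing and the tonic depolarization
step of an UP state; DOWN states are their absence. It does not model
cortical responsiveness (no feedback from TC output to the drive), UP/DOWN
transition waveforms, or any within-UP temporal structure. Passing tests
therefore demonstrate thalamic steady-state behavior under idealized
corticothalamic conditions, not closed-loop thalamocortical dynamics.

## Reduced scale

All shipped analyses run the reduced network (10 TC + 10 RE, synaptic
totals normalized by presynaptic count) with 3–11 s simulations; this
preserves the regime structure because every cell of a type receives the
same normalized drive. The full-size (50+50, 8 s) configuration is a
one-line change (`n_TC=50, n_RE=50`) and is what the regime maps represent
at scale.

## Known limitations

- Absolute regime boundaries inherit the reconstruction uncertainty of the
  parameterization; positions on the excitation axis are internally
  consistent but not directly comparable to other implementations.
- Below the default grid's g_H floor (≈0.008 mS/cm²) the baseline network
  can sustain 8–12 Hz bursting indefinitely because the H-current spindle
  terminator vanishes with g_H; the reference behavior (no sustained
  baseline alpha at any g_H) holds in this reconstruction only on the
  physiological g_H range.
- The maximum-frequency ordering between ×2 and ×3 potentiation is a
  ~0.1 Hz margin on the default grid; it is stable across the seeds tested
  but is intrinsically a near-tie in this reconstruction.
- Mean-voltage classes use the population mean over the whole post-discard
  window; regimes that drift across class boundaries within a window are
  not subdivided.
- Baseline spindles cycle at ~8.2–8.9 Hz inside their epochs, at the slow
  edge of the ~10 Hz reference rhythm: the spindle period and the
  potentiated-alpha frequency ceiling share the GABA_A decay constant in
  this architecture, and the calibration resolves the tension in favor of
  keeping sustained alpha inside 8–13 Hz.
- No adaptive or stiff solver; extremely depolarized corners of the plane
  can diverge and are reported as failed/nonphysiological points.
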