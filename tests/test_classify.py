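import dataclasses

import numpy as np
import pytest

import thalamica as th
from thalamica.classify import (BurstAnalysis, ClassifierConfig, Regime,
                                burst_coverage, classify, detect_bursts,
                                intra_spindle_frequency, is_waxing_waning)


def make_result(mean_v=-85.0, spikes=None, duration=8000.0, discard=1000.0,
                n_cells=5):
    """Synthetic SimulationResult with a flat voltage trace and a given raster."""
    t = np.arange(0.0, duration + 0.1, 1.0)
    v = np.full((t.size, n_cells), float(mean_v))
    spikes = np.asarray(spikes, dtype=float).reshape(-1, 2) if spikes is not None \
        else np.empty((0, 2))
    prov = {"integrator": {"settle_discard": discard}}
    return th.SimulationResult(
        t=t, V_tc=v, V_re=v.copy(), hT_tc=np.zeros_like(v),
        Ca_tc=np.zeros_like(v), I_h_tc=np.zeros_like(v),
        spikes_tc=spikes, spikes_re=np.empty((0, 2)), provenance=prov)


def cluster_raster(times, n_cells=5, spikes_per_burst=3, isi=6.0):
    """All cells emit a spikes_per_burst burst at each listed time."""
    rows = []
    for t0 in times:
        for c in range(n_cells):
            for k in range(spikes_per_burst):
                rows.append((c, t0 + k * isi + 0.01 * c))
    return np.array(rows)


def test_detect_bursts_empty_raster():
    b = detect_bursts(np.empty((0, 2)))
    assert b.n_network_bursts == 0 and b.frequency_hz == 0.0


def test_detect_bursts_constructed_10hz():
    # 3-spike clusters every 100 ms for 8 s -> 10 Hz network bursting
    times = np.arange(1000.0, 9000.0, 100.0)
    b = detect_bursts(cluster_raster(times), gap=30.0)
    assert b.n_network_bursts == times.size
    assert b.frequency_hz == pytest.approx(10.0, rel=1e-6)
    assert b.mean_burst_size == pytest.approx(3.0)


def test_detect_bursts_jittered_frequency_within_5pct():
    rng = np.random.default_rng(0)
    times = np.arange(1000.0, 9000.0, 100.0) + rng.uniform(-5, 5, 80)
    b = detect_bursts(cluster_raster(times), gap=30.0)
    assert abs(b.frequency_hz - 10.0) / 10.0 < 0.05


def test_waxing_waning_verdicts():
    cfg = ClassifierConfig()
    span = (1000.0, 9000.0)
    # uninterrupted 10 Hz bursting over the full record -> not waxing-waning
    sustained = detect_bursts(cluster_raster(np.arange(1000.0, 9000.0, 100.0)))
    assert not is_waxing_waning(sustained, *span, cfg)
    # 1 s bursting epochs separated by 1 s silences -> waxing-waning
    epochs = np.concatenate([np.arange(s, s + 1000.0, 100.0)
                             for s in (1000.0, 3000.0, 5000.0, 7000.0)])
    spindles = detect_bursts(cluster_raster(epochs))
    assert is_waxing_waning(spindles, *span, cfg)
    # a single short transient followed by silence -> grouped with spindles
    transient = detect_bursts(cluster_raster(np.arange(1000.0, 1600.0, 100.0)))
    assert is_waxing_waning(transient, *span, cfg)


def test_classify_silent_classes_by_mean_voltage():
    assert classify(make_result(mean_v=-85.0)).regime == Regime.SILENT_HYPERPOLARIZED
    assert classify(make_result(mean_v=-60.0)).regime == Regime.SILENT_DEPOLARIZED


def test_classify_nonphysiological_bounds():
    assert classify(make_result(mean_v=-105.0)).regime == Regime.NONPHYSIOLOGICAL
    assert classify(make_result(mean_v=-45.0)).regime == Regime.NONPHYSIOLOGICAL


def test_classify_oscillatory_classes():
    # persistent 5 Hz bursting -> sub-alpha (theta band)
    lb = classify(make_result(
        mean_v=-65.0, spikes=cluster_raster(np.arange(1000.0, 9000.0, 200.0))))
    assert lb.regime == Regime.SUB_ALPHA and lb.band == "theta"
    # persistent 10 Hz bursting -> alpha
    lb = classify(make_result(
        mean_v=-65.0, spikes=cluster_raster(np.arange(1000.0, 9000.0, 100.0))))
    assert lb.regime == Regime.ALPHA
    # spindle epochs -> transients/spindles
    epochs = np.concatenate([np.arange(s, s + 1200.0, 100.0)
                             for s in (1500.0, 4500.0, 7000.0)])
    lb = classify(make_result(mean_v=-68.0, spikes=cluster_raster(epochs)))
    assert lb.regime == Regime.TRANSIENTS_SPINDLES


def test_classify_rapid_tonic_firing_is_nonphysiological():
    # persistent 25 Hz single-spike firing under depolarization
    spikes = cluster_raster(np.arange(1000.0, 9000.0, 40.0), spikes_per_burst=1)
    lb = classify(make_result(mean_v=-55.0, spikes=spikes))
    assert lb.regime == Regime.NONPHYSIOLOGICAL


def test_classification_is_total_over_synthetic_inputs():
    rng = np.random.default_rng(5)
    for _ in range(25):
        mean_v = rng.uniform(-120.0, -40.0)
        if rng.random() < 0.5:
            spikes = None
        else:
            period = rng.uniform(30.0, 400.0)
            n = rng.integers(2, 60)
            spikes = cluster_raster(1000.0 + period * np.arange(n),
                                    spikes_per_burst=int(rng.integers(1, 5)))
        lb = classify(make_result(mean_v=mean_v, spikes=spikes))
        assert isinstance(lb.regime, Regime)


def test_classify_stability_to_jitter_and_voltage_perturbation():
    base_times = np.arange(1000.0, 9000.0, 100.0)
    rng = np.random.default_rng(8)
    ref = classify(make_result(mean_v=-65.0, spikes=cluster_raster(base_times)))
    for k in range(5):
        jit = rng.uniform(-1.0, 1.0, base_times.size)
        lb = classify(make_result(mean_v=-65.0 + rng.uniform(-0.5, 0.5),
                                  spikes=cluster_raster(base_times + jit)))
        assert lb.regime == ref.regime


def test_classify_requires_enough_record():
    with pytest.raises(ValueError):
        classify(make_result(duration=500.0, discard=1000.0))


def test_band_boundary_goes_to_lower_band():
    # exactly 8 Hz -> theta/sub-alpha, not alpha; exactly 13 Hz -> alpha
    lb8 = classify(make_result(mean_v=-65.0,
                               spikes=cluster_raster(np.arange(1000.0, 9000.0, 125.0))))
    assert lb8.regime == Regime.SUB_ALPHA
    lb13 = classify(make_result(
        mean_v=-65.0, spikes=cluster_raster(np.arange(1000.0, 9000.0, 1000.0 / 13.0),
                                            spikes_per_burst=2, isi=5.0)))
    assert lb13.regime == Regime.ALPHA


def test_intra_spindle_frequency_excludes_silences():
    epochs = np.concatenate([np.arange(s, s + 1000.0, 100.0)
                             for s in (1500.0, 4500.0, 7000.0)])
    res = make_result(mean_v=-68.0, spikes=cluster_raster(epochs))
    assert intra_spindle_frequency(res) == pytest.approx(10.0, rel=0.01)


def test_classifier_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(t_window=(-70.0, -80.0)).validate()
    with pytest.raises(ValueError):
        ClassifierConfig(alpha_band=(13.0, 8.0)).validate()
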