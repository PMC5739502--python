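import numpy as np
import pytest

import thalamica as th
from thalamica.drive import CompiledDrive, compile_drive, export_spike_trains
from thalamica.params import ConfigError


def test_zero_rate_yields_empty_trains():
    trains = th.generate_poisson_spikes(0.0, 8000.0, 5, seed=1)
    assert all(tr.size == 0 for tr in trains)


def test_negative_rate_rejected():
    with pytest.raises(ConfigError):
        th.generate_poisson_spikes(-1.0, 1000.0, 1, seed=0)
    with pytest.raises(ConfigError):
        th.DriveConfig(poisson_rate=-2.0).validate()


def test_trains_are_seeded_and_independent():
    a = th.generate_poisson_spikes(12.0, 8000.0, 3, seed=7)
    b = th.generate_poisson_spikes(12.0, 8000.0, 3, seed=7)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert not np.array_equal(a[0][:5], a[1][:5])


def test_poisson_intervals_are_exponential_and_rate_converges():
    # pooled ISI moments over a modest seed set match the exponential law
    rate, dur = 12.0, 8000.0
    isis, counts = [], []
    for seed in range(60):
        (tr,) = th.generate_poisson_spikes(rate, dur, 1, seed=seed)
        counts.append(tr.size)
        isis.append(np.diff(tr))
    isis = np.concatenate(isis)
    mean_isi = 1000.0 / rate
    assert np.mean(isis) == pytest.approx(mean_isi, rel=0.05)
    assert np.std(isis) == pytest.approx(mean_isi, rel=0.08)  # CV ~ 1
    expected = rate * dur / 1000.0
    se = np.sqrt(expected / len(counts))
    assert abs(np.mean(counts) - expected) < 3.0 * se


def test_schedule_partitions_time_exactly():
    sched = th.UpDownSchedule.alternating(n_cycles=3, up_ms=400.0, down_ms=600.0)
    bounds = sched.boundaries
    assert bounds[-1] == pytest.approx(6 * 500.0)
    assert np.all(np.diff(bounds) > 0)
    durations = np.diff(np.concatenate([[0.0], bounds]))
    np.testing.assert_allclose(
        durations, [iv.duration for iv in sched.intervals])


def test_schedule_rejects_bad_intervals():
    with pytest.raises(ConfigError):
        th.Interval("UP", -5.0)
    with pytest.raises(ConfigError):
        th.Interval("SIDEWAYS", 100.0)
    with pytest.raises(ConfigError):
        th.UpDownSchedule(())


def test_drive_at_up_down_semantics():
    sched = th.UpDownSchedule((th.Interval("DOWN", 500.0, 2.0, -0.2),
                               th.Interval("UP", 500.0, 2.0, -0.2)))
    drv = th.DriveConfig(poisson_rate=12.0, up_excitation_step=0.3)
    rate, step, mult = th.drive_at(100.0, sched, drv)
    assert rate == 0.0 and step == 0.0 and mult == 2.0
    rate, step, mult = th.drive_at(700.0, sched, drv)
    assert rate == 12.0 and step == pytest.approx(0.3) and mult == 2.0
    with pytest.raises(ValueError):
        th.drive_at(1000.0, sched, drv)
    with pytest.raises(ValueError):
        th.drive_at(-1.0, sched, drv)


def test_single_up_interval_drive_is_constant():
    sched = th.UpDownSchedule((th.Interval("UP", 1000.0, 1.0, 0.0),))
    drv = th.DriveConfig(up_excitation_step=0.25)
    vals = {th.drive_at(t, sched, drv) for t in (0.0, 250.0, 999.0)}
    assert len(vals) == 1


def test_compile_drive_targets_and_segments():
    cfg = th.baseline(n_TC=4, n_RE=3)
    sched = th.UpDownSchedule((th.Interval("DOWN", 300.0, 1.0, -0.1),
                               th.Interval("UP", 300.0, 3.0, 0.2)))
    drv = th.DriveConfig(poisson_rate=40.0, up_excitation_step=0.3,
                         targets=("TC",), seed=5)
    cd = compile_drive(sched, drv, cfg)
    assert isinstance(cd, CompiledDrive)
    np.testing.assert_allclose(cd.seg_ends, [300.0, 600.0])
    np.testing.assert_allclose(cd.seg_mult, [1.0, 3.0])
    # DOWN: only the interval excitation; UP: interval excitation + step
    np.testing.assert_allclose(cd.seg_iapp_tc, [-0.1, 0.2 + 0.3])
    # all spikes inside the UP interval, all targets are TC cells
    assert cd.spike_times.size > 0
    assert np.all((cd.spike_times >= 300.0) & (cd.spike_times < 600.0))
    assert np.all(cd.spike_targets < 4)
    # RE targeting is a config flag
    cd2 = compile_drive(sched, th.DriveConfig(poisson_rate=40.0, seed=5,
                                              targets=("TC", "RE")), cfg)
    assert np.any(cd2.spike_targets >= 4)


def test_cortical_drive_depolarizes_target_cells():
    cfg = th.baseline(n_TC=2, n_RE=2, background_excitation_TC=-0.2)
    sched = th.UpDownSchedule((th.Interval("UP", 1000.0, 1.0, 0.0),))
    drv = th.DriveConfig(poisson_rate=100.0, up_excitation_step=0.0, seed=3)
    integ = th.IntegratorConfig(total_duration=1000.0, settle_discard=0.0)
    quiet = th.simulate(cfg, integ, seed=1)
    driven = th.simulate(cfg, integ, drive=compile_drive(sched, drv, cfg), seed=1)
    assert driven.V_tc[2000:].mean() > quiet.V_tc[2000:].mean() + 1.0


def test_spike_trains_export_tsv(tmp_path):
    cfg = th.baseline(n_TC=3, n_RE=2)
    sched = th.UpDownSchedule((th.Interval("UP", 500.0, 1.0, 0.0),))
    cd = compile_drive(sched, th.DriveConfig(poisson_rate=30.0, seed=2), cfg)
    out = tmp_path / "trains.tsv"
    export_spike_trains(cd, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "target_id\ttime_ms"
    assert len(lines) == cd.spike_times.size + 1
    tid, tms = lines[1].split("\t")
    assert int(tid) == cd.spike_targets[0]
    assert abs(float(tms) - cd.spike_times[0]) < 1e-3
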