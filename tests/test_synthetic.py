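"""Generator contracts: cycle geometry, determinism, coverage, realism."""

import numpy as np
import pytest

from pcgseg.io import CLASSES, expand_labels
from pcgseg.metrics import evaluate
from pcgseg.synthetic import (
    BurstSpec,
    SynthConfig,
    make_benchmark,
    simulate_cycle,
    simulate_record,
)


def test_cycle_length_matches_heart_rate():
    cfg = SynthConfig(heart_rate_jitter=0.0)
    samples, rows = simulate_cycle(cfg, np.random.default_rng(0))
    assert samples.size == 1000  # 60 bpm at 1000 Hz
    assert [r[2] for r in rows] == list(CLASSES)
    # rows abut with shared boundaries
    for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
        assert s2 == e1


def test_phase_lengths_sum_to_cycle():
    cfg = SynthConfig(heart_rate_bpm=75.0)
    lengths = cfg.phase_lengths()
    assert sum(lengths) == int(round(60.0 / 75.0 * 1000))


def test_burst_dominates_systolic_interior():
    cfg = SynthConfig(heart_rate_jitter=0.0, noise_snr_db=np.inf, amplitude_jitter=0.0)
    samples, rows = simulate_cycle(cfg, np.random.default_rng(1))
    s1 = samples[rows[0][0] - 1 : rows[0][1] - 1]
    sysint = samples[rows[1][0] - 1 : rows[1][1] - 1]
    floor = np.abs(sysint).max() if np.abs(sysint).max() > 0 else 1e-12
    assert np.abs(s1).max() / floor >= 5


def test_murmur_off_systole_matches_noise_floor():
    cfg = SynthConfig(duration_s=30.0, seed=3, noise_snr_db=20.0, murmur="off")
    rec, table = simulate_record(cfg)
    labels = expand_labels(table).labels
    sys_rms = np.sqrt(np.mean(rec.samples[labels == 1] ** 2))
    # diastole is also silent apart from sensor noise: same floor
    dia_rms = np.sqrt(np.mean(rec.samples[labels == 3] ** 2))
    assert sys_rms == pytest.approx(dia_rms, rel=0.1)


def test_systolic_murmur_raises_systole_energy():
    base = SynthConfig(duration_s=20.0, seed=4, murmur="off")
    murm = SynthConfig(duration_s=20.0, seed=4, murmur="systolic", murmur_amplitude=0.2)
    for cfg in (base, murm):
        rec, table = simulate_record(cfg)
        labels = expand_labels(table).labels
        cfg_rms = np.sqrt(np.mean(rec.samples[labels == 1] ** 2))
        if cfg.murmur == "off":
            rms_off = cfg_rms
        else:
            rms_on = cfg_rms
    assert rms_on > 2 * rms_off


def test_record_cycle_count_zero_jitter():
    cfg = SynthConfig(duration_s=10.0, heart_rate_jitter=0.0)
    _, table = simulate_record(cfg)
    assert sum(1 for r in table.rows if r[2] == "S1") == 10


def test_record_deterministic_per_seed():
    cfg = SynthConfig(duration_s=5.0, seed=99)
    rec1, t1 = simulate_record(cfg)
    rec2, t2 = simulate_record(cfg)
    np.testing.assert_array_equal(rec1.samples, rec2.samples)
    assert t1.rows == t2.rows


def test_different_seeds_differ():
    a, _ = simulate_record(SynthConfig(duration_s=5.0, seed=1))
    b, _ = simulate_record(SynthConfig(duration_s=5.0, seed=2))
    assert not np.array_equal(a.samples, b.samples)


def test_duration_shorter_than_cycle_rejected():
    with pytest.raises(ValueError, match="cycle"):
        simulate_record(SynthConfig(duration_s=0.5, heart_rate_bpm=60.0))


def test_phase_underflow_rejected():
    with pytest.raises(ValueError, match="underflow"):
        # systole share rounds to exactly the S1 duration: no systolic samples
        SynthConfig(systole_fraction=0.12).phase_lengths()


def test_every_draw_satisfies_io_invariants():
    """Record/table pairs from many seeds always validate and cover fully."""
    for seed in range(300):
        cfg = SynthConfig(duration_s=2.2, seed=seed,
                          heart_rate_bpm=50 + (seed % 50),
                          heart_rate_jitter=0.1)
        rec, table = simulate_record(cfg)  # RegionTable validates on build
        seq = expand_labels(table)
        assert len(seq) == rec.n_samples
        assert np.all(np.isfinite(rec.samples))


def test_phase_fractions_converge():
    """Label shares approach the configured cycle geometry on long records."""
    cfg = SynthConfig(duration_s=100.0, seed=8, heart_rate_jitter=0.0)
    _, table = simulate_record(cfg)
    seq = expand_labels(table)
    frac = np.bincount(seq.labels, minlength=4) / len(seq)
    s1_n, sys_n, s2_n, dia_n = cfg.phase_lengths()
    expected = np.array([s1_n, sys_n, s2_n, dia_n]) / 1000.0
    np.testing.assert_allclose(frac, expected, atol=0.05)


def test_make_benchmark_split_and_geometry(fast_synth_cfg, fast_pp_cfg):
    train_ds, test_ds = make_benchmark(
        10, fast_synth_cfg, split_seed=5, pp_cfg=fast_pp_cfg
    )
    train_ids = set(train_ds.source_ids)
    test_ids = set(test_ds.source_ids)
    assert len(train_ids) == 7 and len(test_ids) == 3
    assert not train_ids & test_ids
    assert train_ds.window_len == test_ds.window_len
    # 2 s windows at the decimated 200 Hz feature rate
    assert train_ds.window_len == 400


def test_make_benchmark_deterministic(fast_synth_cfg, fast_pp_cfg):
    a = make_benchmark(4, fast_synth_cfg, split_seed=2, pp_cfg=fast_pp_cfg)
    b = make_benchmark(4, fast_synth_cfg, split_seed=2, pp_cfg=fast_pp_cfg)
    np.testing.assert_array_equal(a[0].features, b[0].features)
    np.testing.assert_array_equal(a[1].labels, b[1].labels)


def test_benchmark_class_proportions(fast_pp_cfg):
    cfg = SynthConfig(duration_s=20.0, seed=6)
    train_ds, test_ds = make_benchmark(4, cfg, split_seed=1, pp_cfg=fast_pp_cfg)
    labels = np.concatenate([train_ds.labels.ravel(), test_ds.labels.ravel()])
    frac = np.bincount(labels, minlength=4) / labels.size
    s1_n, sys_n, s2_n, dia_n = cfg.phase_lengths()
    expected = np.array([s1_n, sys_n, s2_n, dia_n]) / 1000.0
    np.testing.assert_allclose(frac, expected, atol=0.05)


def test_noise_level_orders_site_accuracy(fast_pp_cfg):
    """Planted per-site noise levels surface in the per-site accuracy order."""
    from pcgseg.io import SegmentDataset
    from pcgseg.models import ModelConfig, train
    from pcgseg.synthetic import record_to_segments
    from dataclasses import replace

    # fit a model on clean records, then score sites that differ only in
    # their planted sensor-noise level
    fit_parts = []
    for k in range(6):
        cfg = SynthConfig(duration_s=10.0, seed=200 + k, noise_snr_db=25.0,
                          record_id=f"fit{k}", heart_rate_bpm=55 + 3 * k)
        rec, table = simulate_record(cfg)
        fit_parts.append(record_to_segments(rec, table, fast_pp_cfg))
    model = train(
        SegmentDataset.concatenate(fit_parts),
        ModelConfig(architecture="bigru", hidden_units=24, epochs=25, seed=0,
                    batch_size=4, learning_rate=0.005),
        holdout=False,
    )

    # the conditioning chain suppresses out-of-band noise strongly, so the
    # planted levels are spaced widely enough to survive preprocessing
    site_snrs = {"MV": 30.0, "TV": 5.0, "PV": -10.0}
    parts = []
    for k in range(9):
        site = list(site_snrs)[k % 3]
        cfg = SynthConfig(
            duration_s=10.0, seed=300 + k, noise_snr_db=site_snrs[site],
            site=site, record_id=f"r{k:02d}", heart_rate_bpm=55 + 3 * (k % 5),
        )
        rec, table = simulate_record(cfg)
        parts.append(record_to_segments(rec, table, fast_pp_cfg))
    ds = SegmentDataset.concatenate(parts)
    reports = {r.group: r for r in evaluate(model, ds, group_by="site")}
    assert reports["MV"].accuracy >= reports["TV"].accuracy >= reports["PV"].accuracy
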