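"""Filtering, resampling, channel exclusion, epoch selection,
re-referencing and band power."""

import numpy as np
import pytest

from eegtree.containers import (
    BROADBAND,
    DEFAULT_BANDS,
    DEFAULT_EYE_CHANNELS,
    BandDefinition,
    Recording,
    montage_labels,
)
from eegtree.preprocess import (
    band_decompose,
    band_power,
    condition_signal,
    drop_channels,
    epoch_and_select,
    rereference_average,
)


def sine_recording(freq, duration=10.0, rate=1000.0, n_channels=1, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording(data, montage_labels(n_channels)[:n_channels], rate)


# ------------------------------------------------------ condition_signal
def test_passband_tone_preserved_and_resampled():
    rec = sine_recording(10.0, duration=10.0, rate=1000.0)
    out = condition_signal(rec, 0.5, 30.0, 500.0)
    assert out.rate == 500.0
    assert out.n_samples == rec.n_samples // 2
    rms_in = np.sqrt((rec.data**2).mean())
    rms_out = np.sqrt((out.data[:, 500:-500] ** 2).mean())
    assert abs(rms_out / rms_in - 1) < 0.01


def test_stopband_tone_suppressed():
    rec = sine_recording(50.0, duration=20.0, rate=1000.0)
    out = condition_signal(rec, 0.5, 30.0, 500.0)
    # the 0.5 Hz pole rings for a few seconds at the boundaries; judge the
    # steady-state interior against the filter's squared magnitude response
    interior = out.data[:, 1500:-1500]
    assert np.sqrt((interior**2).mean()) < 0.05 * np.sqrt((rec.data**2).mean())


def test_zero_in_zero_out_and_linearity(rng):
    zeros = Recording(np.zeros((2, 5000)), ["E1", "E2"], 1000.0)
    assert np.allclose(condition_signal(zeros).data, 0.0)

    data = rng.standard_normal((2, 5000))
    rec = Recording(data, ["E1", "E2"], 1000.0)
    rec3 = Recording(3.0 * data, ["E1", "E2"], 1000.0)
    assert np.allclose(3.0 * condition_signal(rec).data,
                       condition_signal(rec3).data)


def test_condition_signal_errors():
    rec = sine_recording(10.0, duration=1.0)
    with pytest.raises(ValueError):
        condition_signal(rec, 0.5, 300.0, 500.0)  # above target Nyquist
    with pytest.raises(ValueError):
        condition_signal(Recording(np.empty((1, 0)), ["E1"], 1000.0))


# --------------------------------------------------------- drop_channels
def test_default_eye_exclusion_leaves_120_channels(rng):
    rec = Recording(rng.standard_normal((128, 100)), montage_labels(128), 500.0)
    out = drop_channels(rec, DEFAULT_EYE_CHANNELS)
    assert out.n_channels == 120
    kept = [lab for lab in rec.labels if lab not in DEFAULT_EYE_CHANNELS]
    assert out.labels == kept  # order preserved


def test_drop_channels_edge_cases(rng):
    rec = Recording(rng.standard_normal((4, 50)), ["E1", "E2", "E3", "E4"], 100.0)
    assert drop_channels(rec, []).labels == rec.labels
    with pytest.raises(KeyError):
        drop_channels(rec, ["E99"])
    with pytest.raises(ValueError):
        drop_channels(rec, rec.labels)


# ------------------------------------------------------ epoch_and_select
def test_five_minute_recording_yields_72_epochs():
    rec = sine_recording(10.0, duration=300.0, rate=500.0)
    ep = epoch_and_select(rec, 2.0, n_keep=72)
    assert ep.n_epochs == 72
    assert ep.n_samples == 1000


def test_no_selection_keeps_all_150_epochs():
    rec = sine_recording(10.0, duration=300.0, rate=500.0)
    assert epoch_and_select(rec, 2.0, n_keep=None).n_epochs == 150


def test_filter_then_head_selection_order():
    rate = 100.0
    rec = sine_recording(5.0, duration=20.0, rate=rate)  # 10 x 2-s epochs
    data = rec.data.copy()
    data[0, int(2.5 * rate)] = 50.0   # spike in epoch index 1
    data[0, int(6.5 * rate)] = 50.0   # spike in epoch index 3
    rec = Recording(data, rec.labels, rate)
    ep = epoch_and_select(rec, 2.0, n_keep=6, reject_threshold=10.0)
    peaks = np.abs(ep.data).max(axis=(1, 2))
    assert ep.n_epochs == 6
    assert np.all(peaks <= 10.0)
    # survivors are epochs 0,2,4,5,6,7 -> first sample of each checks order
    starts = ep.data[:, 0, 0]
    expected = [rec.data[0, int(k * 2 * rate)] for k in (0, 2, 4, 5, 6, 7)]
    assert np.allclose(starts, expected)


def test_insufficient_epochs_raise():
    rec = sine_recording(10.0, duration=10.0, rate=500.0)
    with pytest.raises(ValueError):
        epoch_and_select(rec, 2.0, n_keep=72)
    noisy = Recording(np.full((1, 2000), 100.0) + sine_recording(
        10.0, duration=4.0, rate=500.0).data, ["E1"], 500.0)
    with pytest.raises(ValueError):
        epoch_and_select(noisy, 2.0, n_keep=1, reject_threshold=10.0)


def test_epoch_concatenation_reconstructs_recording(rng):
    data = rng.standard_normal((3, 1050))
    rec = Recording(data, ["E1", "E2", "E3"], 100.0)
    ep = epoch_and_select(rec, 2.0, n_keep=None)
    rebuilt = np.concatenate([ep.data[e] for e in range(ep.n_epochs)], axis=1)
    assert np.array_equal(rebuilt, data[:, :1000])


# --------------------------------------------------- rereference_average
def test_rereference_zero_mean_and_flag(rng):
    rec = Recording(rng.standard_normal((5, 600)), montage_labels(5)[:5], 100.0)
    ep = epoch_and_select(rec, 2.0, n_keep=None)
    ref = rereference_average(ep)
    assert np.abs(ref.data.mean(axis=1)).max() < 1e-10
    assert ref.rereferenced
    with pytest.raises(ValueError):
        rereference_average(ref)
    # mathematically idempotent: re-subtracting the mean changes nothing
    again = ref.data - ref.data.mean(axis=1, keepdims=True)
    assert np.allclose(again, ref.data)


def test_rereference_degenerate_inputs(rng):
    equal = np.tile(rng.standard_normal(200), (4, 1))
    ep = epoch_and_select(Recording(equal, montage_labels(4)[:4], 100.0),
                          2.0, n_keep=None)
    assert np.allclose(rereference_average(ep).data, 0.0)

    v = rng.standard_normal(200)
    pm = np.stack([v, -v])
    ep2 = epoch_and_select(Recording(pm, ["E1", "E2"], 100.0), 2.0, n_keep=None)
    assert np.allclose(rereference_average(ep2).data, pm.reshape(1, 2, 200))


# -------------------------------------------------------- band_decompose
def _broadband_epochs(data, rate):
    rec = Recording(data, montage_labels(data.shape[0])[: data.shape[0]], rate)
    return epoch_and_select(rec, 2.0, n_keep=None)


def test_theta_tone_lands_in_theta_band():
    rate = 500.0
    t = np.arange(int(20 * rate)) / rate
    ep = _broadband_epochs(np.sin(2 * np.pi * 6.0 * t)[None, :], rate)
    out = band_decompose(ep, DEFAULT_BANDS)
    assert set(out) == {"delta", "theta", "alpha", "beta"}
    total = ep.data.var()
    assert out["theta"].data.var() >= 0.90 * total
    assert out["alpha"].data.var() <= 0.05 * total
    for band_ep in out.values():
        assert band_ep.data.shape == ep.data.shape


def test_band_variances_approximately_partition_white_noise(rng):
    rate = 500.0
    data = rng.standard_normal((1, int(60 * rate)))
    rec = condition_signal(Recording(data, ["E1"], rate), 0.5, 30.0, rate)
    ep = epoch_and_select(rec, 2.0, n_keep=None)
    out = band_decompose(ep, DEFAULT_BANDS)
    band_sum = sum(b.data.var() for b in out.values())
    assert abs(band_sum / ep.data.var() - 1) < 0.15


def test_band_decompose_rejects_bad_input(rng):
    ep = _broadband_epochs(rng.standard_normal((1, 1000)), 100.0)
    with pytest.raises(ValueError):
        band_decompose(ep.copy_with(band="theta"), DEFAULT_BANDS)
    overlapping = (BandDefinition("a", 1, 6), BandDefinition("b", 4, 10))
    with pytest.raises(ValueError):
        band_decompose(ep, overlapping)


# ------------------------------------------------------------ band_power
def test_pure_tone_concentrates_relative_power():
    rate = 500.0
    t = np.arange(int(30 * rate)) / rate
    ep = _broadband_epochs(np.sin(2 * np.pi * 10.0 * t)[None, :], rate)
    table = band_power(ep, DEFAULT_BANDS)
    alpha = table[(table.band == "alpha")].iloc[0]
    assert alpha.rel_power >= 0.99


def test_white_noise_relative_power_tracks_bandwidth(rng):
    rate = 500.0
    rels = {b.name: [] for b in DEFAULT_BANDS}
    for _ in range(5):
        data = rng.standard_normal((1, int(60 * rate)))
        ep = _broadband_epochs(data, rate)
        table = band_power(ep, DEFAULT_BANDS)
        for b in DEFAULT_BANDS:
            rels[b.name].append(
                float(table[table.band == b.name].rel_power.iloc[0])
            )
    for b in DEFAULT_BANDS:
        expected = b.width / 29.5
        assert np.mean(rels[b.name]) == pytest.approx(expected, rel=0.15)


def test_band_power_degenerate_and_invalid():
    rate = 500.0
    ep = _broadband_epochs(np.zeros((1, int(10 * rate))), rate)
    table = band_power(ep, DEFAULT_BANDS)
    assert np.isnan(table.rel_power).all()
    assert (table.power == 0).all()
    with pytest.raises(ValueError):
        band_power(ep, (BandDefinition("hi", 30.0, 45.0),))
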