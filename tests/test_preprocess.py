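import numpy as np
import pytest

from dyadsync.errors import (
    IrrecoverableChannelError,
    ParameterError,
    ValidationError,
)
from dyadsync.preprocess import (
    bandpass,
    despike,
    despike_flags,
    filter_channels,
    preprocess_recording,
)

from conftest import build_recording

FS = 7.81


# ---------------------------------------------------------------------------
# channel quality filtering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gain,cv,kept",
    [
        (9.0, 3.0, False),   # gain over threshold
        (5.0, 7.6, False),   # CV over threshold
        (8.0, 7.5, True),    # boundary values pass (strict inequality)
        (1.0, 1.0, True),
    ],
)
def test_filter_channel_rule(gain, cv, kept):
    rec = build_recording(gains_a={4: gain}, cvs_a={4: cv})
    retained, exclusions = filter_channels(rec, gain_max=8.0, cv_max=7.5)
    assert (4 in retained["a"]) is kept
    if not kept:
        assert sum(e.channel == 4 and e.subject == "a" for e in exclusions) == 1


def test_exclusions_logged_once_with_reason():
    rec = build_recording(gains_a={4: 12.0}, cvs_a={6: 9.0})
    _, exclusions = filter_channels(rec)
    by_channel = {(e.subject, e.channel): e for e in exclusions}
    assert len(exclusions) == len(by_channel) == 2
    assert by_channel[("a", 4)].reason == "gain>8"
    assert by_channel[("a", 6)].reason == "cv>7.5"


def test_missing_metadata_names_channel():
    rec = build_recording()
    del rec.subjects[0].gain[13]
    with pytest.raises(ValidationError, match="13"):
        filter_channels(rec)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def _oracle_flags(x, w, k):
    """Direct evaluation of the moving-median/MAD rule (truncated windows)."""
    n = len(x)
    h = w // 2
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        win = x[max(0, i - h) : min(n, i + h + 1)]
        med = np.median(win)
        mad = np.median(np.abs(win - med))
        flags[i] = abs(x[i] - med) > k * 1.4826 * mad
    return flags


def test_clean_series_untouched(rng):
    t = np.arange(2000) / FS
    x = np.sin(2 * np.pi * 0.05 * t) + 0.3 * np.sin(2 * np.pi * 0.11 * t + 1.0)
    out = despike(x, window_s=1.0, k=5.0, sampling_rate=FS)
    assert np.array_equal(out, x)


def test_injected_spike_recovered(rng):
    t = np.arange(2000) / FS
    clean = np.sin(2 * np.pi * 0.05 * t) + 0.05 * rng.standard_normal(t.size)
    spike_mag = 50.0
    x = clean.copy()
    x[700] += spike_mag
    out = despike(x, window_s=1.0, k=5.0, sampling_rate=FS)
    assert despike_flags(x, 1.0, 5.0, FS)[700]
    assert np.max(np.abs(out - clean)) < spike_mag / 10


def test_step_edge_flags_match_oracle():
    """On a long step, any flags sit at the edge and match the direct rule.

    A clean level shift is signal-like for the moving-median detector: each
    sample sides with the majority of its own window, so flags can appear
    only within half a window of the discontinuity (and a perfectly clean
    symmetric step may produce none at all -- baseline shifts are left to
    the band-pass stage).
    """
    x = np.concatenate([np.zeros(100), 10.0 * np.ones(100)])
    x += 0.01 * np.sin(np.arange(200))  # break exact ties
    w = 7  # 1 s window at 7.81 Hz
    flags = despike_flags(x, 1.0, 5.0, FS)
    assert np.array_equal(flags, _oracle_flags(x, w, 5.0))
    assert not flags[: 100 - w].any() and not flags[100 + w :].any()
    # a short glitch in the flat region IS flagged (and only near itself)
    y = x.copy()
    y[50] = 8.0
    flags_glitch = despike_flags(y, 1.0, 5.0, FS)
    assert np.array_equal(flags_glitch, _oracle_flags(y, w, 5.0))
    assert flags_glitch[50]
    flagged = np.flatnonzero(flags_glitch)
    assert np.all((np.abs(flagged - 50) <= w) | (np.abs(flagged - 100) <= w))


def test_despike_output_length_and_interpolation():
    x = np.zeros(50)
    x[25] = 100.0
    out = despike(x, window_s=1.0, k=5.0, sampling_rate=FS)
    assert out.size == x.size
    assert abs(out[25]) < 1e-12  # interpolated between zero neighbours


def test_all_flagged_is_irrecoverable():
    x = np.tile([0.0, 10.0], 30)
    with pytest.raises(IrrecoverableChannelError):
        despike(x, window_s=0.4, k=0.1, sampling_rate=FS)


def test_window_too_small():
    with pytest.raises(ParameterError, match="fewer than 3"):
        despike(np.zeros(10), window_s=0.1, k=5.0, sampling_rate=FS)


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


def test_dc_rejection():
    x = np.full(4000, 3.7)
    y = bandpass(x, 0.01, 0.2, FS, order=3)
    assert np.max(np.abs(y)) < 1e-8 * 3.7


def test_stopband_and_passband():
    t = np.arange(8000) / FS
    hi = np.sin(2 * np.pi * 1.0 * t)
    lo = np.sin(2 * np.pi * 0.05 * t)
    assert _rms(bandpass(hi, 0.01, 0.2, FS)) <= 0.1 * _rms(hi)  # >= 20 dB down
    assert _rms(bandpass(lo, 0.01, 0.2, FS)) >= 0.9 * _rms(lo)


def test_approximate_idempotence_in_band():
    t = np.arange(8000) / FS
    x = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.1 * t)
    once = bandpass(x, 0.01, 0.2, FS)
    twice = bandpass(once, 0.01, 0.2, FS)
    assert _rms(twice - once) < 0.05 * _rms(once)


def test_invalid_band():
    with pytest.raises(ParameterError):
        bandpass(np.zeros(100), 0.2, 0.01, FS)
    with pytest.raises(ParameterError):
        bandpass(np.zeros(100), 0.01, 4.0, FS)  # above Nyquist


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def test_preprocess_recording_retains_and_converts(noisy_dyad):
    hemo_a, hemo_b, exclusions = preprocess_recording(noisy_dyad)
    for hemo in (hemo_a, hemo_b):
        assert set(hemo.hbo) == set(hemo.hbr)
        for ch in hemo.channels:
            assert hemo.hbo[ch].size == noisy_dyad.n_samples
            assert np.all(np.isfinite(hemo.hbo[ch]))
            # band-pass removes the mean (up to finite-window leakage)
            assert abs(np.mean(hemo.hbo[ch])) < 1e-3 * np.std(hemo.hbo[ch])
    excluded = {(e.subject, e.channel) for e in exclusions}
    assert len(excluded) == len(exclusions)  # each channel logged once
    for subj, hemo in (("a", hemo_a), ("b", hemo_b)):
        assert all(ch not in hemo.channels for s, ch in excluded if s == subj)
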