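"""Filtering response, bad-channel detection, spherical-spline interpolation
and ICA blink removal."""

import numpy as np
import pytest
from scipy import signal

import pdqeeg as pq
from pdqeeg.preprocess import (
    FilterSpec,
    apply_filters,
    design_bandpass,
    design_notch,
    detect_bad_channels,
    interpolate_spherical_spline,
    interpolation_weights,
    remove_blink_components,
)
from pdqeeg.recording import EEGRecording


def _recording(data, fs=200.0):
    n_ch = data.shape[0]
    pos = np.vstack([_sphere(n_ch - 1), [0, 0, 1.0]])
    labels = [f"E{i+1:02d}" for i in range(n_ch - 1)] + ["Cz"]
    roles = ["active"] * (n_ch - 1) + ["reference"]
    return EEGRecording(data=data, sfreq=fs, labels=labels, positions=pos,
                       roles=roles)


def _sphere(n):
    i = np.arange(n)
    z = 1 - (i + 0.5) / n * 1.6
    th = 2 * np.pi * i / ((1 + 5**0.5) / 2)
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


# ------------------------------------------------------------------ filters

def test_passband_sinusoid_preserved():
    fs, t = 200.0, np.arange(0, 90 * 200) / 200.0
    x = np.sin(2 * np.pi * 10 * t)
    rec = _recording(np.tile(x, (9, 1)))
    out = apply_filters(rec)
    mid = out.data[0, 2000:-2000]
    assert abs(mid.max() - 1.0) < 0.06


def test_notch_kills_mains_frequency():
    fs, t = 200.0, np.arange(0, 90 * 200) / 200.0
    x = np.sin(2 * np.pi * 50 * t)
    rec = _recording(np.tile(x, (9, 1)))
    out = apply_filters(rec)
    rms_in = np.sqrt(np.mean(x**2))
    rms_out = np.sqrt(np.mean(out.data[0, 2000:-2000] ** 2))
    assert rms_out <= 0.01 * rms_in


def test_zero_signal_stays_zero():
    rec = _recording(np.zeros((9, 18000)))
    assert np.allclose(apply_filters(rec).data, 0.0)


def test_too_short_recording_raises():
    rec = _recording(np.random.default_rng(0).standard_normal((9, 4000)))
    with pytest.raises(ValueError, match="too short"):
        apply_filters(rec)


def test_designed_response_meets_spec():
    """Compound zero-phase response: flat in 1-30 Hz, >=40 dB at 0.25 and 50 Hz."""
    for fs in (200.0, 1000.0):
        fspec = FilterSpec()
        f = np.linspace(0.01, fs / 2, 20000)
        _, hbp = signal.freqz(design_bandpass(fspec, fs), worN=f, fs=fs)
        _, hnt = signal.freqz(design_notch(fspec, fs), worN=f, fs=fs)
        resp_db = 2 * 20 * np.log10(np.maximum(np.abs(hbp) * np.abs(hnt), 1e-12))
        pb = (f >= 1) & (f <= 30)
        assert np.abs(resp_db[pb]).max() < 0.5
        assert resp_db[f <= 0.25].max() < -40
        assert resp_db[np.argmin(np.abs(f - 50))] < -40


# ------------------------------------------------------- bad-channel flags

def test_flat_channel_flagged(clean_rec):
    data = clean_rec.data.copy()
    data[5] = 0.0
    rec = clean_rec.with_data(data)
    assert detect_bad_channels(rec) == [rec.labels[5]]


def test_runaway_channel_flagged(clean_rec):
    data = clean_rec.data.copy()
    data[7] *= 10.0
    rec = clean_rec.with_data(data)
    assert rec.labels[7] in detect_bad_channels(rec)


def test_clean_recording_has_no_flags(clean_rec):
    assert detect_bad_channels(clean_rec) == []


# ------------------------------------------------------------ interpolation

def test_spline_reproduces_constant_field(clean_rec):
    data = np.ones_like(clean_rec.data) * 3.7
    rec = clean_rec.with_data(data)
    out = interpolate_spherical_spline(rec, [rec.labels[2], rec.labels[8]])
    assert np.allclose(out.data[2], 3.7, atol=1e-6)
    assert np.allclose(out.data[8], 3.7, atol=1e-6)


def test_spline_recovers_smooth_dipolar_field(clean_rec):
    # potential of a tangential dipole just under the scalp: smooth in space
    moment = np.array([1.0, 0.5, 0.8])
    field = clean_rec.positions @ moment
    t = np.linspace(0, 1, 500)
    data = np.outer(field, np.sin(2 * np.pi * 3 * t) + 0.5)
    rec = clean_rec.with_data(data)
    truth = data[6].copy()
    out = interpolate_spherical_spline(rec, [rec.labels[6]])
    r = np.corrcoef(truth, out.data[6])[0, 1]
    assert r >= 0.95


def test_spline_matches_reference_implementation(clean_rec):
    """Interpolation operator agrees with MNE's spherical-spline matrix."""
    from mne.channels.interpolation import _make_interpolation_matrix

    good = clean_rec.positions[:20]
    bad = clean_rec.positions[20:24]
    ours = interpolation_weights(good, bad)
    theirs = _make_interpolation_matrix(good, bad, alpha=1e-5)
    assert np.allclose(ours, theirs, atol=1e-6)


def test_empty_bad_list_is_identity(clean_rec):
    out = interpolate_spherical_spline(clean_rec, [])
    assert np.array_equal(out.data, clean_rec.data)


def test_good_channels_untouched(clean_rec):
    out = interpolate_spherical_spline(clean_rec, [clean_rec.labels[3]])
    untouched = [i for i in range(clean_rec.n_channels) if i != 3]
    assert np.array_equal(out.data[untouched], clean_rec.data[untouched])


def test_too_few_good_channels_raises(clean_rec):
    bad = [clean_rec.labels[i] for i in range(22)]
    with pytest.raises(ValueError, match="at least 4"):
        interpolate_spherical_spline(clean_rec, bad)


# ---------------------------------------------------------------- ICA stage

@pytest.fixture(scope="module")
def blink_twins():
    base = dict(duration=75.0, seed=21)
    clean = pq.generate_eeg(pq.EEGGenSpec(**base))
    dirty = pq.generate_eeg(pq.EEGGenSpec(blink_rate=10.0, **base))
    return clean, dirty


def _delta_power(rec, idx):
    f, p = signal.welch(rec.data[idx], rec.sfreq, nperseg=int(4 * rec.sfreq))
    m = (f >= 0.5) & (f < 4)
    return p[:, m].sum(axis=1)


def test_blink_removal_restores_frontal_band_power(blink_twins):
    clean, dirty = blink_twins
    out = remove_blink_components(dirty, seed=21)
    frontal = [clean.index_of(l) for l in clean.frontal_labels()]
    others = [i for i in clean.scalp_indices() if i not in frontal]
    p_clean_f = _delta_power(clean, frontal).mean()
    p_dirty_f = _delta_power(dirty, frontal).mean()
    p_out_f = _delta_power(out, frontal).mean()
    # at least halves the contaminated low-frequency power ...
    assert p_out_f <= 0.5 * p_dirty_f
    # ... while non-frontal channels barely move
    rel = np.abs(_delta_power(out, others) - _delta_power(clean, others))
    assert np.all(rel / _delta_power(clean, others) <= 0.10)


def test_blink_free_recording_nearly_unchanged(clean_rec):
    out = remove_blink_components(clean_rec, seed=7)
    for i in clean_rec.scalp_indices():
        r = np.corrcoef(clean_rec.data[i], out.data[i])[0, 1]
        assert r >= 0.95


def test_ica_is_seed_deterministic(blink_twins):
    _clean, dirty = blink_twins
    a = remove_blink_components(dirty, seed=5)
    b = remove_blink_components(dirty, seed=5)
    assert np.array_equal(a.data, b.data)


# ------------------------------------------------------------- composition

def test_preprocess_idempotent_on_clean_data(clean_rec):
    once = pq.preprocess_recording(clean_rec, seed=1)
    twice = pq.preprocess_recording(once, seed=1)
    rms1 = once.data[once.scalp_indices()].std(axis=1)
    rms2 = twice.data[twice.scalp_indices()].std(axis=1)
    assert np.all(np.abs(rms2 - rms1) / rms1 < 0.05)


def test_preprocess_preserves_montage(clean_rec):
    out = pq.preprocess_recording(clean_rec, seed=1)
    assert out.labels == clean_rec.labels
    assert out.sfreq == clean_rec.sfreq
    assert out.n_samples == clean_rec.n_samples


def test_white_noise_spectrum_flat_after_filtering(rng):
    data = rng.standard_normal((9, 48000))
    rec = _recording(data, fs=200.0)
    out = apply_filters(rec)
    psd = pq.multitaper_psd(out)
    med = pq.global_median_spectrum(psd, out.roles)
    band = (psd.freqs >= 1) & (psd.freqs <= 30)
    db = 10 * np.log10(med[band])
    assert db.max() - db.min() < 2.0      # within +-1 dB of flat
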