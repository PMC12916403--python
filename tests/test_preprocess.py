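"""Preprocessing chain: resampling fidelity, filter responses, segmentation
book-keeping and the invertible per-subject normalization."""

import numpy as np
import pytest

from ppg2ecg import preprocess as pp
from ppg2ecg import synthdata as sd


# -- resampling -------------------------------------------------------------

def test_resample_identity_grid(rng):
    x = rng.normal(size=200)
    assert np.allclose(pp.resample(x, 64, 64), x, atol=1e-9)


def test_resample_sine_against_closed_form():
    t = np.arange(64 * 10) / 64
    y = pp.resample(np.sin(2 * np.pi * 2 * t), 64, 130)
    ref = np.sin(2 * np.pi * 2 * np.arange(len(y)) / 130)
    # ignore the last few samples held at the input edge
    assert np.abs(y[:-5] - ref[:-5]).max() < 1e-3


def test_resample_length_arithmetic():
    assert len(pp.resample(np.zeros(640), 64, 130)) == 1300


def test_resample_rejects_tiny_input():
    with pytest.raises(ValueError):
        pp.resample(np.zeros(3), 64, 130)


# -- filters ----------------------------------------------------------------

def test_ecg_filter_passband_gain():
    fs = 130.0
    t = np.arange(int(30 * fs)) / fs
    tone = np.sin(2 * np.pi * 20 * t)
    out = pp.filter_ecg(tone, fs)
    ratio = np.sqrt(np.mean(out[260:-260] ** 2) / np.mean(tone[260:-260] ** 2))
    assert 0.89 <= ratio <= 1.12


def test_ecg_filter_rejects_slow_drift():
    fs = 130.0
    t = np.arange(int(60 * fs)) / fs
    drift = np.sin(2 * np.pi * 0.05 * t)
    out = pp.filter_ecg(drift, fs)
    assert np.sqrt(np.mean(out ** 2) / np.mean(drift ** 2)) < 0.1


def test_filters_remove_dc_and_preserve_length(rng):
    const = np.full(int(40 * 130), 2.5)
    out = pp.filter_ecg(const, 130)
    assert np.abs(out).max() < 0.01 * const[0]    # DC suppressed > 40 dB
    x = rng.normal(size=int(20 * 130))
    assert len(pp.filter_ppg(x, 130)) == len(x)
    assert len(pp.filter_ecg(x, 130)) == len(x)


def test_filter_nyquist_guard():
    with pytest.raises(ValueError):
        pp.filter_ecg(np.zeros(1000), fs=60)      # 45 Hz band needs fs > 90


# -- median -----------------------------------------------------------------

def test_median_despike_hand_example():
    out = pp.median_despike(np.array([1.0, 9.0, 2.0, 8.0, 3.0]), 3)
    assert np.array_equal(out, [1, 2, 8, 3, 3])


def test_median_despike_kills_isolated_spike():
    x = np.zeros(50)
    x[25] = 10.0
    assert pp.median_despike(x, 5).max() < 1e-12


def test_median_despike_keeps_monotone_interior():
    ramp = np.arange(20.0)
    assert np.array_equal(pp.median_despike(ramp, 3)[1:-1], ramp[1:-1])


def test_median_despike_rejects_even_kernel():
    with pytest.raises(ValueError):
        pp.median_despike(np.zeros(10), 4)


# -- segmentation -----------------------------------------------------------

def test_segment_sizes_and_hop():
    e = np.zeros(2600)
    segs = pp.segment(e, e, 130, 4, 0.2)
    assert len(segs[0][1]) == 520
    assert segs[1][0] - segs[0][0] == 416
    assert len(segs) == (2600 - 520) // 416 + 1


def test_segment_zero_overlap_tiles():
    e = np.zeros(1040)
    segs = pp.segment(e, e, 130, 4, 0.0)
    assert [s for s, _, _ in segs] == [0, 520]


@pytest.mark.parametrize("n,window_s,overlap", [(3000, 4, 0.2), (5200, 8, 0.5),
                                                (2600, 16, 0.0)])
def test_segment_count_formula(n, window_s, overlap):
    """Window count equals the brute-force enumeration of valid starts."""
    e = np.zeros(n)
    w = round(window_s * 130)
    if n < w:
        return
    segs = pp.segment(e, e, 130, window_s, overlap)
    hop = max(round(w * (1 - overlap)), 1)
    brute = len([s for s in range(0, n, hop) if s + w <= n])
    assert len(segs) == brute == (n - w) // hop + 1


def test_segment_rejects_short_signal():
    with pytest.raises(ValueError):
        pp.segment(np.zeros(100), np.zeros(100), 130, 4, 0.2)


# -- normalization ----------------------------------------------------------

def test_normalize_endpoints():
    out = pp.normalize(np.array([-0.5, 2.0]), -0.5, 2.0)
    assert np.allclose(out, [-1.0, 1.0])


def test_normalize_roundtrip(rng):
    w = rng.uniform(-0.5, 2.0, 100)
    back = pp.denormalize(pp.normalize(w, -0.5, 2.0), -0.5, 2.0)
    assert np.abs(back - w).max() < 1e-9


def test_normalize_clips_and_counts_exceedances():
    y, n_clip = pp.normalize(np.array([0.0, 5.0, -3.0]), -1.0, 1.0,
                             with_count=True)
    assert n_clip == 2
    assert y.max() == 1.0 and y.min() == -1.0


def test_normalize_rejects_degenerate_range():
    with pytest.raises(ValueError):
        pp.normalize(np.zeros(4), 1.0, 1.0)
    with pytest.raises(ValueError):
        pp.NormParams(0.0, 0.0, -1.0, 1.0)


# -- alignment --------------------------------------------------------------

@pytest.mark.parametrize("true_lag", [0.0, 0.3])
def test_alignment_recovers_pulse_arrival_lag(true_lag):
    prof = sd.SubjectProfile("a", mean_hr=70, hrv_sd=0.03,
                             ppg_lag=true_lag, seed=11)
    rec = sd.make_record(prof, 60)
    _, lag = pp.align_pair(rec)
    assert abs(lag - true_lag) <= 1 / 130


def test_alignment_zeroes_median_peak_offset():
    prof = sd.SubjectProfile("b", mean_hr=72, hrv_sd=0.03, ppg_lag=0.3, seed=13)
    rec = sd.make_record(prof, 60)
    aligned, _ = pp.align_pair(rec)
    from ppg2ecg.evaluation import detect_ppg_peaks
    s = detect_ppg_peaks(aligned.ppg, aligned.ppg_fs)
    offsets = [s[np.argmin(np.abs(s - r))] - r for r in rec.r_peak_times]
    assert abs(np.median(offsets)) < 1 / 64


def test_alignment_requires_enough_signal():
    prof = sd.SubjectProfile("c", seed=1)
    with pytest.raises(ValueError):
        pp.align_pair(sd.make_record(prof, 8))


# -- whole-record pipeline --------------------------------------------------

def test_pipeline_length_bookkeeping_and_invariants(segment_pairs):
    assert segment_pairs, "pipeline produced no segments"
    for sp in segment_pairs:
        assert len(sp.p) == len(sp.e) == round(sp.window_s * sp.fs)
        assert np.abs(sp.p).max() <= 1 and np.abs(sp.e).max() <= 1
        assert sp.norm_params.e_max > sp.norm_params.e_min


def test_archive_roundtrip(tmp_path, segment_pairs):
    cfg = pp.PreprocessConfig(window_s=4)
    path = tmp_path / "segments.npz"
    pp.save_segments(path, segment_pairs, cfg)
    back, cfg2 = pp.load_segments(path)
    assert cfg2.window_s == cfg.window_s
    assert len(back) == len(segment_pairs)
    assert np.array_equal(back[0].p, segment_pairs[0].p)
    assert back[0].subject_id == segment_pairs[0].subject_id


def test_config_validation():
    with pytest.raises(ValueError):
        pp.PreprocessConfig(overlap_frac=1.0)
    with pytest.raises(ValueError):
        pp.PreprocessConfig(median_kernel=4)
    with pytest.raises(ValueError):
        pp.PreprocessConfig(ecg_band=(45.0, 0.5))
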