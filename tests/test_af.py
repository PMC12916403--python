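"""AF harness: QRS excision, Welch band power, data-mixing bookkeeping,
classification metrics and baseline comparison."""

import numpy as np
import pytest

from ppg2ecg import af
from ppg2ecg import synthdata as sd


@pytest.fixture(scope="module")
def clean_components():
    prof = sd.SubjectProfile("a", mean_hr=65, hrv_sd=0.03, seed=21)
    return sd.generate_ecg_components(prof, 60, 130)


# -- QRS excision -----------------------------------------------------------

def test_excision_recovers_qrs_free_component(clean_components):
    ecg, qrs_free, r = clean_components
    base = af.excise_qrs(ecg, 130, widen_ms=60, r_peaks=r)
    assert len(base) == len(ecg)
    assert np.sqrt(np.mean((base - qrs_free) ** 2)) < 0.05


def test_excision_zero_width_replaces_single_sample(clean_components):
    ecg, _, r = clean_components
    base = af.excise_qrs(ecg, 130, widen_ms=0, r_peaks=r)
    changed = np.flatnonzero(base != ecg)
    expected = np.round(np.asarray(r) * 130).astype(int)
    assert set(changed) <= set(expected)


def test_excised_spans_are_exactly_linear(clean_components):
    ecg, _, r = clean_components
    half = int(round(0.06 * 130))
    base = af.excise_qrs(ecg, 130, widen_ms=60, r_peaks=r)
    c = int(round(r[3] * 130))
    span = base[c - half: c + half + 1]
    line = np.linspace(span[0], span[-1], len(span))
    assert np.allclose(span, line, atol=1e-9)


def test_excised_trace_has_no_detectable_r_peaks(clean_components):
    """HR from the excised trace is undefined by construction: the detector
    must not find a beat train resembling the original."""
    from ppg2ecg.evaluation import detect_r_peaks, match_peaks
    ecg, _, r = clean_components
    base = af.excise_qrs(ecg, 130, widen_ms=60, r_peaks=r)
    try:
        det = detect_r_peaks(base, 130)
    except ValueError:
        return
    hits, miss, fa = match_peaks(r, det, tol_s=1.5 / 130)
    assert hits < 0.5 * len(r)


# -- Welch band power -------------------------------------------------------

def test_tone_power_localized_to_fibrillatory_band():
    fs = 130.0
    t = np.arange(int(60 * fs)) / fs
    tone = np.sin(2 * np.pi * 5.0 * t)
    total = af.welch_band_power(tone, fs, af.BAND_TOTAL)
    fib = af.welch_band_power(tone, fs, af.BAND_FIBRILLATORY)
    assert fib / total >= 0.95


def test_white_noise_parseval(rng):
    fs = 130.0
    x = rng.normal(size=int(60 * fs))
    power = af.welch_band_power(x, fs, (0.0, fs / 2))
    assert power == pytest.approx(np.var(x), rel=0.10)


def test_band_power_guards():
    assert af.welch_band_power(np.zeros(4000), 130, (0.05, 9)) == 0.0
    with pytest.raises(ValueError):
        af.welch_band_power(np.zeros(4000), 130, (0.05, 100))


# -- synthetic AF cohort ----------------------------------------------------

def test_af_cohort_spectral_signature():
    recs, labels = af.make_af_cohort(2, 2, 60, seed=5)
    fib = [af.baseline_profile(r.ecg, 130, r_peaks=r.r_peak_times)
           .band_power_fib for r in recs]
    assert min(fib[i] for i in range(2)) > max(fib[i] for i in range(2, 4))


def test_af_rr_variability_elevated():
    recs, labels = af.make_af_cohort(2, 2, 60, seed=8)
    sds = [np.std(np.diff(r.r_peak_times)) for r in recs]
    assert min(sds[:2]) > max(sds[2:])


# -- classification metrics -------------------------------------------------

def test_confusion_matrix_partitions_and_f1_identity(rng):
    y = rng.integers(0, 2, 200)
    p = rng.random(200)
    out = af.classification_metrics(y, p)
    (tn, fp), (fn, tp) = out["confusion"]
    assert tn + fp + fn + tp == 200
    prec, rec = out["precision"], out["recall"]
    if prec + rec:
        assert out["f1"] == pytest.approx(2 * prec * rec / (prec + rec),
                                          abs=1e-12)


def test_perfect_oracle_scores_one():
    y = np.array([0, 1, 0, 1, 1])
    out = af.classification_metrics(y, y.astype(float))
    assert out["accuracy"] == 1.0 and out["f1"] == 1.0


# -- mixing protocol --------------------------------------------------------

def _toy_sets(rng, n=40, t=64):
    X = rng.normal(size=(n, t))
    y = (np.arange(n) % 2).astype(float)
    X[y == 1] += 1.0
    return X, y


def test_mix_bookkeeping_constant_total(rng):
    Xr, yr = _toy_sets(rng)
    Xg, yg = _toy_sets(rng)
    Xt, yt = _toy_sets(rng, n=20)
    oracle = lambda X: (X.mean(axis=1) > 0.5).astype(float)
    totals = set()
    for frac in af.MIX_FRACTIONS:
        out = af.run_mix_experiment((Xr, yr), (Xg, yg), (Xt, yt),
                                    af.MixProtocol(frac, seed=4),
                                    predict_fn=oracle)
        totals.add(out["n_train"])
        (tn, fp), (fn, tp) = out["confusion"]
        assert tn + fp + fn + tp == len(yt)
    assert len(totals) == 1


def test_mix_protocol_validation():
    with pytest.raises(ValueError):
        af.MixProtocol(0.3)


def test_mix_experiment_perfect_oracle(rng):
    Xr, yr = _toy_sets(rng)
    Xt, yt = _toy_sets(rng, n=20)
    out = af.run_mix_experiment((Xr, yr), (Xr, yr), (Xt, yt),
                                af.MixProtocol(1.0, seed=1),
                                predict_fn=lambda X: yt)
    assert out["accuracy"] == 1.0 and out["f1"] == 1.0


def test_trained_classifier_separates_easy_cohort(rng):
    """Tiny Bid-LSTM learns a strongly separated two-class problem."""
    from ppg2ecg.models import AFClassifierConfig
    Xr, yr = _toy_sets(rng, n=32, t=32)
    Xt, yt = _toy_sets(np.random.default_rng(123), n=16, t=32)
    out = af.run_mix_experiment(
        (Xr, yr), (Xr, yr), (Xt, yt), af.MixProtocol(1.0, seed=2),
        classifier="bidlstm", epochs=14, lr=5e-3,
        clf_config=AFClassifierConfig(hidden=6, fc_units=8, dropout=0.0))
    assert out["accuracy"] >= 0.8


# -- baseline comparison ----------------------------------------------------

def test_baseline_compare_identity_limit():
    recs, labels = af.make_af_cohort(1, 1, 40, seed=3)
    ecgs = [r.ecg for r in recs]
    peaks = [r.r_peak_times for r in recs]
    rows = af.baseline_compare(ecgs, [e.copy() for e in ecgs], labels,
                               r_peaks=peaks)
    assert {r["class"] for r in rows} == {"AF", "non-AF"}
    for r in rows:
        assert r["rmse_mean"] == pytest.approx(0.0, abs=1e-12)
        assert r["fd_mean"] == pytest.approx(0.0, abs=1e-12)
        assert r["rho_mean"] == pytest.approx(1.0)
        assert r["dpow_mean"] == pytest.approx(0.0, abs=1e-12)


def test_baseline_compare_registers_injected_drift():
    recs, labels = af.make_af_cohort(1, 1, 40, seed=6)
    fs = 130.0
    drifted = []
    for r in recs:
        t = np.arange(len(r.ecg)) / fs
        drifted.append(r.ecg + 0.1 * np.sin(2 * np.pi * 0.2 * t))
    rows = af.baseline_compare([r.ecg for r in recs], drifted, labels,
                               r_peaks=[r.r_peak_times for r in recs])
    for row in rows:
        assert row["dpow_mean"] > 0
    # drift concentrates in the wander band
    bp_clean = af.baseline_profile(recs[0].ecg, fs,
                                   r_peaks=recs[0].r_peak_times)
    bp_drift = af.baseline_profile(drifted[0], fs,
                                   r_peaks=recs[0].r_peak_times)
    delta_w = bp_drift.band_power_wander - bp_clean.band_power_wander
    delta_f = abs(bp_drift.band_power_fib - bp_clean.band_power_fib)
    assert delta_w > 10 * delta_f
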