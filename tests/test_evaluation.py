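"""Metric oracles (closed forms, brute-force couplings) and peak detection
against synthetic ground truth."""

import functools
import numpy as np
import pytest

from ppg2ecg import evaluation as ev
from ppg2ecg import preprocess as pp
from ppg2ecg import synthdata as sd


# -- RMSE / Pearson ---------------------------------------------------------

def test_rmse_closed_forms(rng):
    x = rng.normal(size=100)
    assert ev.rmse(x, x) == 0.0
    assert ev.rmse(x, x + 0.5) == pytest.approx(0.5)
    y = rng.normal(size=100)
    brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / 100)
    assert ev.rmse(x, y) == pytest.approx(brute, abs=1e-12)
    with pytest.raises(ValueError):
        ev.rmse(x, y[:50])


def test_pearson_closed_forms(rng):
    x = rng.normal(size=100)
    assert ev.pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
    assert ev.pearson_r(x, -x) == pytest.approx(-1.0)
    y = rng.normal(size=100)
    brute = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
    assert ev.pearson_r(x, y) == pytest.approx(brute, abs=1e-10)
    with pytest.raises(ValueError):
        ev.pearson_r(x, np.zeros(100))


# -- Fréchet distance -------------------------------------------------------

def _frechet_brute(P, Q):
    @functools.lru_cache(None)
    def rec(i, j):
        d = float(np.hypot(P[i][0] - Q[j][0], P[i][1] - Q[j][1]))
        if i == 0 and j == 0:
            return d
        opts = []
        if i > 0:
            opts.append(rec(i - 1, j))
        if j > 0:
            opts.append(rec(i, j - 1))
        if i > 0 and j > 0:
            opts.append(rec(i - 1, j - 1))
        return max(min(opts), d)

    return rec(len(P) - 1, len(Q) - 1)


def test_frechet_identities(rng):
    x = rng.normal(size=20)
    assert ev.frechet_distance(x, x) == 0.0
    assert ev.frechet_distance(np.array([2.0]), np.array([5.0])) == 3.0
    y = rng.normal(size=20)
    assert ev.frechet_distance(x, y) == pytest.approx(
        ev.frechet_distance(y, x))
    with pytest.raises(ValueError):
        ev.frechet_distance(np.empty(0), x)


def test_frechet_equals_exhaustive_coupling_enumeration(rng):
    """200 random short curve pairs against the brute-force recursion."""
    for _ in range(200):
        n, m = rng.integers(1, 6), rng.integers(1, 6)
        y, yr = rng.normal(size=n), rng.normal(size=m)
        got = ev.frechet_distance(y, yr)
        P = tuple((float(i), float(v)) for i, v in enumerate(y))
        Q = tuple((float(i), float(v)) for i, v in enumerate(yr))
        assert got == pytest.approx(_frechet_brute(P, Q), abs=1e-10)


# -- R-peak detection -------------------------------------------------------

def test_r_peaks_exact_on_clean_cohort(clean_cohort):
    for rec in clean_cohort:
        det = ev.detect_r_peaks(rec.ecg, rec.ecg_fs)
        hits, miss, fa = ev.match_peaks(rec.r_peak_times, det,
                                        tol_s=1.5 / rec.ecg_fs)
        assert miss == 0 and fa == 0


def test_r_peaks_polarity_robust(clean_cohort):
    rec = clean_cohort[0]
    det = ev.detect_r_peaks(-rec.ecg, rec.ecg_fs)
    hits, miss, fa = ev.match_peaks(rec.r_peak_times, det, tol_s=1.5 / 130)
    assert miss == 0 and fa == 0


def test_r_peaks_refractory_bound(clean_cohort):
    for rec in clean_cohort[:3]:
        det = ev.detect_r_peaks(rec.ecg, rec.ecg_fs)
        assert np.all(np.diff(det) >= 0.2)


def test_r_peaks_guards():
    with pytest.raises(ValueError):
        ev.detect_r_peaks(np.zeros(2000), 130)
    with pytest.raises(ValueError):
        ev.detect_r_peaks(np.random.default_rng(0).normal(size=100), 130)


# -- PPG peak detection -----------------------------------------------------

def test_ppg_peaks_count_at_75_bpm():
    prof = sd.SubjectProfile("a", mean_hr=75, hrv_sd=0.0, seed=6)
    _, r = sd.generate_ecg(prof, 60.0)
    ppg = sd.generate_ppg_from_ecg(r, 60.0, 64.0, lag=0.25)
    det = ev.detect_ppg_peaks(ppg, 64.0)
    assert abs(len(det) - 75) <= 2      # edge beats trimmed from the record


def test_ppg_peaks_exact_against_known_lag():
    for i in range(10):
        gen = np.random.default_rng(500 + i)
        prof = sd.make_subject_profile(f"P{i}", gen)
        _, r = sd.generate_ecg(prof, 60.0)
        ppg = sd.generate_ppg_from_ecg(r, 60.0, 64.0, lag=prof.ppg_lag)
        det = ev.detect_ppg_peaks(ppg, 64.0)
        hits, miss, fa = ev.match_peaks(r + prof.ppg_lag, det, tol_s=2.5 / 64)
        assert miss == 0 and fa == 0


def test_ppg_peaks_min_spacing(clean_cohort):
    det = ev.detect_ppg_peaks(clean_cohort[0].ppg, 64.0)
    assert np.all(np.diff(det) >= 0.25)


# -- MAE-HR -----------------------------------------------------------------

def test_mae_hr_closed_forms():
    gt = [np.array([0.0, 1.0, 2.0, 3.0])]
    assert ev.mae_hr(gt, gt)["mae_hr"] == 0.0
    q = [np.array([0.0, 0.5, 1.0, 1.5])]
    assert ev.mae_hr(gt, q)["mae_hr"] == pytest.approx(60.0)


def test_mae_hr_matches_brute_force_per_segment(rng):
    gts, qs = [], []
    for _ in range(10):
        n = rng.integers(3, 8)
        gts.append(np.cumsum(rng.uniform(0.7, 1.1, n)))
        qs.append(np.cumsum(rng.uniform(0.7, 1.1, n)))
    out = ev.mae_hr(gts, qs)
    brute = np.mean([abs(60 / np.mean(np.diff(g)) - 60 / np.mean(np.diff(q)))
                     for g, q in zip(gts, qs)])
    assert out["mae_hr"] == pytest.approx(brute, abs=1e-12)
    assert out["n"] == 10


def test_mae_hr_exclusion_rules():
    gt = [np.array([0.0, 1.0]), np.array([0.5])]
    q = [np.array([0.0, 1.0]), np.array([0.2, 0.9])]
    out = ev.mae_hr(gt, q)
    assert out["excluded"] == 1 and out["n"] == 1
    with pytest.raises(ValueError):
        ev.mae_hr([np.array([0.0])], [np.array([0.0])])


# -- window-level evaluation ------------------------------------------------

def test_evaluate_windows_identity_oracle(segment_pairs):
    """A perfect generator (returns the reference ECG) scores RMSE 0, ρ 1,
    MAE-HR(E') 0."""
    pairs = segment_pairs[:6]
    it = iter([sp.e for sp in pairs])
    report = ev.evaluate_windows({4: pairs}, lambda p: next(it), fs=130.0)
    row = report.table.iloc[0]
    assert row["rmse_mean"] == pytest.approx(0.0, abs=1e-12)
    assert row["rho_mean"] == pytest.approx(1.0)
    assert row["mae_e_mean"] == pytest.approx(0.0, abs=1e-9)
    assert row["fd_mean"] == pytest.approx(0.0, abs=1e-12)


def test_evaluate_windows_flags_degenerate_generator(segment_pairs):
    pairs = segment_pairs[:3]
    report = ev.evaluate_windows({4: pairs}, lambda p: np.zeros_like(p),
                                 fs=130.0)
    assert report.flagged                      # ρ undefined → flagged, kept
    assert all(f[0] == 4 for f in report.flagged)


def test_mae_hr_p_independent_of_generator(segment_pairs):
    pairs = segment_pairs[:6]
    it1 = iter([sp.e for sp in pairs])
    r1 = ev.evaluate_windows({4: pairs}, lambda p: next(it1), fs=130.0)
    rng = np.random.default_rng(0)
    it2 = iter([np.clip(sp.e + 0.05 * rng.normal(size=len(sp.e)), -1, 1)
                for sp in pairs])
    r2 = ev.evaluate_windows({4: pairs}, lambda p: next(it2), fs=130.0)
    assert r1.table["mae_p_mean"].iloc[0] == pytest.approx(
        r2.table["mae_p_mean"].iloc[0])
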