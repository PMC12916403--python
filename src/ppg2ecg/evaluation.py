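"""Signal-fidelity metrics and heart-rate evaluation.

Per-window metrics between a reference ECG and its reconstruction: RMSE (mV,
computed after denormalization), discrete Fréchet distance between the two
(t, y) curves, Pearson correlation, and MAE of heart rate derived from
detected peaks.  R peaks come from a Pan–Tompkins-style detector (band-pass →
derivative → squaring → moving-window integration → adaptive thresholding
with a refractory period); PPG systolic peaks from a slope-sum detector with
adaptive thresholding and event windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:                                   # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# waveform metrics
# ---------------------------------------------------------------------------

def rmse(y: np.ndarray, yr: np.ndarray) -> float:
    """Root mean squared difference; original (mV) scale is the caller's job."""
    y, yr = np.asarray(y, float), np.asarray(yr, float)
    if y.shape != yr.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y - yr) ** 2)))


def pearson_r(y: np.ndarray, yr: np.ndarray) -> float:
    """Centered inner product over the product of Euclidean norms."""
    y, yr = np.asarray(y, float), np.asarray(yr, float)
    if y.shape != yr.shape:
        raise ValueError("length mismatch")
    yc, rc = y - y.mean(), yr - yr.mean()
    denom = np.linalg.norm(yc) * np.linalg.norm(rc)
    if denom == 0:
        raise ValueError("zero-variance input")
    return float(np.dot(yc, rc) / denom)


def _frechet_dp(dist: np.ndarray) -> float:
    n, m = dist.shape
    ca = np.empty((n, m))
    ca[0, 0] = dist[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], dist[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], dist[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i, j - 1], ca[i - 1, j - 1]),
                           dist[i, j])
    return ca[n - 1, m - 1]


if _HAVE_NUMBA:
    _frechet_dp = njit(cache=False)(_frechet_dp)


def frechet_distance(y: np.ndarray, yr: np.ndarray,
                     t: np.ndarray | None = None,
                     tr: np.ndarray | None = None) -> float:
    """Discrete Fréchet distance between curves (t, y) and (t, yr).

    Standard coupling dynamic program; symmetric, zero iff the curves are
    identical.  With no explicit time axes, sample index is used.
    """
    y, yr = np.asarray(y, float), np.asarray(yr, float)
    if y.size == 0 or yr.size == 0:
        raise ValueError("empty curve")
    ta = np.arange(len(y), dtype=float) if t is None else np.asarray(t, float)
    tb = np.arange(len(yr), dtype=float) if tr is None else np.asarray(tr, float)
    dist = np.sqrt((ta[:, None] - tb[None, :]) ** 2
                   + (y[:, None] - yr[None, :]) ** 2)
    return float(_frechet_dp(dist))


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float,
                   refractory_s: float = 0.2) -> np.ndarray:
    """Pan–Tompkins-style R-peak detection; returns peak times in seconds.

    Stages: 5–15 Hz band-pass → derivative → squaring → 150 ms moving-window
    integration → adaptive signal/noise thresholds with a refractory period.
    Detections are refined to the local extremum of the raw signal, so on
    clean input the returned time is the exact sample of the R maximum,
    regardless of polarity.
    """
    ecg = np.asarray(ecg, float)
    if np.ptp(ecg) == 0:
        raise ValueError("flat signal: no peaks")
    if len(ecg) < 4 * fs:
        raise ValueError("need at least 4 s of signal")
    b, a = butter(2, [5 / (fs / 2), 15 / (fs / 2)], btype="band")
    band = filtfilt(b, a, ecg)
    deriv = np.gradient(band) * fs
    sq = deriv**2
    win = max(int(0.15 * fs), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = max(int(refractory_s * fs), 1)
    cands, _ = find_peaks(mwi, distance=refractory)
    if cands.size == 0:
        raise ValueError("no candidate peaks")
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    peaks = []
    for c in cands:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr:
            peaks.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
    # refine to the raw-signal extremum (polarity-robust via |x - median|)
    half = int(0.10 * fs)
    ref = np.abs(ecg - np.median(ecg))
    refined = []
    for c in peaks:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        refined.append(lo + int(np.argmax(ref[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory bound after refinement
    out = []
    for r in refined:
        if not out or r - out[-1] >= refractory:
            out.append(r)
        elif ref[r] > ref[out[-1]]:
            out[-1] = r
    return np.asarray(out) / fs


def detect_ppg_peaks(ppg: np.ndarray, fs: float,
                     min_spacing_s: float = 0.25) -> np.ndarray:
    """Systolic-peak detection via clipped slope-sum + adaptive threshold.

    Returns peak times (seconds), strictly increasing with spacing of at
    least ``min_spacing_s``.
    """
    ppg = np.asarray(ppg, float)
    if np.ptp(ppg) == 0:
        raise ValueError("flat signal: no peaks")
    if len(ppg) < 4 * fs:
        raise ValueError("need at least 4 s of signal")
    hi_edge = min(8.0, 0.45 * fs)
    b, a = butter(4, [0.5 / (fs / 2), hi_edge / (fs / 2)], btype="band")
    filt = filtfilt(b, a, ppg)
    slope = np.clip(np.diff(filt, prepend=filt[0]), 0, None)
    win = max(int(0.128 * fs), 1)
    ssf = np.convolve(slope, np.ones(win), mode="same")

    spacing = max(int(min_spacing_s * fs), 1)
    thr = 0.4 * np.quantile(ssf[ssf > 0], 0.90) if np.any(ssf > 0) else 0.0
    events, _ = find_peaks(ssf, height=thr, distance=spacing)
    if events.size == 0:
        raise ValueError("no pulse events detected")
    # refine: local maximum of the (wide-band) pulse wave near each event
    b2, a2 = butter(4, [0.5 / (fs / 2), min(15.0, 0.45 * fs) / (fs / 2)],
                    btype="band")
    wide = filtfilt(b2, a2, ppg)
    half = int(0.25 * fs)
    refined = []
    for c in events:
        lo, hi = max(0, c - half // 2), min(len(ppg), c + half + 1)
        refined.append(lo + int(np.argmax(wide[lo:hi])))
    refined = np.unique(refined)
    out = []
    for r in refined:
        if not out or r - out[-1] >= spacing:
            out.append(r)
        elif wide[r] > wide[out[-1]]:
            out[-1] = r
    return np.asarray(out) / fs


def match_peaks(truth: np.ndarray, detected: np.ndarray,
                tol_s: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (hits, misses, false alarms)."""
    truth = np.asarray(truth, float)
    detected = list(np.asarray(detected, float))
    hits = 0
    for tt in truth:
        if not detected:
            break
        j = int(np.argmin(np.abs(np.asarray(detected) - tt)))
        if abs(detected[j] - tt) <= tol_s:
            hits += 1
            detected.pop(j)
    return hits, len(truth) - hits, len(detected)


# ---------------------------------------------------------------------------
# heart-rate MAE
# ---------------------------------------------------------------------------

def segment_hr(peaks: np.ndarray) -> float:
    """HR (bpm) = 60 / mean RR within the segment; needs >= 2 peaks."""
    peaks = np.asarray(peaks, float)
    if len(peaks) < 2:
        raise ValueError("need at least two peaks for an RR interval")
    return 60.0 / float(np.mean(np.diff(peaks)))


def mae_hr(peaks_gt: list, peaks_q: list) -> dict:
    """Mean absolute HR error over segments; segments with < 2 peaks in
    either train are excluded and counted.

    Inputs are lists of per-segment peak-time arrays.
    """
    if len(peaks_gt) != len(peaks_q):
        raise ValueError("segment count mismatch")
    errors, excluded = [], 0
    for gt, q in zip(peaks_gt, peaks_q):
        if len(gt) < 2 or len(q) < 2:
            excluded += 1
            continue
        errors.append(abs(segment_hr(gt) - segment_hr(q)))
    if not errors:
        raise ValueError("no segment retained for the HR comparison")
    return {"mae_hr": float(np.mean(errors)), "n": len(errors),
            "excluded": excluded}


# ---------------------------------------------------------------------------
# window-level report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    table: pd.DataFrame          # one row per window length
    per_segment: pd.DataFrame    # one row per evaluated segment
    flagged: list                # (window_s, segment index, reason)


def evaluate_windows(test_pairs_by_window: dict, generate_fn,
                     fs: float = 130.0) -> MetricsReport:
    """Metric battery over window lengths.

    ``test_pairs_by_window`` maps window length (s) to a list of SegmentPairs;
    ``generate_fn`` maps a normalized PPG window to a normalized ECG window
    (the trained generator, or an oracle).  Metrics are computed on the
    denormalized (mV) scale; MAE-HR compares HR from detected peaks of the
    reference ECG against both the reconstruction (E') and the input PPG (P).
    """
    from .preprocess import denormalize

    rows, seg_rows, flagged = [], [], []
    for window_s, pairs in sorted(test_pairs_by_window.items()):
        vals = {k: [] for k in ("rmse", "fd", "rho")}
        pk_gt, pk_gen, pk_ppg = [], [], []
        for i, sp in enumerate(pairs):
            gen_e = np.asarray(generate_fn(sp.p), float)
            e_mv = denormalize(sp.e, sp.norm_params.e_min, sp.norm_params.e_max)
            g_mv = denormalize(gen_e, sp.norm_params.e_min, sp.norm_params.e_max)
            try:
                row = {
                    "rmse": rmse(e_mv, g_mv),
                    "fd": frechet_distance(e_mv, g_mv,
                                           t=np.arange(len(e_mv)) / fs,
                                           tr=np.arange(len(g_mv)) / fs),
                    "rho": pearson_r(e_mv, g_mv),
                }
            except ValueError as err:
                flagged.append((window_s, i, str(err)))
                continue
            for k, v in row.items():
                vals[k].append(v)
            seg_rows.append({"window_s": window_s, "segment": i,
                             "subject_id": sp.subject_id, **row})
            try:
                seg_gt = detect_r_peaks(e_mv, fs)
                seg_gen = detect_r_peaks(g_mv, fs)
                seg_ppg = detect_ppg_peaks(
                    denormalize(sp.p, sp.norm_params.p_min,
                                sp.norm_params.p_max), fs)
            except ValueError as err:
                seg_gt = seg_gen = seg_ppg = np.empty(0)
                flagged.append((window_s, i, f"peaks: {err}"))
            pk_gt.append(seg_gt)
            pk_gen.append(seg_gen)
            pk_ppg.append(seg_ppg)
        try:
            mae_e = mae_hr(pk_gt, pk_gen)
            mae_p = mae_hr(pk_gt, pk_ppg)
        except ValueError:
            mae_e = mae_p = {"mae_hr": np.nan, "n": 0,
                             "excluded": len(pk_gt)}
        rows.append({
            "segment_length_s": window_s,
            "rmse_mean": np.mean(vals["rmse"]), "rmse_sd": np.std(vals["rmse"]),
            "fd_mean": np.mean(vals["fd"]), "fd_sd": np.std(vals["fd"]),
            "rho_mean": np.mean(vals["rho"]), "rho_sd": np.std(vals["rho"]),
            "mae_e_mean": mae_e["mae_hr"], "mae_p_mean": mae_p["mae_hr"],
            "n_segments": len(vals["rmse"]),
            "n_hr_excluded": mae_e["excluded"] + mae_p["excluded"],
        })
    return MetricsReport(pd.DataFrame(rows), pd.DataFrame(seg_rows), flagged)
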