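"""Paired-signal preprocessing: align, resample, filter, despike, segment,
normalize.

The chain mirrors common wearable-ECG practice: the PPG is shifted so its
systolic peaks line up with the ECG R peaks, both channels are cubic-spline
resampled to a shared 130 Hz grid, the ECG is band-passed 0.5-45 Hz with a
zero-phase FIR and the PPG 0.5-8 Hz with a forward-backward Butterworth, a
running median removes residual spikes, and overlapping windows are cut and
min-max normalized per subject into (-1, 1).  Normalization is invertible so
metrics can be computed back on the original millivolt scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks, firwin

from .synthdata import SignalRecord

log = logging.getLogger(__name__)

ALLOWED_WINDOWS_S = (4, 8, 16, 32, 64, 96, 128, 160)


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 130.0
    ecg_band: tuple = (0.5, 45.0)
    ppg_band: tuple = (0.5, 8.0)
    median_kernel: int = 5          # ~38 ms at 130 Hz: kills spikes, spares QRS
    window_s: float = 4.0
    overlap_frac: float = 0.20
    train_frac: float = 0.8         # portion of each record used to fit min-max

    def __post_init__(self):
        for lo, hi in (self.ecg_band, self.ppg_band):
            if not (0 < lo < hi < self.target_fs / 2):
                raise ValueError("band edges must satisfy 0 < low < high < fs/2")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.median_kernel % 2 == 0 or self.median_kernel < 3:
            raise ValueError("median_kernel must be odd and >= 3")


@dataclass
class NormParams:
    """Per-subject, per-channel min-max used by the invertible normalization."""

    p_min: float
    p_max: float
    e_min: float
    e_max: float

    def __post_init__(self):
        if self.p_max <= self.p_min or self.e_max <= self.e_min:
            raise ValueError("degenerate normalization range (max <= min)")


@dataclass
class SegmentPair:
    """One aligned, filtered, normalized (p, e) window — the training unit."""

    subject_id: str
    p: np.ndarray
    e: np.ndarray
    window_s: float
    fs: float
    start_time: float
    norm_params: NormParams

    def __post_init__(self):
        n = round(self.window_s * self.fs)
        if len(self.p) != n or len(self.e) != n:
            raise ValueError("segment lengths inconsistent with window_s * fs")
        if np.abs(self.p).max() > 1 + 1e-9 or np.abs(self.e).max() > 1 + 1e-9:
            raise ValueError("normalized samples must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def resample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Cubic-spline interpolation onto a uniform ``fs_out`` grid."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(signal, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples for cubic-spline resampling")
    duration = len(x) / fs_in
    t_in = np.arange(len(x)) / fs_in
    n_out = round(duration * fs_out)
    t_out = np.arange(n_out) / fs_out
    spline = CubicSpline(t_in, x)
    out = spline(np.clip(t_out, 0, t_in[-1]))
    return out


def filter_ecg(signal: np.ndarray, fs: float,
               band: tuple = (0.5, 45.0)) -> np.ndarray:
    """Zero-phase band-pass FIR (windowed-sinc, symmetric 'same' convolution)."""
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError("sampling rate violates Nyquist for the pass band")
    x = np.asarray(signal, dtype=float)
    # transition ~0.25 Hz at the low edge; cap taps below the signal length
    numtaps = min(int(4 * fs / lo) | 1, (len(x) // 3) * 2 - 1)
    if numtaps < 31:
        raise ValueError("signal too short for the FIR band-pass")
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    pad = numtaps // 2
    xp = np.pad(x, pad, mode="reflect")
    return np.convolve(xp, taps, mode="same")[pad:-pad]


def filter_ppg(signal: np.ndarray, fs: float,
               band: tuple = (0.5, 8.0)) -> np.ndarray:
    """Forward-backward 4th-order Butterworth band-pass (zero phase)."""
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError("sampling rate violates Nyquist for the pass band")
    b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, np.asarray(signal, dtype=float))


def median_despike(signal: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Running median with edge replication; length preserved."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    return median_filter(np.asarray(signal, dtype=float), size=kernel,
                         mode="nearest")


def _peak_train(signal: np.ndarray, fs: float, min_dist_s: float) -> np.ndarray:
    # half of the largest excursion: excludes T waves / dicrotic bumps
    height = 0.5 * np.max(signal)
    peaks, _ = find_peaks(signal, height=height,
                          distance=max(int(min_dist_s * fs), 1))
    return peaks / fs


def estimate_lag(record: SignalRecord, max_lag_s: float = 0.6,
                 step_s: float = 0.002) -> float:
    """Pulse-arrival lag via cross-correlation of smoothed peak trains.

    One global lag per record; robust to occasional missed beats.
    """
    ecg_f = filter_ecg(record.ecg, record.ecg_fs)
    # wider PPG band than the analysis filter: an 8 Hz low-pass visibly
    # shifts the asymmetric systolic peak, which would bias the lag
    ppg_f = filter_ppg(record.ppg, record.ppg_fs,
                       band=(0.5, min(15.0, 0.45 * record.ppg_fs)))
    r_times = _peak_train(ecg_f, record.ecg_fs, 0.25)
    s_times = _peak_train(ppg_f, record.ppg_fs, 0.3)
    if len(r_times) < 3 or len(s_times) < 3:
        raise ValueError("not enough peaks detectable to align the channels")
    grid = np.arange(0.0, record.duration, step_s)
    sigma = 0.015
    def smear(times):
        out = np.zeros_like(grid)
        for tt in times:
            lo = max(0, int((tt - 5 * sigma) / step_s))
            hi = min(len(grid), int((tt + 5 * sigma) / step_s) + 1)
            out[lo:hi] += np.exp(-0.5 * ((grid[lo:hi] - tt) / sigma) ** 2)
        return out
    e_train, p_train = smear(r_times), smear(s_times)
    lags = np.arange(0, int(max_lag_s / step_s) + 1)
    scores = [np.dot(e_train[: len(grid) - lag], p_train[lag:]) for lag in lags]
    return float(lags[int(np.argmax(scores))] * step_s)


def align_pair(record: SignalRecord) -> tuple[SignalRecord, float]:
    """Shift the PPG earlier by the estimated lag; edge-pad to keep length."""
    if record.duration < 10:
        raise ValueError("alignment needs at least 10 s of signal")
    lag = estimate_lag(record)
    shift = round(lag * record.ppg_fs)
    ppg = np.concatenate([record.ppg[shift:],
                          np.full(shift, record.ppg[-1])]) if shift else record.ppg.copy()
    shifted = SignalRecord(record.subject_id, record.ecg, record.ecg_fs,
                           ppg, record.ppg_fs,
                           record.r_peak_times, record.duration)
    return shifted, lag


def segment(ecg: np.ndarray, ppg: np.ndarray, fs: float, window_s: float,
            overlap_frac: float = 0.2):
    """Cut both channels into windows with identical start indices.

    Returns a list of ``(start_index, ppg_window, ecg_window)``; the trailing
    partial window is dropped.
    """
    if len(ecg) != len(ppg):
        raise ValueError("channels must share a time base before segmentation")
    w = round(window_s * fs)
    if len(ecg) < w:
        raise ValueError("signal shorter than one window")
    hop = max(round(w * (1 - overlap_frac)), 1)
    starts = range(0, len(ecg) - w + 1, hop)
    return [(s, ppg[s:s + w].copy(), ecg[s:s + w].copy()) for s in starts]


def fit_norm(ppg: np.ndarray, ecg: np.ndarray) -> NormParams:
    """Per-subject min-max statistics (fit on the training portion only)."""
    return NormParams(float(np.min(ppg)), float(np.max(ppg)),
                      float(np.min(ecg)), float(np.max(ecg)))


def _affine(x, lo, hi):
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def normalize(window: np.ndarray, lo: float, hi: float,
              with_count: bool = False):
    """Map [lo, hi] linearly onto [-1, 1]; out-of-range values are clipped."""
    if hi <= lo:
        raise ValueError("degenerate normalization range")
    y = _affine(np.asarray(window, dtype=float), lo, hi)
    n_clip = int(np.sum((y < -1) | (y > 1)))
    if n_clip:
        log.warning("normalize: clipped %d samples outside the fitted range",
                    n_clip)
    y = np.clip(y, -1.0, 1.0)
    return (y, n_clip) if with_count else y


def denormalize(window: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Inverse of :func:`normalize` (exact for unclipped samples)."""
    if hi <= lo:
        raise ValueError("degenerate normalization range")
    return (np.asarray(window, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


# ---------------------------------------------------------------------------
# whole-record pipeline
# ---------------------------------------------------------------------------

def preprocess_record(record: SignalRecord, cfg: PreprocessConfig,
                      norm: NormParams | None = None):
    """align → resample → filter → median → segment → normalize.

    Returns ``(segments, norm_params, lag)``.  When ``norm`` is given (e.g.
    train-fitted parameters applied at test time) it is reused instead of
    refitted.
    """
    aligned, lag = align_pair(record)
    ecg = resample(aligned.ecg, record.ecg_fs, cfg.target_fs)
    ppg = resample(aligned.ppg, record.ppg_fs, cfg.target_fs)
    n = min(len(ecg), len(ppg))
    ecg, ppg = ecg[:n], ppg[:n]
    ecg = median_despike(filter_ecg(ecg, cfg.target_fs, cfg.ecg_band),
                         cfg.median_kernel)
    ppg = median_despike(filter_ppg(ppg, cfg.target_fs, cfg.ppg_band),
                         cfg.median_kernel)
    if norm is None:
        n_train = int(len(ecg) * cfg.train_frac)
        norm = fit_norm(ppg[:n_train], ecg[:n_train])
    pairs = []
    for start, pw, ew in segment(ecg, ppg, cfg.target_fs, cfg.window_s,
                                 cfg.overlap_frac):
        pairs.append(SegmentPair(
            subject_id=record.subject_id,
            p=normalize(pw, norm.p_min, norm.p_max),
            e=normalize(ew, norm.e_min, norm.e_max),
            window_s=cfg.window_s, fs=cfg.target_fs,
            start_time=start / cfg.target_fs, norm_params=norm))
    return pairs, norm, lag


def preprocess_cohort(records, cfg: PreprocessConfig):
    """Run the full chain per subject; returns a flat list of SegmentPairs."""
    out = []
    for rec in records:
        pairs, _, _ = preprocess_record(rec, cfg)
        out.extend(pairs)
    return out


# ---------------------------------------------------------------------------
# archive container (single .npz per cohort + JSON manifest of the config)
# ---------------------------------------------------------------------------

def save_segments(path, pairs: list[SegmentPair], cfg: PreprocessConfig):
    np.savez(
        path,
        p=np.stack([sp.p for sp in pairs]),
        e=np.stack([sp.e for sp in pairs]),
        subject_id=np.array([sp.subject_id for sp in pairs]),
        start_time=np.array([sp.start_time for sp in pairs]),
        norm=np.array([[sp.norm_params.p_min, sp.norm_params.p_max,
                        sp.norm_params.e_min, sp.norm_params.e_max]
                       for sp in pairs]),
        manifest=np.frombuffer(json.dumps({
            "target_fs": cfg.target_fs, "window_s": cfg.window_s,
            "overlap_frac": cfg.overlap_frac,
            "ecg_band": list(cfg.ecg_band), "ppg_band": list(cfg.ppg_band),
            "median_kernel": cfg.median_kernel,
        }).encode(), dtype=np.uint8),
    )


def load_segments(path):
    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"]).decode())
        cfg = PreprocessConfig(
            target_fs=manifest["target_fs"],
            ecg_band=tuple(manifest["ecg_band"]),
            ppg_band=tuple(manifest["ppg_band"]),
            median_kernel=manifest["median_kernel"],
            window_s=manifest["window_s"],
            overlap_frac=manifest["overlap_frac"])
        pairs = []
        for i in range(len(z["p"])):
            nm = z["norm"][i]
            pairs.append(SegmentPair(
                subject_id=str(z["subject_id"][i]), p=z["p"][i], e=z["e"][i],
                window_s=cfg.window_s, fs=cfg.target_fs,
                start_time=float(z["start_time"][i]),
                norm_params=NormParams(*nm)))
    return pairs, cfg
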