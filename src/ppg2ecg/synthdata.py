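"""Synthetic paired PPG/ECG cohorts with ground-truth R peaks.

The generator emulates the structure of wearable recordings: single-lead ECG
sampled at 130 Hz with P–QRS–T morphology built from per-beat Gaussian bumps,
and a single-channel PPG at 64 Hz whose systolic peak trails each R peak by a
subject-specific pulse-arrival lag, with an optional dicrotic notch.  Motion
artifacts (baseline drift, transient spikes, slow amplitude modulation) can be
injected at a controllable level.  Everything is a pure function of the
subject profile and seed, so downstream stages can be tested bit-reproducibly
without any external dataset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

ECG_FS_DEFAULT = 130.0
PPG_FS_DEFAULT = 64.0

# Per-beat wave placement (seconds relative to the R peak) and widths.
# Amplitudes of P/R/T come from the subject profile; Q and S scale with R.
_WAVE_OFFSETS = {"P": -0.16, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.26}
_WAVE_WIDTHS = {"P": 0.025, "Q": 0.012, "R": 0.011, "S": 0.013, "T": 0.045}
_Q_FRAC = -0.12
_S_FRAC = -0.22


@dataclass(frozen=True)
class SubjectProfile:
    """Physiological parameters of one simulated subject."""

    subject_id: str
    mean_hr: float = 70.0          # beats per minute
    hrv_sd: float = 0.04           # SD of RR intervals, seconds
    ecg_amplitudes: tuple = (0.15, 1.1, 0.3)   # P, R, T peak heights, mV
    ppg_lag: float = 0.25          # pulse-arrival delay of systolic peak, s
    artifact_level: float = 0.0    # dimensionless, [0, 1]
    seed: int = 0

    def __post_init__(self):
        if not (30.0 <= self.mean_hr <= 220.0):
            raise ValueError(f"mean_hr {self.mean_hr} outside [30, 220] bpm")
        if self.hrv_sd < 0:
            raise ValueError("hrv_sd must be >= 0")
        if self.ppg_lag < 0:
            raise ValueError("ppg_lag must be >= 0")
        if not (0.0 <= self.artifact_level <= 1.0):
            raise ValueError("artifact_level must lie in [0, 1]")


@dataclass
class SignalRecord:
    """One subject's raw paired traces plus synthetic ground truth."""

    subject_id: str
    ecg: np.ndarray                # mV
    ecg_fs: float
    ppg: np.ndarray                # arbitrary units
    ppg_fs: float
    r_peak_times: np.ndarray       # seconds, ground truth
    duration: float

    def __post_init__(self):
        if len(self.ecg) != round(self.duration * self.ecg_fs):
            raise ValueError("ECG length inconsistent with duration and fs")
        if len(self.ppg) != round(self.duration * self.ppg_fs):
            raise ValueError("PPG length inconsistent with duration and fs")
        if np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")


def _draw_beat_times(profile: SubjectProfile, duration: float,
                     rng: np.random.Generator) -> np.ndarray:
    """i.i.d. truncated-normal RR intervals with the profile's mean and SD."""
    mean_rr = 60.0 / profile.mean_hr
    times = [0.5 * mean_rr]
    while times[-1] < duration + mean_rr:
        rr = rng.normal(mean_rr, profile.hrv_sd)
        # truncate away non-physiological draws
        while rr < 0.25 * mean_rr:
            rr = rng.normal(mean_rr, profile.hrv_sd)
        times.append(times[-1] + rr)
    t = np.asarray(times)
    return t[t < duration - 0.05]


def generate_ecg_components(profile: SubjectProfile, duration: float,
                            fs: float = ECG_FS_DEFAULT):
    """ECG as a sum of per-beat Gaussian bumps, returned with its QRS-free part.

    Returns ``(ecg, qrs_free, r_peaks)``.  R-peak times are snapped to the
    sampling grid so the discrete maximum coincides exactly with the reported
    peak time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    rng = np.random.default_rng(profile.seed)
    beats = _draw_beat_times(profile, duration, rng)
    beats = np.round(beats * fs) / fs              # snap R to the grid
    beats = beats[(beats > 0.3) & (beats < duration - 0.3)]
    n = round(duration * fs)
    t = np.arange(n) / fs
    amp_p, amp_r, amp_t = profile.ecg_amplitudes
    waves = {
        "P": amp_p, "Q": _Q_FRAC * amp_r, "R": amp_r,
        "S": _S_FRAC * amp_r, "T": amp_t,
    }
    full = np.zeros(n)
    qrs_free = np.zeros(n)
    rr_prev = np.diff(beats, prepend=beats[0] - 60.0 / profile.mean_hr)
    for tr, rr in zip(beats, rr_prev):
        # compress wave placement for short cycles so beats never overlap
        c = float(np.clip(rr / 0.8, 0.45, 1.0))
        for w, amp in waves.items():
            mu = tr + _WAVE_OFFSETS[w] * c
            sig = _WAVE_WIDTHS[w] * (c if w in ("P", "T") else 1.0)
            lo = max(0, int((mu - 5 * sig) * fs))
            hi = min(n, int((mu + 5 * sig) * fs) + 1)
            bump = amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sig) ** 2)
            full[lo:hi] += bump
            if w in ("P", "T"):
                qrs_free[lo:hi] += bump
    return full, qrs_free, beats


def generate_ecg(profile: SubjectProfile, duration: float,
                 fs: float = ECG_FS_DEFAULT):
    """Clean synthetic ECG trace and its ground-truth R-peak times."""
    ecg, _, r_peaks = generate_ecg_components(profile, duration, fs)
    return ecg, r_peaks


def _pulse_kernel(u: np.ndarray) -> np.ndarray:
    """Asymmetric systolic pulse: fast rise, slower fall, unit peak at u=0."""
    rise, fall = 0.07, 0.16
    return np.where(u < 0, np.exp(-0.5 * (u / rise) ** 2),
                    np.exp(-0.5 * (u / fall) ** 2))


def generate_ppg_from_ecg(r_peaks: np.ndarray, duration: float,
                          fs: float = PPG_FS_DEFAULT, lag: float = 0.25,
                          notch_depth: float = 0.35) -> np.ndarray:
    """PPG with one systolic pulse per beat, peaking ``lag`` seconds after R.

    The dicrotic notch is a scaled, delayed copy of the systolic kernel.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size == 0 or np.any(np.diff(r_peaks) <= 0):
        raise ValueError("r_peaks must be non-empty and strictly increasing")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    n = round(duration * fs)
    t = np.arange(n) / fs
    out = np.full(n, 0.05)                        # small positive baseline
    for tr in r_peaks:
        centre = tr + lag
        lo = max(0, int((centre - 0.5) * fs))
        hi = min(n, int((centre + 0.9) * fs) + 1)
        u = t[lo:hi] - centre
        out[lo:hi] += _pulse_kernel(u) + notch_depth * 0.5 * _pulse_kernel(u - 0.30)
    return out


def add_motion_artifacts(signal: np.ndarray, fs: float, level: float,
                         seed: int) -> np.ndarray:
    """Band-limited drift + transient spikes + slow amplitude modulation.

    ``level=0`` returns the input bit-identically; all components scale
    linearly with ``level`` relative to the signal's own standard deviation.
    """
    if not (0.0 <= level <= 1.0):
        raise ValueError("level must lie in [0, 1]")
    x = np.asarray(signal, dtype=float)
    if level == 0.0:
        return x.copy()
    rng = np.random.default_rng(seed)
    n = len(x)
    scale = np.std(x) if np.std(x) > 0 else 1.0

    # 0.1-1 Hz baseline drift from filtered white noise
    white = rng.normal(size=n)
    b, a = butter(2, [0.1 / (fs / 2), min(1.0 / (fs / 2), 0.99)], btype="band")
    drift = filtfilt(b, a, white)
    drift *= level * 2.0 * scale / max(np.std(drift), 1e-12)

    # Poisson-arriving transient spikes (short Gaussian bumps)
    spikes = np.zeros(n)
    n_spikes = rng.poisson(level * 0.25 * n / fs)
    width = max(int(0.03 * fs), 1)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    for _ in range(n_spikes):
        pos = rng.integers(n)
        amp = rng.choice([-1.0, 1.0]) * level * 5.0 * scale * rng.uniform(0.5, 1.0)
        lo = max(0, pos - 3 * width)
        hi = min(n, pos + 3 * width + 1)
        spikes[lo:hi] += amp * kernel[(lo - pos + 3 * width):(hi - pos + 3 * width)]

    # slow multiplicative amplitude modulation (~0.05-0.2 Hz)
    phase = rng.uniform(0, 2 * np.pi)
    f_mod = rng.uniform(0.05, 0.2)
    am = 1.0 + level * 0.5 * np.sin(2 * np.pi * f_mod * np.arange(n) / fs + phase)

    return x * am + drift + spikes


def make_subject_profile(subject_id: str, rng: np.random.Generator,
                         artifact_level: float = 0.0) -> SubjectProfile:
    """Draw a subject from realistic resting ranges (HR 55-95 bpm etc.)."""
    return SubjectProfile(
        subject_id=subject_id,
        mean_hr=float(rng.uniform(55, 95)),
        hrv_sd=float(rng.uniform(0.02, 0.07)),
        ecg_amplitudes=(
            float(rng.uniform(0.1, 0.2)),
            float(rng.uniform(0.8, 1.4)),
            float(rng.uniform(0.2, 0.4)),
        ),
        ppg_lag=float(rng.uniform(0.15, 0.35)),
        artifact_level=float(artifact_level),
        seed=int(rng.integers(2**31)),
    )


def make_record(profile: SubjectProfile, duration: float,
                ecg_fs: float = ECG_FS_DEFAULT,
                ppg_fs: float = PPG_FS_DEFAULT) -> SignalRecord:
    ecg, r_peaks = generate_ecg(profile, duration, ecg_fs)
    ppg = generate_ppg_from_ecg(r_peaks, duration, ppg_fs, lag=profile.ppg_lag)
    if profile.artifact_level > 0:
        ppg = add_motion_artifacts(ppg, ppg_fs, profile.artifact_level,
                                   seed=profile.seed + 1)
        ecg = add_motion_artifacts(ecg, ecg_fs, 0.3 * profile.artifact_level,
                                   seed=profile.seed + 2)
    return SignalRecord(profile.subject_id, ecg, ecg_fs, ppg, ppg_fs,
                        r_peaks, duration)


def make_cohort(n_subjects: int, duration: float, seed: int,
                ecg_fs: float = ECG_FS_DEFAULT, ppg_fs: float = PPG_FS_DEFAULT,
                artifact_level: float = 0.0) -> list[SignalRecord]:
    """Generate ``n_subjects`` independent records with distinct profiles."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        profile = make_subject_profile(f"S{i + 1:03d}", rng,
                                       artifact_level=artifact_level)
        records.append(make_record(profile, duration, ecg_fs, ppg_fs))
    return records


# ---------------------------------------------------------------------------
# on-disk layout: one directory per subject with CSV traces + JSON sidecar
# ---------------------------------------------------------------------------

def _write_trace(path: Path, fs: float, values: np.ndarray):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for i, v in enumerate(values):
            w.writerow([f"{i / fs:.6f}", f"{v:.6f}"])


def write_cohort(records: list[SignalRecord], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        d = out_dir / rec.subject_id
        d.mkdir(exist_ok=True)
        _write_trace(d / "ecg.csv", rec.ecg_fs, rec.ecg)
        _write_trace(d / "ppg.csv", rec.ppg_fs, rec.ppg)
        with open(d / "r_peaks.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["r_peak_s"])
            for tr in rec.r_peak_times:
                w.writerow([f"{tr:.6f}"])
        meta = {"subject_id": rec.subject_id, "ecg_fs": rec.ecg_fs,
                "ppg_fs": rec.ppg_fs, "duration": rec.duration}
        (d / "meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(in_dir) -> list[SignalRecord]:
    in_dir = Path(in_dir)
    records = []
    for d in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        meta = json.loads((d / "meta.json").read_text())
        ecg = np.loadtxt(d / "ecg.csv", delimiter=",", skiprows=1, usecols=1)
        ppg = np.loadtxt(d / "ppg.csv", delimiter=",", skiprows=1, usecols=1)
        r_peaks = np.loadtxt(d / "r_peaks.csv", delimiter=",", skiprows=1, ndmin=1)
        records.append(SignalRecord(meta["subject_id"], ecg, meta["ecg_fs"],
                                    ppg, meta["ppg_fs"], r_peaks,
                                    meta["duration"]))
    return records
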