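"""Self-supervised pretext transformations for ECG windows.

Six operators — additive noise at a target SNR, amplitude scaling, temporal
inversion, segment permutation, negation and segment-wise time warping —
turn each clean window into a pseudo-labeled example for multi-task
pre-training of the critic.  Parameter ranges follow the pretext-task
recipe: SNR α ∈ [2, 45] dB, scale b ∈ [0.1, 10], segment count m ∈ [2, 40],
stretch factor k ∈ [1.05, 4].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRANSFORM_KINDS = ("noise", "scale", "invert", "permute", "negate", "timewarp")

DEFAULT_RANGES = {
    "alpha": (2.0, 45.0),
    "b": (0.1, 10.0),
    "m": (2, 40),
    "k": (1.05, 4.0),
}


@dataclass(frozen=True)
class TransformSpec:
    """Identity of one transformation plus its sampled parameters."""

    kind: str
    alpha: float | None = None     # dB SNR (noise)
    b: float | None = None         # scale factor
    m: int | None = None           # segment count (permute / timewarp)
    k: float | None = None         # stretch factor (timewarp)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS + ("original",):
            raise ValueError(f"unknown transformation kind {self.kind!r}")
        if self.alpha is not None and not (2.0 <= self.alpha <= 45.0):
            raise ValueError("alpha outside [2, 45] dB")
        if self.b is not None and not (0.1 <= self.b <= 10.0):
            raise ValueError("b outside [0.1, 10]")
        if self.m is not None and not (2 <= self.m <= 40):
            raise ValueError("m outside [2, 40]")
        if self.k is not None and not (1.05 <= self.k <= 4.0):
            raise ValueError("k outside [1.05, 4]")


@dataclass
class PretextExample:
    """Fixed-length window plus a six-way indicator of the applied transform."""

    signal: np.ndarray
    labels: np.ndarray             # shape (6,), all-zero means "original"

    def __post_init__(self):
        if self.labels.shape != (6,) or self.labels.sum() > 1:
            raise ValueError("labels must be a six-way indicator, at most one hot")


def add_noise(e: np.ndarray, alpha: float,
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Gaussian noise whose power follows E_Navg = 10^((E_Eavg − α)/10).

    Signal power E_Eavg enters in dB (10·log10 of mean squared amplitude);
    the resulting noise power is a linear variance.
    """
    e = np.asarray(e, dtype=float)
    p_sig = float(np.mean(e**2))
    if p_sig == 0:
        raise ValueError("SNR undefined for an all-zero signal")
    rng = np.random.default_rng(rng)
    e_avg_db = 10.0 * np.log10(p_sig)
    noise_power = 10.0 ** ((e_avg_db - alpha) / 10.0)
    return e + rng.normal(0.0, np.sqrt(noise_power), size=e.shape)


def scale(e: np.ndarray, b: float) -> np.ndarray:
    if b <= 0:
        raise ValueError("scale factor must be positive")
    return np.asarray(e, dtype=float) * b


def time_invert(e: np.ndarray) -> np.ndarray:
    return np.asarray(e)[::-1].copy()


def permute(e: np.ndarray, m: int,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Split into ``m`` near-equal contiguous parts and shuffle (never identity)."""
    e = np.asarray(e)
    if m < 2:
        raise ValueError("m must be >= 2")
    if m > len(e):
        raise ValueError("m exceeds the signal length")
    rng = np.random.default_rng(rng)
    parts = np.array_split(e, m)
    order = rng.permutation(m)
    while np.array_equal(order, np.arange(m)):
        order = rng.permutation(m)
    return np.concatenate([parts[i] for i in order])


def negate(e: np.ndarray) -> np.ndarray:
    return -np.asarray(e)


def time_warp(e: np.ndarray, m: int, k: float,
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Stretch a random half of ``m`` segments by ``k``, compress the rest by
    1/k, then clip or zero-pad back to the original length."""
    e = np.asarray(e, dtype=float)
    if m < 2:
        raise ValueError("m must be >= 2")
    if k < 1.0:
        raise ValueError("stretch factor must be >= 1")
    rng = np.random.default_rng(rng)
    parts = np.array_split(e, m)
    stretch_idx = set(rng.permutation(m)[: m // 2].tolist())
    warped = []
    for i, part in enumerate(parts):
        factor = k if i in stretch_idx else 1.0 / k
        n_new = max(round(len(part) * factor), 1)
        pos_old = np.arange(len(part))
        pos_new = np.linspace(0, len(part) - 1, n_new)
        warped.append(np.interp(pos_new, pos_old, part))
    out = np.concatenate(warped)
    n = len(e)
    if len(out) >= n:
        return out[:n]
    return np.pad(out, (0, n - len(out)))


def apply_transform(e: np.ndarray, spec: TransformSpec) -> np.ndarray:
    if spec.kind == "original":
        return np.asarray(e, dtype=float).copy()
    if spec.kind == "noise":
        return add_noise(e, spec.alpha, spec.seed)
    if spec.kind == "scale":
        return scale(e, spec.b)
    if spec.kind == "invert":
        return time_invert(e)
    if spec.kind == "permute":
        return permute(e, spec.m, spec.seed)
    if spec.kind == "negate":
        return negate(e)
    return time_warp(e, spec.m, spec.k, spec.seed)


def draw_spec(kind: str, rng: np.random.Generator,
              ranges: dict | None = None) -> TransformSpec:
    r = dict(DEFAULT_RANGES, **(ranges or {}))
    seed = int(rng.integers(2**31))
    if kind == "noise":
        return TransformSpec(kind, alpha=float(rng.uniform(*r["alpha"])), seed=seed)
    if kind == "scale":
        return TransformSpec(kind, b=float(rng.uniform(*r["b"])), seed=seed)
    if kind in ("invert", "negate", "original"):
        return TransformSpec(kind, seed=seed)
    if kind == "permute":
        return TransformSpec(kind, m=int(rng.integers(r["m"][0], r["m"][1] + 1)),
                             seed=seed)
    return TransformSpec(kind, m=int(rng.integers(r["m"][0], r["m"][1] + 1)),
                         k=float(rng.uniform(*r["k"])), seed=seed)


def build_pretext_dataset(segments, seed: int,
                          ranges: dict | None = None) -> list[PretextExample]:
    """Each input window yields the original plus its six transformed copies."""
    segments = list(segments)
    if not segments:
        raise ValueError("empty segment collection")
    rng = np.random.default_rng(seed)
    examples = []
    for idx, seg in enumerate(segments):
        seg = np.asarray(seg, dtype=float)
        examples.append(PretextExample(seg.copy(), np.zeros(6)))
        for j, kind in enumerate(TRANSFORM_KINDS):
            spec = draw_spec(kind, rng, ranges)
            try:
                sig = apply_transform(seg, spec)
            except ValueError as err:
                raise ValueError(f"segment {idx}: {err}") from err
            labels = np.zeros(6)
            labels[j] = 1.0
            examples.append(PretextExample(sig, labels))
    return examples
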