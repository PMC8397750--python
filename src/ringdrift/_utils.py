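"""Shared numerical helpers (seed derivation, correlations, circular arithmetic)."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stage-specific 31-bit seed from a master seed and a label.

    Stable across runs and platforms (CRC32 of the label mixed with the master
    seed through ``SeedSequence``).
    """
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, label))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def pairwise_mean_corr(vectors: np.ndarray) -> float:
    """Mean Pearson correlation over unordered row pairs; constant rows skipped."""
    n = vectors.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            c = pearson(vectors[i], vectors[j])
            if np.isfinite(c):
                vals.append(c)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def circular_diff(a: np.ndarray, b: np.ndarray, period: float = 1.0) -> np.ndarray:
    """Absolute circular difference on a circle of given period, in [0, period/2]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def fit_gaussian(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gaussian fit: (mean, SD with 1/n normalization)."""
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    return float(x.mean()), float(x.std(ddof=0))
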