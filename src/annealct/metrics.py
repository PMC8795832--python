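"""Reconstruction quality measures: PSNR, EuE and WPSNR.

Images are absorption-coefficient grids in [0, 1], so the PSNR peak is
L = 1.  EuE is the relative Euclidean error ||ref - est|| / ||ref||.
WPSNR weights squared errors by a noise-visibility factor
``w = 1 / (1 + var_local / var_global)`` computed from a 3x3
local-variance map of the reference, so errors in flat regions (where
the eye notices them) count more than errors in textured ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QualityReport",
    "psnr",
    "euclidean_error",
    "wpsnr",
    "nvf_weights",
    "quality_report",
]


def _pair(ref, est):
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape or ref.ndim != 2:
        raise ValueError("reference and estimate must be equal-shape 2-D arrays")
    return ref, est


@dataclass(frozen=True)
class QualityReport:
    psnr: float
    eue: float
    wpsnr: float


def psnr(ref: np.ndarray, est: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; identical images report inf."""
    ref, est = _pair(ref, est)
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def euclidean_error(ref: np.ndarray, est: np.ndarray) -> float:
    """Relative Euclidean error ||ref - est||_2 / ||ref||_2."""
    ref, est = _pair(ref, est)
    norm = float(np.linalg.norm(ref))
    if norm == 0.0:
        raise ValueError("EuE is undefined for an all-zero reference")
    return float(np.linalg.norm(ref - est)) / norm


def _local_mean(img: np.ndarray, radius: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-window local sums / counts via an integral image."""
    n0, n1 = img.shape
    integral = np.zeros((n0 + 1, n1 + 1))
    integral[1:, 1:] = img.cumsum(0).cumsum(1)
    r0 = np.clip(np.arange(n0) - radius, 0, None)
    r1 = np.clip(np.arange(n0) + radius + 1, None, n0)
    c0 = np.clip(np.arange(n1) - radius, 0, None)
    c1 = np.clip(np.arange(n1) + radius + 1, None, n1)
    sums = (
        integral[np.ix_(r1, c1)]
        - integral[np.ix_(r0, c1)]
        - integral[np.ix_(r1, c0)]
        + integral[np.ix_(r0, c0)]
    )
    counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return sums, counts


def local_variance(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Population variance over the (border-clipped) 3x3 neighbourhood."""
    img = np.asarray(img, dtype=float)
    s, cnt = _local_mean(img, radius)
    s2, _ = _local_mean(img**2, radius)
    mean = s / cnt
    return np.maximum(s2 / cnt - mean**2, 0.0)


def nvf_weights(ref: np.ndarray) -> np.ndarray:
    """Noise-visibility weights w = 1 / (1 + var_local / var_global).

    A constant reference (zero global variance) yields uniform weights,
    so WPSNR then coincides with PSNR.
    """
    ref = np.asarray(ref, dtype=float)
    if ref.max() == ref.min():  # constant reference: uniform weights
        return np.ones_like(ref)
    return 1.0 / (1.0 + local_variance(ref) / float(ref.var()))


def wpsnr(ref: np.ndarray, est: np.ndarray) -> float:
    """Weighted PSNR in dB using noise-visibility weights of ``ref``."""
    ref, est = _pair(ref, est)
    w = nvf_weights(ref)
    wmse = float((w * (ref - est) ** 2).sum() / w.sum())
    if wmse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / wmse)


def quality_report(ref: np.ndarray, est: np.ndarray) -> QualityReport:
    return QualityReport(
        psnr=psnr(ref, est),
        eue=euclidean_error(ref, est),
        wpsnr=wpsnr(ref, est),
    )
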