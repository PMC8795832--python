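"""Deterministic FBP and ART baselines for the sparse-view comparison.

FBP ramp-filters each projection in the frequency domain and smears it
back over the grid with linear interpolation; the displayed image is
min-max normalized and clipped to [0, 1].  ART is classic unregularized
Kaczmarz: the nearest-bin forward model defines one linear equation per
(bin, view) pair, processed cyclically with a relaxation factor and a
non-negativity projection after each sweep.
"""

from __future__ import annotations

import numpy as np

from .forward_model import Sinogram, bin_map
from .wavelet_init import back_project, ramp_filter

__all__ = [
    "filtered_back_projection",
    "fbp_reconstruct",
    "art_reconstruct",
]


def filtered_back_projection(sino: Sinogram, side: int) -> np.ndarray:
    """Raw (linear, unclipped) ramp-filtered back-projection."""
    if sino.values.size == 0:
        raise ValueError("empty sinogram")
    filtered = np.empty_like(sino.values)
    for j in range(sino.n_views):
        filtered[:, j] = ramp_filter(sino.values[:, j])
    return back_project(filtered, sino.geometry.angles, side)


def fbp_reconstruct(sino: Sinogram, side: int, normalize: bool = True) -> np.ndarray:
    """FBP estimate in [0, 1]; a zero sinogram yields a zero image."""
    raw = filtered_back_projection(sino, side)
    if not normalize:
        return np.clip(raw, 0.0, 1.0)
    span = raw.max() - raw.min()
    if span == 0.0:
        return np.zeros_like(raw)
    return np.clip((raw - raw.min()) / span, 0.0, 1.0)


def art_reconstruct(
    sino: Sinogram,
    side: int,
    sweeps: int = 20,
    relaxation: float = 0.25,
) -> np.ndarray:
    """Kaczmarz row-action solution of the nearest-bin projection system."""
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if not 0.0 < relaxation <= 1.0:
        raise ValueError("relaxation must lie in (0, 1]")
    bm = bin_map(side, sino.geometry).reshape(side * side, sino.n_views)
    # rows[(j, b)] = pixels contributing to bin b of view j
    rows: list[tuple[int, int, np.ndarray]] = []
    for j in range(sino.n_views):
        order = np.argsort(bm[:, j], kind="stable")
        sorted_bins = bm[order, j]
        boundaries = np.flatnonzero(np.diff(sorted_bins)) + 1
        for group in np.split(order, boundaries):
            rows.append((j, int(bm[group[0], j]), group))
    f = np.zeros(side * side)
    p = sino.values
    for _ in range(sweeps):
        for j, b, idx in rows:
            residual = p[b, j] - f[idx].sum()
            f[idx] += relaxation * residual / idx.size
        np.clip(f, 0.0, None, out=f)  # non-negativity after each sweep
    return f.reshape(side, side)
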