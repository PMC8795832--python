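"""Seeded generation of lung-like test phantoms.

A 2-D slice analogue of a fractal bronchial-tree lung phantom: an
elliptical thorax (soft tissue, ~0.85) encloses two darker lung fields
(~0.15) filled with a recursive, bifurcating tree of brighter vessel /
airway segments (~0.7) whose length and width decay geometrically with
depth and whose branch angles carry seeded jitter.  Optional peripheral
ground-glass-opacity (GGO) blobs -- seeded Gaussian bumps of +0.3 --
emulate the hazy peripheral densities characteristic of COVID-19 chest
CT.  Absorption coefficients are dimensionless in [0, 1] and quantized
to a uniform intensity lattice.

The same spec always yields a bit-identical phantom; geometry is drawn
in normalized [-1, 1]^2 coordinates on a supersampled canvas and
block-averaged down so sub-pixel seed jitter survives at small sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidSpecError",
    "PhantomSpec",
    "generate_lung_phantom",
    "lung_field_mask",
    "downsample",
    "quantize",
]

# normalized-coordinate anatomy: (cx, cy, semi_x, semi_y)
_BODY = (0.0, 0.0, 0.92, 0.75)
_LUNGS = ((-0.38, -0.02, 0.26, 0.50), (0.38, -0.02, 0.26, 0.50))
_BACKGROUND = 0.0
_BODY_VALUE = 0.85
_LUNG_VALUE = 0.15
_BRANCH_VALUE = 0.70
_DECAY = 0.7          # per-level length/width decay of the bronchial tree
_BRANCH_ANGLE = math.radians(28.0)
_JITTER_STD = math.radians(8.0)
_GGO_AMPLITUDE = 0.30
_SUPERSAMPLE = 4


class InvalidSpecError(ValueError):
    """Raised for phantom specifications that violate their contract."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic lung phantom.

    ``side`` is the output grid size (any n >= 2), ``branching_depth``
    the number of bifurcation generations, ``ggo_count`` the number of
    peripheral ground-glass blobs and ``intensity_levels`` the size of
    the uniform quantization lattice in [0, 1].
    """

    side: int
    seed: int = 0
    branching_depth: int = 4
    ggo_count: int = 0
    intensity_levels: int = 256

    def __post_init__(self) -> None:
        if int(self.side) < 2:
            raise InvalidSpecError("phantom side must be at least 2")
        if int(self.branching_depth) < 0:
            raise InvalidSpecError("branching_depth must be >= 0")
        if int(self.ggo_count) < 0:
            raise InvalidSpecError("ggo_count must be >= 0")
        if int(self.intensity_levels) < 2:
            raise InvalidSpecError("intensity_levels must be >= 2")


def quantize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Snap values in [0, 1] to the uniform lattice k / (levels - 1)."""
    return np.round(np.asarray(img, dtype=float) * (levels - 1)) / (levels - 1)


def _grid(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in [-1, 1]^2 (u right, v up)."""
    c = (np.arange(side) + 0.5) / side * 2.0 - 1.0
    u = np.broadcast_to(c, (side, side))
    v = np.broadcast_to(-c[:, None], (side, side))
    return u, v


def _inside(u, v, ellipse) -> np.ndarray:
    cx, cy, a, b = ellipse
    return ((u - cx) / a) ** 2 + ((v - cy) / b) ** 2 <= 1.0


def _capsule(u, v, p0, p1, width) -> np.ndarray:
    """Mask of points within ``width`` of segment p0-p1."""
    du, dv = p1[0] - p0[0], p1[1] - p0[1]
    norm2 = du * du + dv * dv
    if norm2 == 0.0:
        d2 = (u - p0[0]) ** 2 + (v - p0[1]) ** 2
    else:
        s = np.clip(((u - p0[0]) * du + (v - p0[1]) * dv) / norm2, 0.0, 1.0)
        d2 = (u - p0[0] - s * du) ** 2 + (v - p0[1] - s * dv) ** 2
    return d2 <= width * width


def _grow_tree(u, v, mask_lung, rng, start, heading, length, width, depth):
    """Recursively rasterize a bifurcating tree; returns a bool mask."""
    tree = np.zeros_like(u, dtype=bool)
    end = (start[0] + length * math.cos(heading), start[1] + length * math.sin(heading))
    tree |= _capsule(u, v, start, end, width) & mask_lung
    if depth > 0:
        for sign, scale in ((-1.0, 1.0), (1.0, 0.85)):  # a large and a small sprout
            jitter = rng.normal(0.0, _JITTER_STD)
            child_heading = heading + sign * _BRANCH_ANGLE + jitter
            tree |= _grow_tree(
                u, v, mask_lung, rng, end, child_heading,
                length * _DECAY * scale, width * _DECAY, depth - 1,
            )
    return tree


def lung_field_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the two lung fields at ``spec.side`` resolution."""
    u, v = _grid(int(spec.side))
    mask = np.zeros_like(u, dtype=bool)
    for lung in _LUNGS:
        mask |= _inside(u, v, lung)
    return mask


def generate_lung_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom described by ``spec``; bit-identical per spec."""
    side = int(spec.side)
    rng = np.random.default_rng(int(spec.seed))
    hi = side * _SUPERSAMPLE
    u, v = _grid(hi)

    img = np.full((hi, hi), _BACKGROUND)
    img[_inside(u, v, _BODY)] = _BODY_VALUE
    lungs = np.zeros((hi, hi), dtype=bool)
    for lung in _LUNGS:
        lungs |= _inside(u, v, lung)
    img[lungs] = _LUNG_VALUE

    for cx, cy, a, b in _LUNGS:
        in_lung = _inside(u, v, (cx, cy, a, b))
        root = (cx, cy + 0.85 * b)
        tree = _grow_tree(
            u, v, in_lung, rng,
            start=root, heading=-math.pi / 2.0,
            length=0.5 * b, width=0.05,
            depth=int(spec.branching_depth),
        )
        img[tree] = _BRANCH_VALUE

    for i in range(int(spec.ggo_count)):
        cx, cy, a, b = _LUNGS[i % 2]
        phi = rng.uniform(0.0, 2.0 * math.pi)
        radial = rng.uniform(0.55, 0.90)  # peripheral placement
        gx = cx + a * radial * math.cos(phi)
        gy = cy + b * radial * math.sin(phi)
        sigma = rng.uniform(0.08, 0.15)
        bump = _GGO_AMPLITUDE * np.exp(
            -((u - gx) ** 2 + (v - gy) ** 2) / (2.0 * sigma**2)
        )
        img += np.where(lungs, bump, 0.0)

    img = downsample(np.clip(img, 0.0, 1.0), side)
    return quantize(img, int(spec.intensity_levels))


def downsample(img: np.ndarray, target_side: int) -> np.ndarray:
    """Block-mean reduction to ``target_side``; preserves the global mean."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be a square 2-D array")
    side = img.shape[0]
    if target_side < 1 or side % target_side != 0:
        raise ValueError(
            f"target side {target_side} must divide image side {side}"
        )
    f = side // target_side
    return img.reshape(target_side, f, target_side, f).mean(axis=(1, 3))
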