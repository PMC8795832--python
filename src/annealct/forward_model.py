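"""Discrete parallel-beam Radon forward model.

The scanner is parallel-beam: ``M`` view angles uniformly spaced over
``[0, pi)`` and a 1-D detector of ``t_b`` unit-width bins centred on the
image grid.  The forward projection of an image ``f(x, y)`` is the
line-integral map

    P_theta(t) = sum over pixels of f(x, y) for which the rotated offset
                 x cos(theta) + y sin(theta) rounds to detector bin t,

i.e. a binary-indicator (nearest-bin) projector: every pixel contributes
its full value to exactly one bin per view, so each view conserves the
total image mass.  Pixel centres are measured from the grid centre,
``x = col - (n-1)/2`` and ``y = (n-1)/2 - row``, and rounding is
half-up so that the half-integer coordinates of even-sided grids map to
distinct bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "ProjectionGeometry",
    "Sinogram",
    "default_n_bins",
    "bin_map",
    "radon_forward",
    "single_view",
]


class GeometryError(ValueError):
    """Raised when a projection geometry is inconsistent with an image."""


def default_n_bins(side: int) -> int:
    """Smallest odd integer >= sqrt(2) * side, so diagonals never clip."""
    n = int(np.ceil(np.sqrt(2.0) * side))
    return n if n % 2 == 1 else n + 1


@dataclass(frozen=True)
class ProjectionGeometry:
    """View angles and detector-bin layout of a parallel-beam scan.

    ``angles`` must be strictly increasing within ``[0, pi)``; bins have
    unit spacing and are centred on the grid centre.
    """

    angles: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if angles.ndim != 1 or angles.size == 0:
            raise GeometryError("angles must be a non-empty 1-D sequence")
        if np.any(angles < 0.0) or np.any(angles >= np.pi):
            raise GeometryError("view angles must lie in [0, pi)")
        if angles.size > 1 and np.any(np.diff(angles) <= 0):
            raise GeometryError("view angles must be strictly increasing")
        if int(self.n_bins) < 1:
            raise GeometryError("n_bins must be positive")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "n_bins", int(self.n_bins))

    @property
    def n_views(self) -> int:
        return self.angles.size

    @classmethod
    def uniform(
        cls, n_views: int, side: int | None = None, n_bins: int | None = None
    ) -> "ProjectionGeometry":
        """Geometry with ``n_views`` angles i*pi/M and a default detector.

        When ``n_bins`` is omitted, ``side`` must be given and the
        detector gets ``default_n_bins(side)`` bins.
        """
        if n_views < 1:
            raise GeometryError("need at least one view")
        if n_bins is None:
            if side is None:
                raise GeometryError("either side or n_bins is required")
            n_bins = default_n_bins(side)
        angles = np.arange(n_views) * np.pi / n_views
        return cls(angles=angles, n_bins=n_bins)


@dataclass
class Sinogram:
    """A ``t_b x M`` matrix of line-integral projections with its geometry."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise GeometryError("sinogram values must be 2-D (bins x views)")
        if values.shape != (self.geometry.n_bins, self.geometry.n_views):
            raise GeometryError(
                f"sinogram shape {values.shape} does not match geometry "
                f"({self.geometry.n_bins} bins x {self.geometry.n_views} views)"
            )
        if not np.all(np.isfinite(values)):
            raise GeometryError("sinogram values must be finite")
        self.values = values

    @property
    def n_views(self) -> int:
        return self.geometry.n_views

    @property
    def n_bins(self) -> int:
        return self.geometry.n_bins


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be a square 2-D array")
    return img


def bin_map(side: int, geom: ProjectionGeometry) -> np.ndarray:
    """Per-view detector bin index of every pixel, shape (side, side, M).

    Raises :class:`GeometryError` when any pixel would fall outside the
    detector (``n_bins`` too small for this grid).
    """
    rows, cols = np.indices((side, side))
    x = cols - (side - 1) / 2.0
    y = (side - 1) / 2.0 - rows
    t = (
        x[..., None] * np.cos(geom.angles)
        + y[..., None] * np.sin(geom.angles)
    )
    # half-up rounding implements the binary line indicator while keeping
    # half-integer offsets of even grids in distinct bins; offsets are
    # snapped to 1e-9 first so float noise in cos/sin cannot flip a tie
    b = np.floor(np.round(t, 9) + 0.5).astype(np.int64) + (geom.n_bins - 1) // 2
    if b.min() < 0 or b.max() >= geom.n_bins:
        raise GeometryError(
            f"detector with {geom.n_bins} bins is too small for a "
            f"{side}x{side} grid; need at least {default_n_bins(side)}"
        )
    return b


def radon_forward(img: np.ndarray, geom: ProjectionGeometry) -> Sinogram:
    """Nearest-bin forward projection of ``img`` under ``geom``."""
    img = _validate_image(img)
    side = img.shape[0]
    bm = bin_map(side, geom)
    flat = img.ravel()
    values = np.empty((geom.n_bins, geom.n_views))
    for j in range(geom.n_views):
        values[:, j] = np.bincount(
            bm[..., j].ravel(), weights=flat, minlength=geom.n_bins
        )
    return Sinogram(values=values, geometry=geom)


def single_view(img: np.ndarray, theta: float, geom: ProjectionGeometry) -> np.ndarray:
    """One projection vector ``P_theta``, consistent with ``radon_forward``."""
    if not 0.0 <= theta < np.pi:
        raise GeometryError("theta must lie in [0, pi)")
    img = _validate_image(img)
    side = img.shape[0]
    rows, cols = np.indices((side, side))
    x = cols - (side - 1) / 2.0
    y = (side - 1) / 2.0 - rows
    t = x * np.cos(theta) + y * np.sin(theta)
    b = np.floor(np.round(t, 9) + 0.5).astype(np.int64) + (geom.n_bins - 1) // 2
    if b.min() < 0 or b.max() >= geom.n_bins:
        raise GeometryError("detector too small for this grid")
    return np.bincount(b.ravel(), weights=img.ravel(), minlength=geom.n_bins)
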