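"""File formats: binary 8-bit PGM images, CSV images, sinogram text.

Sinograms are stored as a comma-delimited bins-x-views matrix preceded
by a header line ``# angles_deg: a1,a2,...``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .forward_model import ProjectionGeometry, Sinogram

__all__ = [
    "write_pgm",
    "read_pgm",
    "write_image_csv",
    "read_image_csv",
    "write_sinogram",
    "read_sinogram",
]


def write_pgm(path, img: np.ndarray) -> None:
    """8-bit binary (P5) greymap of a [0, 1] image."""
    arr = np.round(np.clip(np.asarray(img, dtype=float), 0.0, 1.0) * 255.0)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path), format="PPM")


def read_pgm(path) -> np.ndarray:
    """Greymap back to floats in [0, 1]."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


def write_image_csv(path, img: np.ndarray) -> None:
    np.savetxt(Path(path), np.asarray(img, dtype=float), delimiter=",")


def read_image_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(Path(path), delimiter=","))


def write_sinogram(path, sino: Sinogram) -> None:
    angles_deg = ",".join(f"{np.degrees(a):.10g}" for a in sino.geometry.angles)
    np.savetxt(
        Path(path),
        sino.values,
        delimiter=",",
        header=f"angles_deg: {angles_deg}",
        comments="# ",
    )


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    prefix = "# angles_deg:"
    if not header.startswith(prefix):
        raise ValueError(f"{path} lacks the '# angles_deg:' header line")
    angles = np.radians(
        [float(tok) for tok in header[len(prefix):].split(",") if tok.strip()]
    )
    values = np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#"))
    geom = ProjectionGeometry(angles=angles, n_bins=values.shape[0])
    return Sinogram(values=values, geometry=geom)
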