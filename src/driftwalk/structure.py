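"""Binary membrane structures: occupancy grids, binarisation and PNG I/O.

A membrane cross-section is represented as a two-dimensional boolean
occupancy grid.  White pixels (value 255 in an 8-bit image) are obstacles —
the inorganic filler particles — and black pixels (value 0) are the walkable
polymer matrix.  All simulation and morphology code operates on this grid;
the pixel scale (nominally 5 nm per pixel for the SEM images this models) is
carried as metadata only and never enters a computation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "BinaryStructure",
    "binarize",
    "matrix_fraction",
    "load_structure",
    "save_structure",
]

OBSTACLE_LEVEL = 255
MATRIX_LEVEL = 0


@dataclass
class BinaryStructure:
    """A binary obstacle/matrix occupancy grid.

    Parameters
    ----------
    obstacle
        Boolean array of shape ``(height, width)``; ``True`` marks an
        obstacle pixel, ``False`` a matrix (walkable) pixel.  Row index is
        the y axis, column index the x axis.
    pixel_scale_nm
        Physical length of one pixel edge in nanometres.  Metadata only.
    threshold
        The binarisation level that produced this grid, if it came from a
        grayscale image; ``None`` for generated or directly constructed
        structures.
    """

    obstacle: np.ndarray
    pixel_scale_nm: float = 5.0
    threshold: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.obstacle)
        if arr.ndim != 2:
            raise ValueError(f"occupancy grid must be 2D, got ndim={arr.ndim}")
        if arr.size == 0:
            raise ValueError("occupancy grid must be non-empty")
        self.obstacle = np.ascontiguousarray(arr.astype(bool))

    @property
    def height(self) -> int:
        return self.obstacle.shape[0]

    @property
    def width(self) -> int:
        return self.obstacle.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.obstacle.shape

    @property
    def matrix(self) -> np.ndarray:
        """Boolean mask of walkable (matrix) pixels."""
        return ~self.obstacle

    @property
    def n_matrix(self) -> int:
        return int(self.matrix.sum())

    def matrix_fraction(self) -> float:
        """Fraction rho of the image occupied by matrix (black) pixels."""
        return self.n_matrix / self.obstacle.size

    def checksum(self) -> str:
        """SHA-256 of the occupancy grid (shape-qualified), for manifests."""
        h = hashlib.sha256()
        h.update(f"{self.height}x{self.width}:".encode())
        h.update(np.packbits(self.obstacle).tobytes())
        return h.hexdigest()

    def to_image(self) -> Image.Image:
        """Render as an 8-bit grayscale image (white=obstacle, black=matrix)."""
        levels = np.where(self.obstacle, OBSTACLE_LEVEL, MATRIX_LEVEL)
        return Image.fromarray(levels.astype(np.uint8), mode="L")

    def save_png(self, path) -> None:
        self.to_image().save(path, format="PNG")

    @classmethod
    def from_png(cls, path, pixel_scale_nm: float = 5.0) -> "BinaryStructure":
        """Load a binary structure from a PNG.

        The image is converted to 8-bit grayscale; any pixel at or above
        mid-gray (128) is classified as obstacle.  For images that are
        already strictly binary (0/255) the round trip through
        :meth:`save_png` is byte-lossless.
        """
        with Image.open(path) as im:
            gray = np.asarray(im.convert("L"))
        return cls(obstacle=gray >= 128, pixel_scale_nm=pixel_scale_nm)


def binarize(image: np.ndarray, threshold="otsu", pixel_scale_nm: float = 5.0) -> BinaryStructure:
    """Convert a grayscale image to a binary obstacle/matrix structure.

    Pixels at or above the threshold become obstacles (white convention),
    pixels below become matrix.

    Parameters
    ----------
    image
        2D grayscale array.  Integer arrays are assumed 8-bit and rescaled
        to [0, 1]; float arrays are used as-is and must lie in [0, 1].
    threshold
        Either a fixed level in [0, 1] or the name of an automatic method.
        Currently ``"otsu"`` is supported.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        raise ValueError(
            "multi-channel image: convert to a single grayscale channel "
            "(e.g. PIL convert('L')) before binarising"
        )
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2D grayscale array")

    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("float image values must lie in [0, 1]")

    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown automatic threshold method: {threshold!r}")
        if img.min() == img.max():
            # no contrast: nothing distinguishes filler from matrix
            warnings.warn(
                "constant image has no Otsu threshold; classifying all pixels as matrix",
                stacklevel=2,
            )
            level = np.inf
        else:
            from skimage.filters import threshold_otsu

            level = float(threshold_otsu(img))
    else:
        level = float(threshold)
        if not 0.0 <= level <= 1.0:
            raise ValueError("fixed threshold must lie in [0, 1]")

    return BinaryStructure(
        obstacle=img >= level,
        pixel_scale_nm=pixel_scale_nm,
        threshold=None if np.isinf(level) else level,
    )


def matrix_fraction(structure: BinaryStructure) -> float:
    """Matrix fraction rho: (# matrix pixels) / (total pixels)."""
    return structure.matrix_fraction()


def load_structure(path, pixel_scale_nm: float = 5.0) -> BinaryStructure:
    return BinaryStructure.from_png(path, pixel_scale_nm=pixel_scale_nm)


def save_structure(structure: BinaryStructure, path) -> None:
    structure.save_png(path)
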