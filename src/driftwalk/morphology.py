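"""Morphology descriptors of binary membrane structures.

Three descriptors characterise how the walkable polymer matrix fills the
image:

* the matrix fraction ``rho`` (area fraction of black pixels),
* the box-counting fractal dimension ``df`` of the matrix set,
* the generalized-dimension spectrum ``D(q)`` of the coarse-grained
  matrix-mass measure, whose spread ``delta_D = D(q_min) - D(q_max)`` is the
  degree of multifractality.

All estimators coarse-grain the image with a geometric schedule of box
sizes and fit a power law by least squares in log-log coordinates.  The
default schedule is powers of two from 2 px up to a quarter of the shorter
image side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structure import BinaryStructure

__all__ = [
    "BoxCountResult",
    "MultifractalSpectrum",
    "MorphologyReport",
    "default_box_sizes",
    "box_counting_dimension",
    "generalized_dimensions",
    "morphology_report",
]


def default_box_sizes(shape: tuple[int, int]) -> np.ndarray:
    """Powers of 2 from 2 px up to min(height, width) / 4."""
    smax = min(shape) // 4
    if smax < 2:
        raise ValueError(f"image too small for box counting: shape={shape}")
    n = int(np.floor(np.log2(smax)))
    return 2 ** np.arange(1, n + 1)


def _box_mass(mask: np.ndarray, size: int) -> np.ndarray:
    """Sum of `mask` over a size x size box partition (edge boxes may be smaller)."""
    h, w = mask.shape
    rows = np.add.reduceat(mask, np.arange(0, h, size), axis=0)
    return np.add.reduceat(rows, np.arange(0, w, size), axis=1)


def _as_measure(structure_or_measure) -> np.ndarray:
    if isinstance(structure_or_measure, BinaryStructure):
        return structure_or_measure.matrix.astype(np.float64)
    arr = np.asarray(structure_or_measure, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("measure must be a non-empty 2D array")
    if (arr < 0).any():
        raise ValueError("measure must be non-negative")
    return arr


def _validate_sizes(box_sizes, shape) -> np.ndarray:
    sizes = np.unique(np.asarray(box_sizes, dtype=int))
    if sizes.size < 3:
        raise ValueError("need at least 3 box sizes")
    if sizes[0] < 1 or sizes[-1] > min(shape):
        raise ValueError("box sizes must lie between 1 and the shorter image side")
    if sizes[-1] / sizes[0] < 8:
        raise ValueError("box sizes should span at least one decade (factor ~10)")
    return sizes


@dataclass
class BoxCountResult:
    """Box-counting dimension with regression diagnostics."""

    df: float
    r_squared: float
    stderr: float
    box_sizes: np.ndarray
    counts: np.ndarray


@dataclass
class MultifractalSpectrum:
    """Generalized dimensions D(q) and the multifractality spread."""

    q: np.ndarray
    D: np.ndarray
    r_squared: np.ndarray
    delta_D: float
    degenerate: bool = False

    def as_table(self) -> list[dict]:
        return [
            {"q": float(q), "D": float(d), "r_squared": float(r2)}
            for q, d, r2 in zip(self.q, self.D, self.r_squared)
        ]


def box_counting_dimension(
    structure: BinaryStructure | np.ndarray,
    box_sizes=None,
) -> BoxCountResult:
    """Box-counting fractal dimension of the matrix set.

    Counts the boxes of each size that contain at least one matrix pixel
    and fits log(count) against log(1/size).  The slope is ``df``.
    """
    mask = (
        structure.matrix
        if isinstance(structure, BinaryStructure)
        else np.asarray(structure, dtype=bool)
    )
    if not mask.any():
        raise ValueError("matrix set is empty: box-counting dimension undefined")
    sizes = (
        default_box_sizes(mask.shape)
        if box_sizes is None
        else _validate_sizes(box_sizes, mask.shape)
    )
    counts = np.array([(_box_mass(mask, int(s)) > 0).sum() for s in sizes])
    fit = stats.linregress(np.log(1.0 / sizes), np.log(counts))
    return BoxCountResult(
        df=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        stderr=float(fit.stderr),
        box_sizes=sizes,
        counts=counts,
    )


DEFAULT_Q_GRID = np.arange(-5, 6)


def generalized_dimensions(
    structure_or_measure,
    q_grid=None,
    box_sizes=None,
    r2_floor: float = 0.9,
) -> MultifractalSpectrum:
    """Generalized-dimension spectrum D(q) of a 2D mass measure.

    For a :class:`BinaryStructure` the measure is the matrix indicator
    (each matrix pixel carries unit mass).  Boxes of size ``s`` partition
    the image; with normalized box masses ``p_i`` the partition sum
    ``Z(q, s) = sum_i p_i**q`` (over non-empty boxes) scales as
    ``s**((q-1) D(q))``, and ``q = 1`` uses the entropy limit
    ``sum_i p_i log p_i ~ D(1) log s``.  D(q) is the least-squares slope
    over the box-size schedule, and ``delta_D = D(q_min) - D(q_max)``.

    Zero-mass boxes are excluded from every sum, which keeps negative
    moment orders finite.  If any per-q regression has R^2 below
    ``r2_floor`` the spectrum is flagged degenerate (and a warning is
    emitted) rather than silently returned.
    """
    measure = _as_measure(structure_or_measure)
    total = measure.sum()
    if total <= 0:
        raise ValueError("measure has zero total mass")
    q_grid = np.asarray(DEFAULT_Q_GRID if q_grid is None else q_grid, dtype=float)
    sizes = (
        default_box_sizes(measure.shape)
        if box_sizes is None
        else _validate_sizes(box_sizes, measure.shape)
    )

    log_s = np.log(sizes.astype(float))
    # per-size lists of normalized non-empty box masses
    ps = []
    for s in sizes:
        m = _box_mass(measure, int(s)).ravel()
        p = m[m > 0] / total
        ps.append(p)

    D = np.empty_like(q_grid)
    r2 = np.empty_like(q_grid)
    for k, q in enumerate(q_grid):
        if np.isclose(q, 1.0):
            y = np.array([np.sum(p * np.log(p)) for p in ps])
            fit = stats.linregress(log_s, y)
            D[k] = fit.slope
        else:
            y = np.array([np.log(np.sum(p**q)) for p in ps])
            fit = stats.linregress(log_s, y)
            D[k] = fit.slope / (q - 1.0)
        r2[k] = fit.rvalue**2

    # NaN R^2 (constant partition function, e.g. a point set) is degenerate too
    degenerate = bool(np.any(~(r2 >= r2_floor)))
    if degenerate:
        if np.isnan(r2).all():
            detail = "R^2 undefined: constant partition function"
        else:
            worst = q_grid[int(np.nanargmin(r2))]
            detail = f"min R^2 = {np.nanmin(r2):.3f} at q = {worst:g}"
        warnings.warn(
            f"degenerate partition-function scaling ({detail}); "
            "D(q) estimates unreliable",
            stacklevel=2,
        )
    delta_D = float(D[np.argmin(q_grid)] - D[np.argmax(q_grid)])
    return MultifractalSpectrum(q=q_grid, D=D, r_squared=r2, delta_D=delta_D, degenerate=degenerate)


@dataclass
class MorphologyReport:
    """Joint morphology summary of one structure."""

    rho: float
    df: float
    df_r_squared: float
    Dq: MultifractalSpectrum
    delta_D: float
    box_sizes: np.ndarray
    q_grid: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "df": self.df,
            "df_r_squared": self.df_r_squared,
            "delta_D": self.delta_D,
            "degenerate_scaling": self.Dq.degenerate,
            "box_sizes": [int(s) for s in self.box_sizes],
            "Dq": self.Dq.as_table(),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def morphology_report(
    structure: BinaryStructure,
    q_grid=None,
    box_sizes=None,
) -> MorphologyReport:
    """Compute rho, df and the D(q) spectrum of one structure."""
    sizes = default_box_sizes(structure.shape) if box_sizes is None else box_sizes
    bc = box_counting_dimension(structure, box_sizes=sizes)
    spec = generalized_dimensions(structure, q_grid=q_grid, box_sizes=sizes)
    return MorphologyReport(
        rho=structure.matrix_fraction(),
        df=bc.df,
        df_r_squared=bc.r_squared,
        Dq=spec,
        delta_D=spec.delta_D,
        box_sizes=bc.box_sizes,
        q_grid=spec.q,
    )
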