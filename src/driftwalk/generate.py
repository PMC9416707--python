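"""Synthetic binary membrane structures.

Artificial membranes emulate binarised SEM cross-sections of a polymer
matrix filled with inorganic particles: obstacles are unions of randomly
placed shapes (disks by default) whose sizes follow a configurable
distribution, placed until the obstacle area first reaches the prescribed
``1 - rho``.  The achieved matrix fraction is exact to one pixel: any
residual shortfall after shape placement is filled by flipping individual
randomly chosen matrix pixels.

The module also provides deterministic fixtures used throughout testing
and in drift experiments: free space, a sealed one-pixel cavity, and
vertical barrier walls that block horizontal transport (a low
horizontal-connectivity morphology on which drifting walkers trap).
"""

from __future__ import annotations

import numpy as np

from .structure import BinaryStructure

__all__ = [
    "generate_artificial",
    "free_space",
    "matrix_cavity",
    "vertical_barriers",
    "standard_fixtures",
]


def _sample_radius(rng: np.random.Generator, size_dist) -> float:
    """Draw one obstacle radius (px) from the configured size distribution."""
    kind = size_dist[0]
    if kind == "lognormal":
        _, median, sigma_log = size_dist
        return float(rng.lognormal(mean=np.log(median), sigma=sigma_log))
    if kind == "fixed":
        return float(size_dist[1])
    if kind == "uniform":
        _, lo, hi = size_dist
        return float(rng.uniform(lo, hi))
    raise ValueError(f"unknown size distribution: {size_dist!r}")


def _shape_indices(cx, cy, r, shape, width, height):
    """Flat pixel indices covered by one obstacle shape, wrapped periodically."""
    ri = int(np.ceil(r))
    ys = np.arange(int(np.floor(cy)) - ri, int(np.ceil(cy)) + ri + 1)
    xs = np.arange(int(np.floor(cx)) - ri, int(np.ceil(cx)) + ri + 1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    if shape == "disk":
        inside = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r**2
    elif shape == "square":
        inside = (np.abs(yy + 0.5 - cy) <= r) & (np.abs(xx + 0.5 - cx) <= r)
    else:
        raise ValueError(f"unknown obstacle shape: {shape!r}")
    iy = yy[inside] % height
    ix = xx[inside] % width
    return np.unique(iy * width + ix)


def generate_artificial(
    target_rho: float,
    width: int = 1024,
    height: int = 1024,
    *,
    shape: str = "disk",
    size_dist=("lognormal", 4.0, 0.5),
    seed=None,
    max_retries: int = 50,
    pixel_scale_nm: float = 5.0,
) -> BinaryStructure:
    """Generate a random obstacle field with a prescribed matrix fraction.

    Shapes are placed at uniform random centres (with periodic wrapping,
    matching the walker's boundary conditions) and may overlap.  A
    placement that would push the obstacle area past the target is
    retried with a fresh sample up to ``max_retries`` times; after that,
    single randomly chosen matrix pixels are flipped until the obstacle
    count equals ``round((1 - target_rho) * width * height)`` exactly.
    The construction is deterministic for a fixed seed.

    Parameters
    ----------
    target_rho
        Desired matrix (walkable) fraction, in (0, 1].
    size_dist
        Obstacle size distribution, one of ``("lognormal", median_px,
        sigma_log)``, ``("fixed", radius_px)`` or ``("uniform", lo, hi)``.
        Larger median radii produce coarser, more clustered filler.
    """
    if not 0.0 < target_rho <= 1.0:
        raise ValueError("target_rho must lie in (0, 1]")
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    rng = np.random.default_rng(seed)
    n_total = width * height
    n_target = int(round((1.0 - target_rho) * n_total))

    obstacle = np.zeros(n_total, dtype=bool)
    count = 0
    rmax = min(width, height) / 2.0 - 1.0
    while count < n_target:
        placed = False
        for _ in range(max_retries):
            r = min(_sample_radius(rng, size_dist), rmax)
            cx = rng.uniform(0.0, width)
            cy = rng.uniform(0.0, height)
            idx = _shape_indices(cx, cy, r, shape, width, height)
            fresh = idx[~obstacle[idx]]
            if count + fresh.size <= n_target:
                obstacle[fresh] = True
                count += fresh.size
                placed = True
                break
        if not placed:
            # remaining deficit is smaller than any sampled shape: fill
            # with individual pixels, random order, until exact
            deficit = n_target - count
            matrix_idx = np.flatnonzero(~obstacle)
            chosen = rng.choice(matrix_idx, size=deficit, replace=False)
            obstacle[chosen] = True
            count = n_target
    return BinaryStructure(
        obstacle=obstacle.reshape(height, width), pixel_scale_nm=pixel_scale_nm
    )


def free_space(width: int = 1024, height: int = 1024) -> BinaryStructure:
    """An empty structure: every pixel is matrix."""
    return BinaryStructure(obstacle=np.zeros((height, width), dtype=bool))


def matrix_cavity(width: int = 64, height: int = 64, cavity: int = 1) -> BinaryStructure:
    """All-obstacle structure with a centred ``cavity x cavity`` matrix pocket.

    A walker starting in the pocket is fully enclosed: every move out is
    rejected, so its displacement is bounded by the cavity diameter.
    """
    if not 1 <= cavity <= min(width, height) - 2:
        raise ValueError("cavity must fit strictly inside the image")
    obstacle = np.ones((height, width), dtype=bool)
    y0 = (height - cavity) // 2
    x0 = (width - cavity) // 2
    obstacle[y0 : y0 + cavity, x0 : x0 + cavity] = False
    return BinaryStructure(obstacle=obstacle)


def vertical_barriers(
    width: int = 1024,
    height: int = 1024,
    spacing: int = 64,
    wall_width: int = 1,
    gap_height: int = 0,
    seed=None,
) -> BinaryStructure:
    """Full-height vertical obstacle walls every ``spacing`` pixels.

    With ``gap_height = 0`` the walls completely block horizontal
    transport; a positive ``gap_height`` opens one randomly placed gap of
    that height per wall, giving sparse horizontal connectivity.
    """
    if spacing <= wall_width:
        raise ValueError("spacing must exceed wall_width")
    rng = np.random.default_rng(seed)
    obstacle = np.zeros((height, width), dtype=bool)
    for x in range(0, width, spacing):
        obstacle[:, x : x + wall_width] = True
        if gap_height > 0:
            g0 = int(rng.integers(0, height - gap_height + 1))
            obstacle[g0 : g0 + gap_height, x : x + wall_width] = False
    return BinaryStructure(obstacle=obstacle)


def standard_fixtures(width: int = 1024, height: int = 1024, seed: int = 0) -> dict:
    """The canned structure set used in drift experiments.

    Returns free space, a sealed cavity, blocking vertical walls, and two
    random obstacle fields at rho = 0.85 and 0.90.
    """
    ss = np.random.SeedSequence(seed)
    s85, s90 = (int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(2))
    return {
        "free": free_space(width, height),
        "cavity": matrix_cavity(min(width, 64), min(height, 64)),
        "barriers": vertical_barriers(width, height, spacing=64, wall_width=2),
        "rho085": generate_artificial(0.85, width, height, seed=s85),
        "rho090": generate_artificial(0.90, width, height, seed=s90),
    }
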