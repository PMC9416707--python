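"""Overdamped Brownian motion with drift on a binary obstacle structure.

Each time step a displacement xi * (cos th, sin th) + (Lx, Ly) is
proposed, with jump length xi ~ N(0, sigma^2), direction th ~ U[0, 2pi)
and a constant drift vector (Lx, Ly).  The move is accepted only if the
straight segment from the current position to the proposed one neither
ends in nor crosses an obstacle pixel (evaluated on the torus: periodic
boundary conditions); a rejected move leaves the walker in place for
that step.  Rejection rather than reflection at obstacle surfaces is a
standard discretisation of hard-wall overdamped dynamics and reproduces
the equilibrium position distribution in confined geometries.

Coordinates are continuous and *unwrapped* — displacement statistics are
unaffected by the wrapping, which only enters the collision test.  Pixel
(i, j) covers the half-open cell [i, i+1) x [j, j+1), x is the column
axis (the drift axis in the standard laboratory frame), y the row axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import segment_free, walk as _walk_kernel
from .structure import BinaryStructure

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "sample_start",
    "propose_displacement",
    "move_legal",
    "simulate_trajectory",
    "simulate_ensemble",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one random-walk ensemble.

    Defaults mirror the reference study conditions: jump scale
    sigma = 0.01 px, N = 1000 trajectories of 10^6 steps.  The drift is
    (lambda_x, lambda_y) in pixels per step; the laboratory frame is
    conventionally chosen so the drift points along +x.
    """

    sigma: float = 0.01
    drift: tuple[float, float] = (0.0, 0.0)
    n_trajectories: int = 1000
    n_steps: int = 1_000_000
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if len(self.drift) != 2:
            raise ValueError("drift must be a 2-vector (lambda_x, lambda_y)")

    @property
    def lambda_x(self) -> float:
        return float(self.drift[0])

    @property
    def lambda_y(self) -> float:
        return float(self.drift[1])

    def to_dict(self) -> dict:
        seed = self.seed
        if isinstance(seed, np.random.SeedSequence):
            seed = seed.entropy
        return {
            "sigma": self.sigma,
            "lambda_x": self.lambda_x,
            "lambda_y": self.lambda_y,
            "n_trajectories": self.n_trajectories,
            "n_steps": self.n_steps,
            "seed": seed,
        }


@dataclass
class Trajectory:
    """One walker's recorded path.

    ``positions[k]`` is the unwrapped (x, y) position at step
    ``steps[k]``; ``steps[0]`` is always 0 (the start).  ``accepted`` —
    present when requested at simulation time — flags which of the
    ``n_steps`` proposals were accepted.
    """

    steps: np.ndarray
    positions: np.ndarray
    n_steps: int
    accepted: np.ndarray | None = field(default=None, repr=False)

    @property
    def start(self) -> np.ndarray:
        return self.positions[0]

    @property
    def is_full(self) -> bool:
        """True when every step 0..n_steps was recorded."""
        return len(self.steps) == self.n_steps + 1

    def displacement(self) -> np.ndarray:
        """Displacement from the start at every recorded step."""
        return self.positions - self.positions[0]

    def squared_displacement(self) -> np.ndarray:
        d = self.displacement()
        return d[:, 0] ** 2 + d[:, 1] ** 2


def sample_start(structure: BinaryStructure, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random matrix-pixel centre (the walker's start position)."""
    matrix_idx = np.flatnonzero(structure.matrix)
    if matrix_idx.size == 0:
        raise ValueError("structure has no matrix pixels to start from")
    flat = matrix_idx[rng.integers(matrix_idx.size)]
    iy, ix = divmod(int(flat), structure.width)
    return np.array([ix + 0.5, iy + 0.5])


def propose_displacement(rng: np.random.Generator, sigma: float, drift, size=None):
    """Draw proposed displacement(s): Gaussian jump + uniform direction + drift."""
    xi = rng.normal(0.0, sigma, size=size)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=size)
    dx = xi * np.cos(theta) + drift[0]
    dy = xi * np.sin(theta) + drift[1]
    if size is None:
        return np.array([dx, dy])
    return np.stack([dx, dy], axis=-1)


def move_legal(structure: BinaryStructure, from_position, to_position) -> bool:
    """True iff the move neither ends in nor crosses an obstacle pixel.

    ``from_position`` must lie in a matrix pixel (after periodic
    wrapping).  The segment is traced exactly through every pixel it
    crosses, with periodic wrapping of pixel indices.
    """
    x0, y0 = float(from_position[0]), float(from_position[1])
    x1, y1 = float(to_position[0]), float(to_position[1])
    H, W = structure.shape
    if structure.obstacle[int(np.floor(y0)) % H, int(np.floor(x0)) % W]:
        raise ValueError("from_position lies in an obstacle pixel")
    if max(abs(x1 - x0), abs(y1 - y0)) > min(W, H):
        warnings.warn(
            "proposed segment longer than the image period; the periodic "
            "collision test is still exact but such jumps are unphysical "
            "at the intended sigma and drift scales",
            stacklevel=2,
        )
    return bool(segment_free(structure.obstacle, x0, y0, x1, y1))


def _resolve_record_steps(n_steps: int, record_steps) -> np.ndarray:
    if record_steps is None:
        rec = np.arange(n_steps + 1, dtype=np.int64)
    else:
        rec = np.unique(np.asarray(record_steps, dtype=np.int64))
        if rec.size == 0 or rec[0] < 0 or rec[-1] > n_steps:
            raise ValueError("record_steps must lie in [0, n_steps]")
        if rec[0] != 0:
            rec = np.concatenate([[0], rec])
    return rec


def simulate_trajectory(
    structure: BinaryStructure,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    record_steps=None,
    keep_accepted: bool = False,
) -> Trajectory:
    """Simulate one walker.

    Parameters
    ----------
    rng
        Source of randomness; defaults to a generator seeded from
        ``config.seed``.
    record_steps
        Step indices at which to record the (unwrapped) position;
        ``None`` records every step.  Step 0 is always recorded.  For
        long runs a log-spaced grid (see
        :func:`driftwalk.analysis.log_spaced_steps`) keeps memory flat.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rec = _resolve_record_steps(config.n_steps, record_steps)
    start = sample_start(structure, rng)

    disp = propose_displacement(rng, config.sigma, config.drift, size=config.n_steps)
    step_scale = 6.0 * config.sigma + float(np.hypot(*config.drift))
    if step_scale > min(structure.shape):
        warnings.warn("per-step displacements can exceed the image period", stacklevel=2)

    out_pos = np.empty((rec.size, 2), dtype=np.float64)
    accepted = np.zeros(config.n_steps, dtype=np.bool_)
    _walk_kernel(
        structure.obstacle,
        float(start[0]),
        float(start[1]),
        np.ascontiguousarray(disp[:, 0]),
        np.ascontiguousarray(disp[:, 1]),
        rec,
        out_pos,
        accepted,
    )
    return Trajectory(
        steps=rec,
        positions=out_pos,
        n_steps=config.n_steps,
        accepted=accepted if keep_accepted else None,
    )


def simulate_ensemble(
    structure: BinaryStructure,
    config: SimulationConfig,
    record_steps=None,
    keep_accepted: bool = False,
) -> list[Trajectory]:
    """Simulate N independent walkers with independently sampled starts.

    Each trajectory uses its own RNG substream spawned deterministically
    from ``config.seed``, so the ensemble is bit-reproducible and
    trajectories are statistically independent.
    """
    seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(config.n_trajectories)
    return [
        simulate_trajectory(
            structure,
            config,
            rng=np.random.default_rng(child),
            record_steps=record_steps,
            keep_accepted=keep_accepted,
        )
        for child in children
    ]
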