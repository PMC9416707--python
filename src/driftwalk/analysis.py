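"""MSD / TAMSD computation and anomalous-diffusion power-law analysis.

The ensemble mean square displacement MSD(t) = <|r(t) - r(0)|^2> is
fitted to the power law MSD = D_alpha * t**alpha by least squares on
ln MSD vs ln t.  alpha < 1 indicates subdiffusion (trapping), alpha = 1
normal diffusion, 1 < alpha < 2 superdiffusion and alpha = 2 ballistic
motion.  Free-space benchmarks: MSD(t) = sigma^2 t without drift and
sigma^2 t + |Lambda|^2 t^2 with drift (the cross term vanishes because
the jump direction is isotropic), with crossover at t* = sigma^2 /
|Lambda|^2.

The default fit window discards the earliest lags (t < 10 steps), the
final 10% of the run, and — when an MSD plateau is detected — the
saturated tail, then keeps at most the central two decades of what
remains so the fit is not dominated by either end of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structure import BinaryStructure
from .walk import SimulationConfig, Trajectory, simulate_ensemble

__all__ = [
    "MSDSeries",
    "FitResult",
    "log_spaced_steps",
    "ensemble_msd",
    "time_averaged_msd",
    "default_fit_window",
    "fit_anomalous_exponent",
    "is_saturated",
    "plateau_onset",
    "fit_with_saturation_handling",
    "drift_scan",
    "trapped_fraction",
    "SCAN_COLUMNS",
]


@dataclass
class MSDSeries:
    """Mean square displacement per time lag (px^2 per step index)."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # "ensemble" | "time_averaged"
    n_samples: np.ndarray | int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "msd": self.values, "n_samples": self.n_samples}
        )


@dataclass
class FitResult:
    """Power-law fit of an MSD series: MSD = D_alpha * t**alpha."""

    alpha: float
    d_alpha: float
    fit_window: tuple[float, float]
    r_squared: float
    stderr_alpha: float
    n_points: int
    saturated: bool = False

    @property
    def ln_d_alpha(self) -> float:
        return float(np.log(self.d_alpha))


def log_spaced_steps(n_steps: int, per_decade: int = 50) -> np.ndarray:
    """Unique integer step indices, ~per_decade points per decade, incl. 0."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n_pts = max(2, int(np.ceil(per_decade * np.log10(n_steps))) + 1)
    grid = np.unique(np.round(np.geomspace(1, n_steps, n_pts)).astype(np.int64))
    return np.concatenate([[0], grid])


def ensemble_msd(trajectories: list[Trajectory], time_grid=None) -> MSDSeries:
    """Ensemble MSD: mean over trajectories of |r_i(t) - r_i(0)|^2.

    All trajectories must share the same recorded step grid.  If
    ``time_grid`` is given it must be a subset of the recorded steps.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    steps = trajectories[0].steps
    for tr in trajectories[1:]:
        if len(tr.steps) != len(steps) or not np.array_equal(tr.steps, steps):
            raise ValueError("trajectories have mismatched recorded step grids")
    sq = np.stack([tr.squared_displacement() for tr in trajectories])
    values = sq.mean(axis=0)
    times = steps
    if time_grid is not None:
        time_grid = np.asarray(time_grid)
        pos = np.searchsorted(steps, time_grid)
        if pos.max(initial=0) >= len(steps) or not np.array_equal(steps[pos], time_grid):
            raise ValueError("time_grid must be a subset of the recorded steps")
        times, values = time_grid, values[pos]
    return MSDSeries(times=times, values=values, kind="ensemble", n_samples=len(trajectories))


def time_averaged_msd(trajectory: Trajectory, lag_grid=None) -> MSDSeries:
    """Time-averaged MSD of one trajectory.

    For lag D the sliding-origin average
    (1 / (T - D)) * sum_t |r(t + D) - r(t)|^2 over t = 0..T-D-1.
    Requires a fully recorded trajectory (every step).
    """
    if not trajectory.is_full:
        raise ValueError("time-averaged MSD needs a fully recorded trajectory")
    T = trajectory.n_steps
    if lag_grid is None:
        lag_grid = log_spaced_steps(T, per_decade=50)[1:]
    lags = np.unique(np.asarray(lag_grid, dtype=np.int64))
    if lags[0] < 1 or lags[-1] >= T + 1:
        raise ValueError("lags must lie in [1, n_steps]")
    pos = trajectory.positions
    values = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=np.int64)
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        values[k] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
        counts[k] = len(d)
    return MSDSeries(times=lags, values=values, kind="time_averaged", n_samples=counts)


def default_fit_window(
    t_max: float,
    t_min_floor: float = 10.0,
    tail_fraction: float = 0.1,
    max_decades: float = 2.0,
) -> tuple[float, float]:
    """Default power-law fit window.

    Excludes lags below ``t_min_floor`` steps and the final
    ``tail_fraction`` of the run, then keeps the central ``max_decades``
    decades of the remaining log-range.
    """
    lo = t_min_floor
    hi = (1.0 - tail_fraction) * t_max
    if hi <= lo:
        return (1.0, float(t_max))
    span = np.log10(hi / lo)
    if span > max_decades:
        mid = 0.5 * (np.log10(lo) + np.log10(hi))
        lo = 10 ** (mid - max_decades / 2.0)
        hi = 10 ** (mid + max_decades / 2.0)
    return (float(lo), float(hi))


def fit_anomalous_exponent(msd: MSDSeries, window=None) -> FitResult:
    """Least-squares line through (ln t, ln MSD): slope alpha, intercept ln D_alpha.

    Non-positive MSD values inside the window are excluded with a
    warning; fewer than 3 usable points is an error.
    """
    if window is None:
        window = default_fit_window(float(msd.times.max()))
    lo, hi = window
    t = np.asarray(msd.times, dtype=np.float64)
    v = msd.values
    sel = (t >= lo) & (t <= hi) & (t > 0)
    if (v[sel] <= 0).any():
        warnings.warn("non-positive MSD values excluded from the fit window", stacklevel=2)
        sel &= v > 0
    if sel.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable MSD points in fit window [{lo:g}, {hi:g}]"
        )
    fit = stats.linregress(np.log(t[sel]), np.log(v[sel]))
    return FitResult(
        alpha=float(fit.slope),
        d_alpha=float(np.exp(fit.intercept)),
        fit_window=(float(lo), float(hi)),
        r_squared=float(fit.rvalue**2),
        stderr_alpha=float(fit.stderr),
        n_points=int(sel.sum()),
    )


def _positive(msd: MSDSeries):
    t = np.asarray(msd.times, dtype=np.float64)
    sel = (t > 0) & (msd.values > 0)
    return t[sel], msd.values[sel]


def is_saturated(msd: MSDSeries, slope_threshold: float = 0.1) -> bool:
    """True when the log-log slope over the final decade of lags is < threshold."""
    t, v = _positive(msd)
    if t.size == 0:
        return True  # MSD identically zero: fully confined
    sel = t >= t.max() / 10.0
    if sel.sum() < 3:
        return False
    slope = stats.linregress(np.log(t[sel]), np.log(v[sel])).slope
    return bool(slope < slope_threshold)


def plateau_onset(
    msd: MSDSeries,
    slope_threshold: float = 0.1,
    window_decades: float = 0.5,
) -> float | None:
    """Earliest lag from which the local log-log slope stays below threshold.

    The local slope at lag t is fitted over [t, t * 10**window_decades].
    Returns None when no such onset exists.
    """
    t, v = _positive(msd)
    if t.size < 3:
        return None
    lt, lv = np.log(t), np.log(v)
    width = window_decades * np.log(10.0)
    slopes = np.full(t.size, np.nan)
    for i in range(t.size):
        sel = (lt >= lt[i]) & (lt <= lt[i] + width)
        if sel.sum() >= 3:
            slopes[i] = stats.linregress(lt[sel], lv[sel]).slope
    ok = slopes < slope_threshold  # NaN compares False
    valid = ~np.isnan(slopes)
    # earliest index from which every later *valid* local slope is flat
    onset = None
    for i in range(t.size):
        later = valid[i:]
        if later.any() and ok[i:][later].all() and ok[i]:
            onset = float(t[i])
            break
    return onset


def fit_with_saturation_handling(
    msd: MSDSeries,
    window=None,
    slope_threshold: float = 0.1,
    min_decades: float = 1.5,
) -> FitResult:
    """Power-law fit with plateau detection.

    When the MSD saturates only near the end of the window, the
    saturated tail is excluded: the fit window is truncated at the
    plateau onset, provided at least ``min_decades`` decades of
    unsaturated lags remain.  When the plateau covers most of the
    window — the ensemble is essentially fully trapped — the fit spans
    the full default window, so the small fitted alpha *is* the
    signature of trapping, as in the saturating-MSD regime at strong
    drift.  The saturation flag is set either way.
    """
    if window is None:
        window = default_fit_window(float(msd.times.max()))
    saturated = is_saturated(msd, slope_threshold)
    lo, hi = window
    if saturated:
        onset = plateau_onset(msd, slope_threshold)
        if onset is not None and onset >= lo * 10**min_decades:
            hi = min(hi, onset)
    try:
        result = fit_anomalous_exponent(msd, window=(lo, hi))
    except ValueError:
        result = fit_anomalous_exponent(msd, window=window)
    result.saturated = saturated
    return result


SCAN_COLUMNS = [
    "lambda",
    "alpha",
    "d_alpha",
    "ln_d_alpha",
    "r2",
    "t_min",
    "t_max",
    "saturated",
]


def drift_scan(
    structure: BinaryStructure,
    sigma: float,
    lambda_grid,
    n_trajectories: int = 200,
    n_steps: int = 100_000,
    seed=None,
    per_decade: int = 50,
) -> pd.DataFrame:
    """Fit (alpha, D_alpha) for each drift value in ``lambda_grid``.

    For every Lambda an independent ensemble is simulated (drift along
    +x), the ensemble MSD is computed on a log-spaced grid and fitted
    with saturation handling.  Returns a table with columns
    ``lambda, alpha, d_alpha, ln_d_alpha, r2, t_min, t_max, saturated``.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(lambda_grid.size)
    record = log_spaced_steps(n_steps, per_decade=per_decade)
    rows = []
    for lam, child in zip(lambda_grid, children):
        config = SimulationConfig(
            sigma=sigma,
            drift=(float(lam), 0.0),
            n_trajectories=n_trajectories,
            n_steps=n_steps,
            seed=child,
        )
        trajs = simulate_ensemble(structure, config, record_steps=record)
        msd = ensemble_msd(trajs)
        fit = fit_with_saturation_handling(msd)
        rows.append(
            {
                "lambda": float(lam),
                "alpha": fit.alpha,
                "d_alpha": fit.d_alpha,
                "ln_d_alpha": fit.ln_d_alpha,
                "r2": fit.r_squared,
                "t_min": fit.fit_window[0],
                "t_max": fit.fit_window[1],
                "saturated": fit.saturated,
            }
        )
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def trapped_fraction(
    trajectories: list[Trajectory],
    window_steps: int,
    epsilon_px: float,
) -> float:
    """Fraction of trajectories nearly immobile over the final window.

    A trajectory counts as trapped when its net displacement over the
    last ``window_steps`` recorded steps is below ``epsilon_px``.
    """
    if window_steps < 1:
        raise ValueError("window_steps must be >= 1")
    n_trapped = 0
    for tr in trajectories:
        if window_steps >= tr.n_steps:
            raise ValueError("window_steps must be smaller than the trajectory length")
        t0 = tr.n_steps - window_steps
        k0 = int(np.searchsorted(tr.steps, t0, side="right")) - 1
        d = tr.positions[-1] - tr.positions[k0]
        if np.hypot(d[0], d[1]) < epsilon_px:
            n_trapped += 1
    return n_trapped / len(trajectories)
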