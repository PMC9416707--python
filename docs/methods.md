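# Methods

## Model and assumptions

`driftwalk` simulates a point-size tracer on a two-dimensional binary
occupancy grid. Matrix (black) pixels are walkable; obstacle (white)
pixels are impenetrable. The dynamics is overdamped Brownian motion with a
constant external drift, discretised per time step as

    dr = xi (cos th, sin th) + (Lx, Ly)

with `xi ~ N(0, sigma^2)` and `th ~ U[0, 2pi)`. The sign of `xi` is left
unfolded: with an isotropic direction the displacement law is identical
either way. A proposed move is accepted only if the segment from the
current to the proposed position neither ends in nor crosses an obstacle
pixel; a rejected proposal consumes the time step with zero displacement.
Rejection (rather than reflection or resampling) is a standard
discretisation of hard-wall overdamped dynamics that reproduces the
analytic equilibrium position distribution in confined wells; resampling
until success would erase exactly the trapping that strong drift induces,
which is the phenomenon of interest.

Assumptions: a single non-interacting tracer; static obstacles; hard
(non-absorbing, non-sticky) obstacle surfaces; two dimensions; periodic
boundary conditions, so the image tile represents bulk material rather
than a bounded sample. Coordinates are continuous and unwrapped —
wrapping applies only to the collision test — so displacement statistics
are free of boundary artifacts.

## Coordinate and collision conventions

Pixel `(i, j)` covers the half-open cell `[i, i+1) x [j, j+1)`; x is the
column axis (the drift axis in the default frame), y the row axis. Walkers
start at the centre of a uniformly chosen matrix pixel; at the default
jump scale (`sigma = 0.01` px, far below the pixel size) sub-pixel start
placement is immaterial, and the centre makes runs reproducible.

The segment-obstacle test is an exact Amanatides–Woo grid traversal: the
proposal segment is walked through every pixel it crosses, wrapping pixel
indices modulo the image size, at O(segment length) cost. An exact
corner crossing (measure zero for Gaussian proposals) is resolved by
visiting one of the two edge-adjacent pixels, a deterministic,
conservative tie-break. A proposal longer than the image period is legal
input but triggers a warning — it cannot occur at the intended `sigma`
and drift scales.

Randomness comes from one named NumPy generator per trajectory, spawned
deterministically from the ensemble seed (`SeedSequence.spawn`), so
ensembles are bit-reproducible and trajectories independent.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `sigma` | std of the Gaussian jump length | px/step | 0.01 |
| `(lambda_x, lambda_y)` | drift added to every proposal | px/step | (0, 0) |
| `n_trajectories` | ensemble size N | — | 1000 |
| `n_steps` | steps per trajectory | — | 10^6 |
| `pixel_scale_nm` | physical pixel size (metadata only) | nm | 5 |

The reference conditions are `sigma = 0.01`, N = 1000, 10^6 steps on
1024 x 1024 structures. The command line and the reproduction script use
a scaled working size of N = 200 and 10^5 steps, which resolves the same
drift phenomenology with proportionally larger Monte-Carlo error; any
run can be taken back to the full reference scale through its config.

Physical units enter only through the pixel scale: with a diffusion
coefficient `D` from experiment or from the Einstein–Smoluchowski /
Stokes–Einstein relations (`D = mu kB T / q`, `D = kB T / 6 pi eta r`),
the Gaussian step obeys `sigma^2 = 2 D dt`, which converts a simulated
drift-to-noise ratio into physical field strengths. No such conversion is
performed in code.

## MSD, TAMSD and exponent fitting

The ensemble MSD is `<|r_i(t) - r_i(0)|^2>` over trajectories; the
time-averaged MSD of one trajectory averages `|r(t+D) - r(t)|^2` over all
sliding origins `t` (the conventional definition). Free-space closed
forms used as oracles throughout the tests: `MSD(t) = sigma^2 t` without
drift and `sigma^2 t + |L|^2 t^2` with drift (the cross term vanishes by
isotropy of `th`), with crossover at `t* = sigma^2 / |L|^2`.

`(alpha, D_alpha)` come from a least-squares line through
`(ln t, ln MSD)`. MSD values are recorded on a log-spaced time grid
(~50 points per decade) so the fit weights scales evenly. The default
fit window excludes lags below 10 steps (discretisation onset), the final
10% of the run (poorly averaged tail), and then keeps the central two
decades of the remaining log-range. On exact power-law input the fit
recovers `(alpha, D_alpha)` to machine precision.

Saturation handling: an MSD is flagged saturated when its log-log slope
over the final decade of lags falls below 0.1. If the plateau begins late
enough that at least 1.5 decades of unsaturated lags remain above the
window floor, the saturated tail is excluded from the fit; when the
plateau covers most of the window — the strong-drift regime in which the
whole ensemble is trapped — the fit deliberately spans the full default
window, because there the plateau *is* the transport result and excluding
it would misreport a trapped ensemble as mobile. The fitted window is
always recorded in the result. `D_alpha` is reported as the intercept
`exp(ln D_alpha)` in px²/stepᵃ; its units depend on `alpha`, so values at
different drifts are comparable only through the fit itself.

The drift scan runs an independent ensemble per drift value (spawned
sub-seeds), fits each MSD with saturation handling and tabulates
`(lambda, alpha, d_alpha, ln_d_alpha, r2, t_min, t_max, saturated)`.
A trapped-fraction diagnostic reports the share of trajectories whose net
displacement over a trailing window stays below a threshold.

## Morphology estimators

* **Matrix fraction** `rho`: exact pixel count ratio, black/total.
* **Box counting** `df`: boxes are a fixed partition at sizes on a
  geometric schedule (default powers of two from 2 px to a quarter of the
  short side); `df` is the slope of `log(count)` vs `log(1/size)`, with
  R² reported. Validated against a full plane (2), a single row (1) and a
  depth-5 Sierpinski carpet (log 8 / log 3, exact at power-of-3 box
  sizes).
* **Generalized dimensions** `D(q)`: the matrix-indicator measure is
  coarse-grained over the same box schedule; for `q != 1`,
  `log sum p_i^q` is regressed on `log size` and divided by `q - 1`;
  `q = 1` uses the entropy limit `sum p_i log p_i`. Zero-mass boxes are
  excluded from all sums, which keeps negative orders finite. The default
  grid is integer `q` in [-5, 5] and
  `delta_D = D(-5) - D(+5)`. Any per-q regression with R² below 0.9 (or
  undefined, e.g. for a point set) flags the spectrum as degenerate with
  a warning instead of failing silently. The estimator reproduces the
  closed-form spectrum of a 2D product binomial cascade
  (`D(q) = -2 log2(p^q + (1-p)^q) / (q - 1)`) and gives a flat spectrum
  on monofractals.

Printed `df`/`delta_D` values for real micrographs depend on the specific
images and their binarisation and are not reproduced here; the estimators
are validated on analytic fixtures instead.

## Synthetic structures

`generate_artificial` emulates a binarised filled-membrane cross-section:
disk (or square) obstacles with lognormal radii (default median 4 px,
log-sd 0.5) are placed at uniform random centres with periodic wrapping,
overlapping freely, until the obstacle area reaches `1 - rho`. A
placement that would overshoot the target is resampled a bounded number
of times; the final residual (smaller than the smallest sampled shape) is
filled by flipping individual random matrix pixels, so the achieved
`rho` is exact to one pixel and the construction always terminates. At
`rho = 0.85` the default parameters yield `df ~ 1.976` and
`delta_D ~ 0.36` — in the range reported for comparable artificial
membrane images — without any tuning to those values.

What the generator does *not* emulate: grayscale partial occupancy,
anisotropic or oriented filler, correlated aggregation beyond what
overlapping lognormal disks produce, and 3D connectivity. Passing tests
on these fields therefore demonstrate the drift-trapping mechanism and
the estimator correctness, not a quantitative match to any particular
real membrane; the drift phenomenology itself is insensitive to
morphological detail, which is why synthetic fields suffice.

Deterministic fixtures complement the random fields: free space (analytic
MSD), a sealed cavity (exact confinement bound), and full-height vertical
barrier walls — a worst-case low-horizontal-connectivity morphology on
which drifting walkers trap and the MSD saturates.

## Numerical choices and degenerate inputs

* Binarisation defaults to Otsu's threshold with a fixed-level override;
  the applied level is stored on the structure. A constant image has no
  Otsu threshold and is classified all-matrix with a warning.
* Box-size schedules require at least three sizes spanning at least a
  decade; empty matrix sets and zero-mass measures are errors.
* Fits require at least three positive MSD points in the window;
  non-positive values are excluded with a warning.
* An all-obstacle structure has no start position and is an error.
* Same seed implies bit-identical structures, trajectories and tables;
  every CLI simulation writes a manifest (config, structure checksum,
  seed, version) sufficient to rerun it bit-exactly.

## Known limitations

* Single-tracer physics only: no crowding interactions between walkers.
* The fitted `alpha` is window-dependent in crossover and saturating
  regimes; the window is always reported, and comparisons should use the
  same window policy. In particular the location of the shallow
  `D_alpha` minimum along the drift axis shifts with the observation
  scale: at the scaled working size the minimum sits one gridpoint above
  its long-run position.
* Ergodicity-breaking statistics, continuous-geometry obstacles,
  reflecting/absorbing boundaries and 3D media are out of scope.
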