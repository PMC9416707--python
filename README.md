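# driftwalk

Obstructed Brownian motion with drift on binary membrane images.

Hybrid polymer membranes — a polymer matrix (e.g. alginate) filled with
inorganic particles (e.g. magnetite) — transport small molecules through the
matrix while the filler acts as impenetrable obstacles. `driftwalk` models
this transport as a point tracer performing two-dimensional overdamped
Brownian motion with a constant drift on a binary image of the membrane
cross-section, and quantifies the resulting anomalous diffusion. It is
aimed at membrane/transport modellers who want to ask: *given a membrane
morphology, how does an external bias (field, pressure, flow) change the
effective transport through it?*

## Model

A structure is a binary pixel grid: black pixels are walkable matrix, white
pixels are obstacles. Each time step the tracer proposes a displacement

    dr = xi (cos th, sin th) + (Lx, Ly),     xi ~ N(0, s^2),  th ~ U[0, 2p)

with jump scale `s` (sigma) and drift vector `(Lx, Ly)` in pixels per step
(the frame is chosen so the drift points along +x: `Lx = L`, `Ly = 0`). The
move is accepted only if the straight segment to the proposed position
neither ends in nor crosses an obstacle pixel (exact grid traversal,
periodic boundary conditions); otherwise the tracer stays put for that
step. Coordinates are kept unwrapped for displacement statistics.

Transport is characterised by the ensemble mean square displacement and its
power law,

    MSD(t) = <|r(t) - r(0)|^2> = D_a t^a,

fitted by least squares on `ln MSD` vs `ln t`. `a < 1` is subdiffusion
(trapping), `a = 1` normal diffusion, `1 < a < 2` superdiffusion and
`a = 2` ballistic motion; `D_a` is the generalized diffusion coefficient
(px²/stepᵃ). A time-averaged MSD over sliding origins of a single
trajectory is also provided. Structures — binarised micrographs or
synthetic obstacle fields generated at a prescribed matrix fraction `rho` —
are characterised by `rho`, the box-counting fractal dimension `df` of the
matrix, and the multifractal spread `delta_D = D(q_min) - D(q_max)` of the
generalized-dimension spectrum.

The central phenomenology this reproduces: on a crowded structure a *small*
drift (`L ~ 0.1 s`) boosts transport toward ballistic motion (`a` rises to
~1.8), while a *strong* drift presses tracers against obstacle faces that
thermal jumps can no longer carry them around — trajectories trap, the MSD
saturates, and the fitted exponent collapses below 1.

## Worked example

```python
import driftwalk as dw

# a 1024x1024 obstacle field at matrix fraction 0.85 (lognormal disk sizes)
s = dw.generate_artificial(0.85, 1024, 1024, seed=11)
rep = dw.morphology_report(s)
print(f"rho     = {rep.rho:.4f}")
print(f"df      = {rep.df:.4f}  (R^2 = {rep.df_r_squared:.5f})")
print(f"delta_D = {rep.delta_D:.4f}")

table = dw.drift_scan(s, sigma=0.01, lambda_grid=[0.0, 0.001, 0.25],
                      n_trajectories=200, n_steps=100_000, seed=5)
print(table[["lambda", "alpha", "ln_d_alpha", "saturated"]].to_string(index=False))
```

prints

```
rho     = 0.8500
df      = 1.9762  (R^2 = 0.99993)
delta_D = 0.3578
 lambda    alpha  ln_d_alpha  saturated
  0.000 1.006982   -9.313116      False
  0.001 1.837882  -12.503132      False
  0.250 0.494188    4.894406       True
```

Reading it: the generated structure hits the prescribed matrix fraction
exactly and is nearly plane-filling (`df` close to 2) with mild
multifractality. Without drift the walk is normally diffusive
(`alpha ~ 1`). A drift of one tenth of the jump scale drives a
superdiffusive peak (`alpha ~ 1.84`), while a drift of 25 jump scales traps
the ensemble: the MSD saturates (flag set) and the fitted exponent drops
to ~0.49 — drift-induced subdiffusion.

The same workflows are available from the shell:

```
driftwalk generate spec.yaml --out structures/
driftwalk binarize sem.png binary.png --threshold otsu
driftwalk morphology structures/m1.png
driftwalk simulate structures/m1.png --config config.yaml --out run/
driftwalk analyze run/trajectories.csv --out run/
driftwalk scan structures/m1.png --lambdas 0,0.001,0.25 --config config.yaml --out scan.csv
```

Every simulation writes a manifest (resolved config, structure checksum,
seed, version) from which the run can be reproduced bit-exactly.

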