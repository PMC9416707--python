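"""Numba kernels for the obstructed random walk.

The collision test is an exact grid traversal (Amanatides & Woo): the
proposed segment is walked pixel by pixel through every cell it crosses,
with periodic wrapping applied to the pixel indices only, so unwrapped
coordinates can grow without bound while collisions are evaluated on the
torus.  Cost is O(segment length in pixels) per proposal.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def segment_free(occ, x0, y0, x1, y1):  # pragma: no cover - exercised via wrappers
    """True iff the segment (x0,y0)->(x1,y1) crosses no obstacle pixel.

    Pixel (i, j) covers the half-open cell [i, i+1) x [j, j+1); x is the
    column axis, y the row axis.  Indices are wrapped modulo the image
    size.  The start pixel is checked too.
    """
    H, W = occ.shape
    ix = int(np.floor(x0))
    iy = int(np.floor(y0))
    ixe = int(np.floor(x1))
    iye = int(np.floor(y1))
    if occ[iy % H, ix % W]:
        return False

    dx = x1 - x0
    dy = y1 - y0
    step_x = 0
    t_max_x = np.inf
    t_dx = np.inf
    if dx > 0.0:
        step_x = 1
        t_max_x = (ix + 1.0 - x0) / dx
        t_dx = 1.0 / dx
    elif dx < 0.0:
        step_x = -1
        t_max_x = (ix - x0) / dx
        t_dx = -1.0 / dx
    step_y = 0
    t_max_y = np.inf
    t_dy = np.inf
    if dy > 0.0:
        step_y = 1
        t_max_y = (iy + 1.0 - y0) / dy
        t_dy = 1.0 / dy
    elif dy < 0.0:
        step_y = -1
        t_max_y = (iy - y0) / dy
        t_dy = -1.0 / dy

    n = abs(ixe - ix) + abs(iye - iy)
    for _ in range(n):
        if t_max_x < t_max_y:
            ix += step_x
            t_max_x += t_dx
        else:
            iy += step_y
            t_max_y += t_dy
        if occ[iy % H, ix % W]:
            return False
    return True


@njit(cache=True)
def walk(occ, x0, y0, ddx, ddy, rec_steps, out_pos, accepted):  # pragma: no cover
    """Run one trajectory of len(ddx) proposed displacements.

    A proposal is accepted iff its segment is obstacle-free; a rejected
    proposal leaves the position unchanged but still consumes the time
    step.  Positions are recorded (unwrapped) at the step indices in
    ``rec_steps`` (sorted, rec_steps[0] == 0).  Returns the number of
    accepted steps.
    """
    x = x0
    y = y0
    out_pos[0, 0] = x
    out_pos[0, 1] = y
    k = 1
    n_rec = rec_steps.shape[0]
    n_acc = 0
    for t in range(ddx.shape[0]):
        nx = x + ddx[t]
        ny = y + ddy[t]
        if segment_free(occ, x, y, nx, ny):
            x = nx
            y = ny
            accepted[t] = True
            n_acc += 1
        if k < n_rec and rec_steps[k] == t + 1:
            out_pos[k, 0] = x
            out_pos[k, 1] = y
            k += 1
    return n_acc
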