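"""Compiled inner loop of the explicit march.

The march is inherently sequential in time and is called thousands of times
per least-squares fit, so the hot loop is JIT-compiled with numba.  The
numpy single-step functions in :mod:`capsuledry.solver` implement the same
stencils independently and serve as the cross-check for this kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def march(
    out_t,
    snaps,
    n_nodes,
    dl,
    thickness,
    m0,
    m_e,
    t_end,
    safety,
    eq_tol,
    d0,
    ea_rt,
    a,
    b,
    additive,
    floor,
    const_d,
    use_const,
    bcoeff,
    geom_g,
    max_steps,
):
    """Explicit time march writing interpolated snapshots into ``snaps``.

    Returns the first stability-limited step size [s], or -2.0 if the step
    budget was exhausted before reaching the last requested time (extreme
    stiffness: a fast boundary node pins the step while the interior barely
    moves).  Parameters mirror the solver options; ``ea_rt`` is Ea/(R*T)
    precomputed for the run's temperature.
    """
    z = n_nodes - 1
    values = np.full(n_nodes, m0)
    values[z] = m_e
    prev = values.copy()
    new = values.copy()
    nodal_d = np.empty(n_nodes)

    i_out = 0
    if out_t[0] == 0.0:
        for k in range(n_nodes):
            snaps[0, k] = values[k]
        i_out = 1

    denom = m0 - m_e
    t = 0.0
    dt_first = -1.0
    dl2 = dl * dl
    n_steps = 0
    while t < t_end and i_out < out_t.shape[0]:
        n_steps += 1
        if n_steps > max_steps:
            return -2.0
        d_max = 0.0
        if use_const:
            for k in range(n_nodes):
                nodal_d[k] = const_d
            d_max = const_d
        else:
            for k in range(n_nodes):
                m = values[k]
                if additive:
                    d = d0 * np.exp(-ea_rt) + a * m - b * m * m
                    if d < floor:
                        d = floor
                else:
                    d = d0 * np.exp(-ea_rt + a * m - b * m * m)
                nodal_d[k] = d
                if d > d_max:
                    d_max = d
        dt = safety * dl2 / (6.0 * d_max)
        if dt > t_end - t:
            dt = t_end - t
        if dt_first < 0.0:
            dt_first = dt

        for k in range(n_nodes):
            prev[k] = values[k]
        new[0] = values[0] + bcoeff * nodal_d[0] * dt / dl2 * (values[1] - values[0])
        for k in range(1, z):
            lap = (values[k + 1] - 2.0 * values[k] + values[k - 1]) / dl2
            grad_m = (values[k + 1] - values[k - 1]) / (2.0 * dl)
            grad_d = (nodal_d[k + 1] - nodal_d[k - 1]) / (2.0 * dl)
            upd = nodal_d[k] * lap + grad_d * grad_m
            if geom_g > 0.0:
                upd += geom_g * nodal_d[k] * grad_m / (k * dl)
            new[k] = values[k] + dt * upd
        new[z] = m_e
        for k in range(n_nodes):
            values[k] = new[k]
        t_prev = t
        t += dt

        while i_out < out_t.shape[0] and out_t[i_out] <= t:
            w = (out_t[i_out] - t_prev) / (t - t_prev)
            for k in range(n_nodes):
                snaps[i_out, k] = (1.0 - w) * prev[k] + w * values[k]
            i_out += 1

        if denom > 0.0:
            # trapezoid average for the early-equilibrium stop
            acc = 0.5 * (values[0] + values[z])
            for k in range(1, z):
                acc += values[k]
            avg = acc * dl / thickness
            if (avg - m_e) / denom < eq_tol:
                break
        else:
            break

    while i_out < out_t.shape[0]:
        for k in range(n_nodes):
            snaps[i_out, k] = values[k]
        i_out += 1
    return dt_first
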