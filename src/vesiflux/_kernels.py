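"""Numba inner loop of the overdamped Langevin simulator.

Positions are in micrometres and times in seconds.  The kernel advances
all vesicles with Euler–Maruyama steps, reflects them off the hard walls,
resolves hard-sphere overlaps by symmetric pushes, records membrane hits
and replaces absorbed vesicles, keeping the ensemble size constant.  All
randomness comes from numba's thread-local NumPy legacy RNG seeded once at
entry, so runs are bitwise reproducible for a given seed.
"""

import numpy as np
from numba import njit

# replacement modes
REPLACE_UNIFORM = 0
REPLACE_FACES = 1
REPLACE_FAR_WALL = 2


@njit(cache=True)
def _reflect_axis(x, lo, hi):
    # specular reflection; steps are tiny so one bounce suffices, but the
    # loop guards pathological inputs
    for _ in range(8):
        if x < lo:
            x = 2.0 * lo - x
        elif x > hi:
            x = 2.0 * hi - x
        else:
            break
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    return x


@njit(cache=True)
def _overlaps_any(pos, n, i, x, y, z, two_r, d2min):
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - x
        if dx > two_r or dx < -two_r:
            continue
        dy = pos[j, 1] - y
        dz = pos[j, 2] - z
        if dx * dx + dy * dy + dz * dz < d2min:
            return True
    return False


@njit(cache=True)
def _draw_replacement(pos, n, i, lo, hi, absorb_y, mode, interactions, two_r, d2min):
    """Sample a fresh non-overlapping position for an absorbed vesicle."""
    wx = hi[0] - lo[0]
    wz = hi[2] - lo[2]
    wy = hi[1] - absorb_y
    a_top = wx * wz
    a_xf = wz * wy  # each of the two faces normal to x
    a_zf = wx * wy
    total = a_top + 2.0 * a_xf + 2.0 * a_zf
    for _ in range(10000):
        if mode == REPLACE_UNIFORM:
            x = lo[0] + wx * np.random.random()
            y = absorb_y + wy * np.random.random()
            z = lo[2] + wz * np.random.random()
        elif mode == REPLACE_FAR_WALL:
            x = lo[0] + wx * np.random.random()
            y = hi[1]
            z = lo[2] + wz * np.random.random()
        else:  # REPLACE_FACES: area-weighted point on the five hard faces
            u = total * np.random.random()
            if u < a_top:
                x = lo[0] + wx * np.random.random()
                y = hi[1]
                z = lo[2] + wz * np.random.random()
            elif u < a_top + 2.0 * a_xf:
                x = lo[0] if u < a_top + a_xf else hi[0]
                y = absorb_y + wy * np.random.random()
                z = lo[2] + wz * np.random.random()
            else:
                x = lo[0] + wx * np.random.random()
                y = absorb_y + wy * np.random.random()
                z = lo[2] if u < a_top + 2.0 * a_xf + a_zf else hi[2]
        if y <= absorb_y:
            continue
        if interactions and _overlaps_any(pos, n, i, x, y, z, two_r, d2min):
            continue
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z
        return True
    return False


@njit(cache=True)
def _resolve_overlaps(pos, n, lo, hi, absorb_y, membrane_reflecting, two_r, max_sweeps):
    """Push overlapping pairs apart symmetrically to contact distance.

    Returns the number of pairs still overlapping after the last sweep.
    """
    d2min = two_r * two_r
    remaining = 0
    for _ in range(max_sweeps):
        remaining = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[j, 0] - pos[i, 0]
                if dx > two_r or dx < -two_r:
                    continue
                dy = pos[j, 1] - pos[i, 1]
                if dy > two_r or dy < -two_r:
                    continue
                dz = pos[j, 2] - pos[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 >= d2min:
                    continue
                remaining += 1
                d = np.sqrt(d2)
                if d < 1e-12:
                    ux, uy, uz = 1.0, 0.0, 0.0
                    d = 0.0
                else:
                    ux, uy, uz = dx / d, dy / d, dz / d
                push = 0.5 * (two_r - d)
                pos[i, 0] = _reflect_axis(pos[i, 0] - push * ux, lo[0], hi[0])
                pos[j, 0] = _reflect_axis(pos[j, 0] + push * ux, lo[0], hi[0])
                pos[i, 2] = _reflect_axis(pos[i, 2] - push * uz, lo[2], hi[2])
                pos[j, 2] = _reflect_axis(pos[j, 2] + push * uz, lo[2], hi[2])
                yi = pos[i, 1] - push * uy
                yj = pos[j, 1] + push * uy
                if membrane_reflecting:
                    yi = _reflect_axis(yi, lo[1], hi[1])
                    yj = _reflect_axis(yj, lo[1], hi[1])
                else:
                    if yi > hi[1]:
                        yi = 2.0 * hi[1] - yi
                    if yj > hi[1]:
                        yj = 2.0 * hi[1] - yj
                pos[i, 1] = yi
                pos[j, 1] = yj
        if remaining == 0:
            break
    return remaining


@njit(cache=True)
def simulate_kernel(seed, pos, t_start, lo, hi, absorb_y, step_std, k_drift, y0,
                    dt, two_r, interactions, membrane_reflecting, replace_mode,
                    max_events, max_steps, events_out):
    """Advance the ensemble; returns (n_events, t_end, unresolved, steps_done).

    ``pos`` is updated in place.  Multiple hits within one step receive
    evenly spaced sub-step timestamps (in vesicle order) so that event
    times are strictly increasing.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_events = 0
    unresolved = 0
    t = t_start
    d2min = two_r * two_r
    hits = np.empty(n, dtype=np.int64)
    step = 0
    for step in range(max_steps):
        t_prev = t
        t = t_start + (step + 1) * dt
        for i in range(n):
            gx = np.random.normal()
            gy = np.random.normal()
            gz = np.random.normal()
            x = pos[i, 0] + step_std * gx
            y = pos[i, 1] + step_std * gy - k_drift * (pos[i, 1] - y0) * dt
            z = pos[i, 2] + step_std * gz
            pos[i, 0] = _reflect_axis(x, lo[0], hi[0])
            pos[i, 2] = _reflect_axis(z, lo[2], hi[2])
            if membrane_reflecting:
                y = _reflect_axis(y, lo[1], hi[1])
            elif y > hi[1]:
                y = 2.0 * hi[1] - y
            pos[i, 1] = y
        if interactions:
            unresolved += _resolve_overlaps(pos, n, lo, hi, absorb_y,
                                            membrane_reflecting, two_r, 10)
        if membrane_reflecting:
            continue
        m = 0
        for i in range(n):
            if pos[i, 1] <= absorb_y:
                hits[m] = i
                m += 1
        if m > 0:
            for j in range(m):
                i = hits[j]
                if n_events < max_events:
                    events_out[n_events] = t_prev + dt * (j + 1.0) / (m + 1.0)
                    n_events += 1
                if not _draw_replacement(pos, n, i, lo, hi, absorb_y,
                                         replace_mode, interactions, two_r, d2min):
                    return n_events, t, unresolved, step + 1
            if n_events >= max_events:
                return n_events, t, unresolved, step + 1
    return n_events, t, unresolved, step + 1
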