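"""Numba-compiled single-scattering transport kernels.

These kernels are the hot path: free flight lengths sampled from the local
elastic mean free path, continuous (CSDA) energy loss along each flight,
screened-Rutherford polar deflections with uniform azimuth, and step
truncation at material boundaries (the remaining flight is resampled in the
new material, which is exact for the memoryless exponential).

Geometry comes in two flavors selected by ``geom_mode``:

* 1 — analytic: a matrix half-space (0 <= z < zmax) containing axis-aligned
  boxes, first match wins;
* 2 — voxelized: a 3-D grid of material indices with lateral clamping,
  ``zmax`` at the bottom of the grid.

Fate codes: 0 = absorbed, 1 = backscattered (crossed z = 0), 2 = transmitted
(crossed z = zmax).  Randomness is numba's thread-local ``np.random``; image
kernels hold one xorshift128+ stream per pixel, seeded by splitmix64 from
(seed, pixel index), so per-pixel results are independent of scan order.

Inverse mean free paths and stopping powers are tabulated per material on a
log-energy grid by :func:`blockface.mc.pack_materials` (from the same
closed-form physics as :mod:`blockface.xsections`) and linearly interpolated
here; scattering-element selection and angle sampling use the closed forms
directly.
"""

import math

import numpy as np
from numba import njit

_BIG = 1e30
_EPS = 1e-6  # nm nudge across boundaries


@njit(cache=True)
def _splitmix64(x):
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def seed_stream(st, seed, stream):
    """Initialize an xorshift128+ state from (seed, stream id) via splitmix64,
    so streams are independent of any execution schedule."""
    h = _splitmix64(np.uint64(seed) ^ (np.uint64(stream) * np.uint64(0xD2B74407B1CE6E93)))
    st[0] = _splitmix64(h) | np.uint64(1)
    st[1] = _splitmix64(h + np.uint64(1)) | np.uint64(1)


@njit(cache=True)
def _rand(st):
    """xorshift128+ uniform double in [0, 1)."""
    x = st[0]
    y = st[1]
    st[0] = y
    x ^= x << np.uint64(23)
    st[1] = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    return float((st[1] + y) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _rel2(e_kev):
    r = (e_kev + 511.0) / (e_kev + 1024.0)
    return r * r


@njit(cache=True)
def _table_lookup(loge, loge0, inv_dloge, table, mi):
    # linear interpolation on the per-material log-energy grid
    u = (loge - loge0) * inv_dloge
    n = table.shape[1]
    if u <= 0.0:
        return table[mi, 0]
    if u >= n - 1.0:
        return table[mi, n - 1]
    i = int(u)
    f = u - i
    return table[mi, i] * (1.0 - f) + table[mi, i + 1] * f


@njit(cache=True)
def _material_at(
    x, y, z, geom_mode, boxes, matrix_idx, vox, vx0, vy0, vh
):
    if geom_mode == 2:
        ix = int((x - vx0) / vh)
        iy = int((y - vy0) / vh)
        iz = int(z / vh)
        nx, ny, nz = vox.shape
        if ix < 0:
            ix = 0
        elif ix >= nx:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy >= ny:
            iy = ny - 1
        if iz < 0:
            iz = 0
        elif iz >= nz:
            iz = nz - 1
        return vox[ix, iy, iz]
    for b in range(boxes.shape[0]):
        if (
            boxes[b, 0] <= x < boxes[b, 1]
            and boxes[b, 2] <= y < boxes[b, 3]
            and boxes[b, 4] <= z < boxes[b, 5]
        ):
            return np.int64(boxes[b, 6])
    return matrix_idx


@njit(cache=True)
def _dist_to_boundary(
    x, y, z, dx, dy, dz, geom_mode, boxes, zmax, vx0, vy0, vh
):
    t = _BIG
    if dz < -1e-12:
        tt = -z / dz
        if tt < t:
            t = tt
    if dz > 1e-12 and zmax < _BIG:
        tt = (zmax - z) / dz
        if tt < t:
            t = tt
    if geom_mode == 2:
        # next voxel plane on each axis
        for ax in range(3):
            if ax == 0:
                p, d, o = x, dx, vx0
            elif ax == 1:
                p, d, o = y, dy, vy0
            else:
                p, d, o = z, dz, 0.0
            if d > 1e-12:
                plane = (math.floor((p - o) / vh) + 1.0) * vh + o
                tt = (plane - p) / d
            elif d < -1e-12:
                plane = math.floor((p - o) / vh) * vh + o
                tt = (plane - p) / d
            else:
                tt = _BIG
            if tt < 1e-9:
                tt = 1e-9
            if tt < t:
                t = tt
        return t
    for b in range(boxes.shape[0]):
        tin = -_BIG
        tout = _BIG
        hit = True
        for ax in range(3):
            if ax == 0:
                p, d, lo, hi = x, dx, boxes[b, 0], boxes[b, 1]
            elif ax == 1:
                p, d, lo, hi = y, dy, boxes[b, 2], boxes[b, 3]
            else:
                p, d, lo, hi = z, dz, boxes[b, 4], boxes[b, 5]
            if abs(d) < 1e-12:
                if p < lo or p >= hi:
                    hit = False
                    break
            else:
                t1 = (lo - p) / d
                t2 = (hi - p) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tin:
                    tin = t1
                if t2 < tout:
                    tout = t2
        if not hit or tin >= tout or tout <= 1e-12:
            continue
        cand = tin if tin > 1e-12 else tout
        if cand < t:
            t = cand
    return t


@njit(cache=True)
def _trace_one(
    st,
    x,
    y,
    z,
    dx,
    dy,
    dz,
    e_ev,
    cutoff_ev,
    geom_mode,
    boxes,
    matrix_idx,
    zmax,
    vox,
    vx0,
    vy0,
    vh,
    mat_nel,
    mat_alpha,
    mat_q,
    loge0,
    inv_dloge,
    inv_tab,
    stop_tab,
):
    max_depth = z if z > 0.0 else 0.0
    while True:
        if e_ev <= cutoff_ev:
            return 0, e_ev, dz, max_depth
        mi = _material_at(x, y, z, geom_mode, boxes, matrix_idx, vox, vx0, vy0, vh)
        e_kev = e_ev * 1e-3
        loge = math.log(e_ev)
        inv = _table_lookup(loge, loge0, inv_dloge, inv_tab, mi)
        lam = _BIG if inv <= 1e-30 else 1.0 / inv
        u = _rand(st)
        s = -lam * math.log(1.0 - u)
        tb = _dist_to_boundary(
            x, y, z, dx, dy, dz, geom_mode, boxes, zmax, vx0, vy0, vh
        )
        scatter = s < tb
        step = s if scatter else tb + _EPS
        de = _table_lookup(loge, loge0, inv_dloge, stop_tab, mi)
        if de * step >= e_ev - cutoff_ev:
            # ran out of energy mid-flight: stop where the CSDA budget ends
            travel = (e_ev - cutoff_ev) / de if de > 0.0 else step
            if travel > step:
                travel = step
            z += dz * travel
            if z > max_depth:
                max_depth = z
            return 0, cutoff_ev, dz, max_depth
        x += dx * step
        y += dy * step
        z += dz * step
        e_ev -= de * step
        if z > max_depth:
            max_depth = z
        if z <= 0.0:
            return 1, e_ev, dz, max_depth
        if z >= zmax:
            return 2, e_ev, dz, max_depth
        if scatter:
            # pick the scattering element with probability n_i sigma_i / sum
            wsum = 0.0
            for k in range(mat_nel[mi]):
                a = mat_alpha[mi, k] / e_kev
                wsum += mat_q[mi, k] / (a * (1.0 + a))
            r = _rand(st) * wsum
            acc = 0.0
            ksel = 0
            for k in range(mat_nel[mi]):
                a = mat_alpha[mi, k] / e_kev
                acc += mat_q[mi, k] / (a * (1.0 + a))
                if r <= acc:
                    ksel = k
                    break
            a = mat_alpha[mi, ksel] / e_kev
            u2 = _rand(st)
            cos_t = 1.0 - 2.0 * a * u2 / (1.0 + a - u2)
            if cos_t > 1.0:
                cos_t = 1.0
            elif cos_t < -1.0:
                cos_t = -1.0
            sin_t = math.sqrt(1.0 - cos_t * cos_t)
            # uniform azimuth without trig: rejection-sample a unit vector
            while True:
                vx = 2.0 * _rand(st) - 1.0
                vy = 2.0 * _rand(st) - 1.0
                rr = vx * vx + vy * vy
                if 1e-12 < rr <= 1.0:
                    break
            rn = 1.0 / math.sqrt(rr)
            cos_p = vx * rn
            sin_p = vy * rn
            if abs(dz) > 0.999999:
                sign = 1.0 if dz > 0.0 else -1.0
                dx = sin_t * cos_p
                dy = sin_t * sin_p
                dz = cos_t * sign
            else:
                den = math.sqrt(1.0 - dz * dz)
                nx = dx * cos_t + sin_t * (dx * dz * cos_p - dy * sin_p) / den
                ny = dy * cos_t + sin_t * (dy * dz * cos_p + dx * sin_p) / den
                nz = dz * cos_t - sin_t * cos_p * den
                dx, dy, dz = nx, ny, nz
            norm = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= norm
            dy /= norm
            dz /= norm


@njit(cache=True)
def trace_batch(
    n,
    x0,
    y0,
    d0x,
    d0y,
    d0z,
    e0_ev,
    cutoff_ev,
    geom_mode,
    boxes,
    matrix_idx,
    zmax,
    vox,
    vx0,
    vy0,
    vh,
    mat_nel,
    mat_alpha,
    mat_q,
    loge0,
    inv_dloge,
    inv_tab,
    stop_tab,
    seed,
):
    """Trace ``n`` trajectories from one beam position; returns per-trajectory
    (fate, exit/final energy, final direction z-component, max depth)."""
    fates = np.empty(n, np.int8)
    e_out = np.empty(n, np.float64)
    dz_out = np.empty(n, np.float64)
    depth = np.empty(n, np.float64)
    st = np.empty(2, np.uint64)
    seed_stream(st, seed, 0)
    for i in range(n):
        f, e, dzx, md = _trace_one(
            st,
            x0,
            y0,
            0.0,
            d0x,
            d0y,
            d0z,
            e0_ev,
            cutoff_ev,
            geom_mode,
            boxes,
            matrix_idx,
            zmax,
            vox,
            vx0,
            vy0,
            vh,
            mat_nel,
            mat_alpha,
            mat_q,
            loge0,
            inv_dloge,
            inv_tab,
            stop_tab,
        )
        fates[i] = f
        e_out[i] = e
        dz_out[i] = dzx
        depth[i] = md
    return fates, e_out, dz_out, depth


@njit(cache=True)
def render_counts(
    xs,
    ys,
    n_traj,
    d0x,
    d0y,
    d0z,
    e0_ev,
    cutoff_ev,
    grid_v,
    cos_lo,
    cos_hi,
    geom_mode,
    boxes,
    matrix_idx,
    zmax,
    vox,
    vx0,
    vy0,
    vh,
    mat_nel,
    mat_alpha,
    mat_q,
    loge0,
    inv_dloge,
    inv_tab,
    stop_tab,
    seed,
):
    """Per-pixel detected and total backscatter counts.

    A backscattered electron is detected when its exit energy is at least the
    grid voltage (in eV) and the cosine of its exit polar angle (measured from
    the outward surface normal) lies in [cos_lo, cos_hi].
    """
    npx = xs.size
    accepted = np.zeros(npx, np.int64)
    total = np.zeros(npx, np.int64)
    st = np.empty(2, np.uint64)
    for p in range(npx):
        seed_stream(st, seed, p)
        for _ in range(n_traj):
            f, e, dzx, _md = _trace_one(
                st,
                xs[p],
                ys[p],
                0.0,
                d0x,
                d0y,
                d0z,
                e0_ev,
                cutoff_ev,
                geom_mode,
                boxes,
                matrix_idx,
                zmax,
                vox,
                vx0,
                vy0,
                vh,
                mat_nel,
                mat_alpha,
                mat_q,
                loge0,
                inv_dloge,
                inv_tab,
                stop_tab,
            )
            if f == 1:
                total[p] += 1
                c = -dzx
                if e >= grid_v and cos_lo <= c <= cos_hi:
                    accepted[p] += 1
    return accepted, total
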