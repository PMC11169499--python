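"""Compiled inner loops for particle advection.

The tracker's public semantics live in :mod:`particle_tracker`; these
kernels reproduce its RK4 step exactly (same interpolation, nesting,
exit, land and reflection rules) but advance whole sub-step chunks per
call, which is what makes multi-seed experiments tractable.  Grid axes
are uniformly spaced (enforced by GridSpec), so index location is
arithmetic; layer midpoints may be non-uniform and are searched.

An equivalence test pins these kernels against the vectorized numpy
reference step.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def _sample_one(
    u, v, w, t0, dt, x0, dx, y0, dy, zmid, is3d,
    tq, xq, yq, zq,
):
    """Multilinear sample of one field at one point; mirrors _interp_field."""
    nt, nk, ny, nx = u.shape
    ft = (tq - t0) / dt
    it = int(np.floor(ft))
    if it < 0:
        it = 0
    elif it > nt - 2:
        it = nt - 2
    ft = ft - it
    fx = (xq - x0) / dx
    ix = int(np.floor(fx))
    if ix < 0:
        ix = 0
    elif ix > nx - 2:
        ix = nx - 2
    fx = fx - ix
    if fx < 0.0:
        fx = 0.0
    elif fx > 1.0:
        fx = 1.0
    fy = (yq - y0) / dy
    iy = int(np.floor(fy))
    if iy < 0:
        iy = 0
    elif iy > ny - 2:
        iy = ny - 2
    fy = fy - iy
    if fy < 0.0:
        fy = 0.0
    elif fy > 1.0:
        fy = 1.0
    iz = 0
    fz = 0.0
    if is3d and nk > 1:
        # manual searchsorted over layer midpoints (possibly non-uniform)
        iz = 0
        while iz < nk - 2 and zq > zmid[iz + 1]:
            iz += 1
        fz = (zq - zmid[iz]) / (zmid[iz + 1] - zmid[iz])
        if fz < 0.0:
            fz = 0.0
        elif fz > 1.0:
            fz = 1.0
    iz1 = iz + 1 if iz + 1 < nk else iz
    uu = 0.0
    vv = 0.0
    ww = 0.0
    for a in range(2):
        wt = ft if a == 1 else 1.0 - ft
        ta = it + a
        for b in range(2):
            wz = fz if b == 1 else 1.0 - fz
            if wz == 0.0:
                continue
            kb = iz1 if b == 1 else iz
            for c in range(2):
                wy = fy if c == 1 else 1.0 - fy
                yc = iy + c
                for d in range(2):
                    wx = fx if d == 1 else 1.0 - fx
                    xd = ix + d
                    wgt = wt * wz * wy * wx
                    if wgt == 0.0:
                        continue
                    uu += wgt * u[ta, kb, yc, xd]
                    vv += wgt * v[ta, kb, yc, xd]
                    if is3d:
                        ww += wgt * w[ta, kb, yc, xd]
    return uu, vv, ww


@njit(cache=False, fastmath=False)
def _bilinear(depth, x0, dx, y0, dy, xq, yq):
    ny, nx = depth.shape
    fx = (xq - x0) / dx
    ix = int(np.floor(fx))
    if ix < 0:
        ix = 0
    elif ix > nx - 2:
        ix = nx - 2
    fx = min(max(fx - ix, 0.0), 1.0)
    fy = (yq - y0) / dy
    iy = int(np.floor(fy))
    if iy < 0:
        iy = 0
    elif iy > ny - 2:
        iy = ny - 2
    fy = min(max(fy - iy, 0.0), 1.0)
    return (
        (1 - fy) * (1 - fx) * depth[iy, ix]
        + (1 - fy) * fx * depth[iy, ix + 1]
        + fy * (1 - fx) * depth[iy + 1, ix]
        + fy * fx * depth[iy + 1, ix + 1]
    )


@njit(cache=False, fastmath=False)
def advect_chunk(
    x, y, z, t,
    n_sub, dt_seconds, is3d,
    # fine field
    fu, fv, fw, f_t0, f_dt, f_x0, f_dx, f_y0, f_dy, f_zmid, f_land,
    # coarse field
    cu, cv, cw, c_t0, c_dt, c_x0, c_dx, c_y0, c_dy, c_zmid, c_land,
    fb, cb,  # fine / coarse bounds (xmin, xmax, ymin, ymax)
    t_lo, t_hi,  # overlapping time coverage
    bath, b_x0, b_dx, b_y0, b_dy, has_bath,
    exited,
):
    """Advance each particle ``n_sub`` RK4 steps in place.

    ``exited[i]`` is set when any stage or step endpoint leaves the
    coarse bounds or the time coverage; that particle stops moving.
    A step ending on a land cell is rejected (position kept).
    """
    dt_h = dt_seconds / 3600.0
    n = x.size
    for i in range(n):
        xi = x[i]
        yi = y[i]
        zi = z[i]
        ti = t[i]
        ex = False
        for s in range(n_sub):
            kx = np.empty(4)
            ky = np.empty(4)
            kz = np.empty(4)
            px = xi
            py = yi
            pz = zi
            for stage in range(4):
                if stage == 1 or stage == 2:
                    frac = 0.5
                elif stage == 3:
                    frac = 1.0
                else:
                    frac = 0.0
                tq = ti + frac * dt_h
                # 1e-6 h tolerance absorbs float accumulation at coverage edges
                if (
                    px < cb[0] or px > cb[1] or py < cb[2] or py > cb[3]
                    or tq < t_lo - 1e-6 or tq > t_hi + 1e-6
                ):
                    ex = True
                    break
                if fb[0] <= px <= fb[1] and fb[2] <= py <= fb[3]:
                    uu, vv, ww = _sample_one(
                        fu, fv, fw, f_t0, f_dt, f_x0, f_dx, f_y0, f_dy,
                        f_zmid, is3d, tq, px, py, pz,
                    )
                else:
                    uu, vv, ww = _sample_one(
                        cu, cv, cw, c_t0, c_dt, c_x0, c_dx, c_y0, c_dy,
                        c_zmid, is3d, tq, px, py, pz,
                    )
                kx[stage] = uu
                ky[stage] = vv
                kz[stage] = ww
                if stage < 3:
                    adv = dt_seconds * (0.5 if stage < 2 else 1.0)
                    px = xi + adv * kx[stage]
                    py = yi + adv * ky[stage]
                    pz = zi + adv * kz[stage] if is3d else zi
            if ex:
                break
            nx_ = xi + dt_seconds / 6.0 * (kx[0] + 2 * kx[1] + 2 * kx[2] + kx[3])
            ny_ = yi + dt_seconds / 6.0 * (ky[0] + 2 * ky[1] + 2 * ky[2] + ky[3])
            if is3d:
                nz_ = zi + dt_seconds / 6.0 * (kz[0] + 2 * kz[1] + 2 * kz[2] + kz[3])
                if nz_ < 0.0:
                    nz_ = -nz_
                if has_bath:
                    seabed = _bilinear(bath, b_x0, b_dx, b_y0, b_dy, nx_, ny_)
                    if nz_ > seabed:
                        nz_ = 2.0 * seabed - nz_
                    if nz_ < 0.0:
                        nz_ = 0.0
            else:
                nz_ = zi
            if nx_ < cb[0] or nx_ > cb[1] or ny_ < cb[2] or ny_ > cb[3]:
                ex = True
                break
            # land rejection: keep the previous position this step
            if fb[0] <= nx_ <= fb[1] and fb[2] <= ny_ <= fb[3]:
                gx = int(np.floor((nx_ - f_x0) / f_dx))
                gy = int(np.floor((ny_ - f_y0) / f_dy))
                gx = min(max(gx, 0), f_land.shape[1] - 2)
                gy = min(max(gy, 0), f_land.shape[0] - 2)
                landed = f_land[gy, gx]
            else:
                gx = int(np.floor((nx_ - c_x0) / c_dx))
                gy = int(np.floor((ny_ - c_y0) / c_dy))
                gx = min(max(gx, 0), c_land.shape[1] - 2)
                gy = min(max(gy, 0), c_land.shape[0] - 2)
                landed = c_land[gy, gx]
            if not landed:
                xi = nx_
                yi = ny_
                zi = nz_
            ti = ti + dt_h
        x[i] = xi
        y[i] = yi
        z[i] = zi
        t[i] = ti
        exited[i] = ex
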