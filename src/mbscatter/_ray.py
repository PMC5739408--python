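"""Shared Siddon-style ray tracer used by both the acquisition simulator and ART.

All rays are traced through an axis-aligned voxel grid with the
Amanatides-Woo incremental traversal; the per-voxel intersection lengths are
exact for the parametric decomposition of the ray, so the same kernel serves
as the forward projector A and as the row generator a_ij of the Kaczmarz
update (one ray = one matrix row, computed on demand).

Coordinates are in mm; the voxel grid is indexed (x, y, z) with the rotation
axis along z.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _ray_hits(nx, ny, nz, ox, oy, oz, vs,
              sx, sy, sz, ex, ey, ez, idx_buf, len_buf):
    """Voxel indices and intersection lengths for one ray (source -> end).

    Returns the number of intersected voxels; flat indices (C order over
    (nx, ny, nz)) in ``idx_buf`` and lengths in mm in ``len_buf``.
    """
    rx = ex - sx
    ry = ey - sy
    rz = ez - sz
    length = (rx * rx + ry * ry + rz * rz) ** 0.5
    if length < _EPS:
        return 0

    tmin = 0.0
    tmax = 1.0
    # slab clipping against the grid bounding box
    if abs(rx) < _EPS:
        if sx < ox or sx > ox + nx * vs:
            return 0
    else:
        t0 = (ox - sx) / rx
        t1 = (ox + nx * vs - sx) / rx
        if t0 > t1:
            t0, t1 = t1, t0
        if t0 > tmin:
            tmin = t0
        if t1 < tmax:
            tmax = t1
    if abs(ry) < _EPS:
        if sy < oy or sy > oy + ny * vs:
            return 0
    else:
        t0 = (oy - sy) / ry
        t1 = (oy + ny * vs - sy) / ry
        if t0 > t1:
            t0, t1 = t1, t0
        if t0 > tmin:
            tmin = t0
        if t1 < tmax:
            tmax = t1
    if abs(rz) < _EPS:
        if sz < oz or sz > oz + nz * vs:
            return 0
    else:
        t0 = (oz - sz) / rz
        t1 = (oz + nz * vs - sz) / rz
        if t0 > t1:
            t0, t1 = t1, t0
        if t0 > tmin:
            tmin = t0
        if t1 < tmax:
            tmax = t1
    if tmin >= tmax:
        return 0

    t = tmin
    px = sx + t * rx
    py = sy + t * ry
    pz = sz + t * rz
    ix = int(np.floor((px - ox) / vs))
    iy = int(np.floor((py - oy) / vs))
    iz = int(np.floor((pz - oz) / vs))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    if iz > nz - 1:
        iz = nz - 1

    if rx > 0.0:
        stepx = 1
        tx = (ox + (ix + 1) * vs - sx) / rx
        dtx = vs / rx
    elif rx < 0.0:
        stepx = -1
        tx = (ox + ix * vs - sx) / rx
        dtx = -vs / rx
    else:
        stepx = 0
        tx = np.inf
        dtx = np.inf
    if ry > 0.0:
        stepy = 1
        ty = (oy + (iy + 1) * vs - sy) / ry
        dty = vs / ry
    elif ry < 0.0:
        stepy = -1
        ty = (oy + iy * vs - sy) / ry
        dty = -vs / ry
    else:
        stepy = 0
        ty = np.inf
        dty = np.inf
    if rz > 0.0:
        stepz = 1
        tz = (oz + (iz + 1) * vs - sz) / rz
        dtz = vs / rz
    elif rz < 0.0:
        stepz = -1
        tz = (oz + iz * vs - sz) / rz
        dtz = -vs / rz
    else:
        stepz = 0
        tz = np.inf
        dtz = np.inf

    n = 0
    while True:
        tnext = tmax
        if tx < tnext:
            tnext = tx
        if ty < tnext:
            tnext = ty
        if tz < tnext:
            tnext = tz
        seg = (tnext - t) * length
        if seg > _EPS:
            idx_buf[n] = (ix * ny + iy) * nz + iz
            len_buf[n] = seg
            n += 1
        if tnext >= tmax - _EPS:
            break
        if tx <= tnext + _EPS:
            ix += stepx
            tx += dtx
        if ty <= tnext + _EPS:
            iy += stepy
            ty += dty
        if tz <= tnext + _EPS:
            iz += stepz
            tz += dtz
        t = tnext
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            break
    return n


@njit(cache=True)
def forward_view_kernel(mu_flat, nx, ny, nz, ox, oy, oz, vs,
                        sx, sy, sz, pix, out):
    """Line integrals of mu for every detector pixel of one view."""
    nrows, ncols = out.shape
    bufsize = 3 * (nx + ny + nz) + 8
    idx_buf = np.empty(bufsize, np.int64)
    len_buf = np.empty(bufsize, np.float64)
    for r in range(nrows):
        for c in range(ncols):
            n = _ray_hits(nx, ny, nz, ox, oy, oz, vs,
                          sx, sy, sz,
                          pix[r, c, 0], pix[r, c, 1], pix[r, c, 2],
                          idx_buf, len_buf)
            acc = 0.0
            for k in range(n):
                acc += len_buf[k] * mu_flat[idx_buf[k]]
            out[r, c] = acc


@njit(cache=True)
def art_view_kernel(mu_flat, nx, ny, nz, ox, oy, oz, vs,
                    sx, sy, sz, pix, p, valid, lam):
    """One sequential Kaczmarz sweep over the valid rays of a single view.

    mu <- mu + lam * a_ij * (p_j - <a_j, mu>) / <a_j, a_j>, ray by ray,
    in row-major detector order.  Returns (sum of squared pre-update
    residuals, rays used, rays skipped for zero row norm).
    """
    nrows, ncols = p.shape
    bufsize = 3 * (nx + ny + nz) + 8
    idx_buf = np.empty(bufsize, np.int64)
    len_buf = np.empty(bufsize, np.float64)
    resid_sq = 0.0
    used = 0
    skipped = 0
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            n = _ray_hits(nx, ny, nz, ox, oy, oz, vs,
                          sx, sy, sz,
                          pix[r, c, 0], pix[r, c, 1], pix[r, c, 2],
                          idx_buf, len_buf)
            norm_sq = 0.0
            fwd = 0.0
            for k in range(n):
                a = len_buf[k]
                norm_sq += a * a
                fwd += a * mu_flat[idx_buf[k]]
            if norm_sq <= 0.0:
                skipped += 1
                continue
            resid = p[r, c] - fwd
            resid_sq += resid * resid
            used += 1
            coef = lam * resid / norm_sq
            for k in range(n):
                mu_flat[idx_buf[k]] += coef * len_buf[k]
    return resid_sq, used, skipped


def ray_hits(nx, ny, nz, origin, voxel_size, src, end):
    """Python-facing single-ray tracer: (flat voxel indices, lengths mm)."""
    bufsize = 3 * (nx + ny + nz) + 8
    idx_buf = np.empty(bufsize, np.int64)
    len_buf = np.empty(bufsize, np.float64)
    n = _ray_hits(nx, ny, nz,
                  float(origin[0]), float(origin[1]), float(origin[2]),
                  float(voxel_size),
                  float(src[0]), float(src[1]), float(src[2]),
                  float(end[0]), float(end[1]), float(end[2]),
                  idx_buf, len_buf)
    return idx_buf[:n].copy(), len_buf[:n].copy()
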