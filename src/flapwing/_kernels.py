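"""Numba kernels for the D3Q27 update and the virtual-flux boundary.

Distributions are stored as ``f[i, j, k, alpha]`` (27 contiguous per node).
Streaming always wraps periodically on the padded array: for non-periodic
faces the wrap only moves values between ghost cells, which are refilled by
the boundary conditions every step before streaming.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fastmath is enabled only on the two bulk kernels: results remain
# deterministic for a given build, which is what the restart contract needs


@njit(cache=True, fastmath=True)
def collide_stream(f, fnew, tau, ex, ey, ez, w):
    """Fused BGK collision + streaming over the whole (padded) array."""
    nx, ny, nz, q = f.shape
    om = 1.0 - 1.0 / tau
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = 0.0
                ux = 0.0
                uy = 0.0
                uz = 0.0
                for a in range(q):
                    v = f[i, j, k, a]
                    p += v
                    ux += ex[a] * v
                    uy += ey[a] * v
                    uz += ez[a] * v
                ux *= 3.0
                uy *= 3.0
                uz *= 3.0
                u2 = ux * ux + uy * uy + uz * uz
                for a in range(q):
                    eu = ex[a] * ux + ey[a] * uy + ez[a] * uz
                    feq = w[a] * (p + eu + 1.5 * eu * eu - 0.5 * u2)
                    out = feq + om * (f[i, j, k, a] - feq)
                    ii = i + ex[a]
                    jj = j + ey[a]
                    kk = k + ez[a]
                    if ii < 0:
                        ii = nx - 1
                    elif ii >= nx:
                        ii = 0
                    if jj < 0:
                        jj = ny - 1
                    elif jj >= ny:
                        jj = 0
                    if kk < 0:
                        kk = nz - 1
                    elif kk >= nz:
                        kk = 0
                    fnew[ii, jj, kk, a] = out


@njit(cache=True, fastmath=True)
def macro_fields(f, ex, ey, ez, p, ux, uy, uz):
    nx, ny, nz, q = f.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                s = 0.0
                sx = 0.0
                sy = 0.0
                sz = 0.0
                for a in range(q):
                    v = f[i, j, k, a]
                    s += v
                    sx += ex[a] * v
                    sy += ey[a] * v
                    sz += ez[a] * v
                p[i, j, k] = s
                ux[i, j, k] = 3.0 * sx
                uy[i, j, k] = 3.0 * sy
                uz[i, j, k] = 3.0 * sz


@njit(cache=True)
def find_crossings(
    i0, i1, j0, j1, k0, k1,
    ox, oy, oz, dx,
    ex, ey, ez,
    rox, roy, roz,      # rectangle origin corner
    e1x, e1y, e1z,      # unit span direction
    e2x, e2y, e2z,      # unit chord direction
    span, chord,
    nxp, nyp, nzp,      # unit rectangle normal
    ci, cj, ck, calpha, ca, cside, cvx, cvy, cvz,
    cut,
):
    """Collect lattice links crossing the rectangle inside the index box.

    Writes one record per (node, direction) whose link to the neighbour pierces
    the rectangle; ``cside`` is +1 if the node lies on the +normal side.  Also
    marks ``cut[i, j, k, a]`` for every cut link.  Returns the record count.
    """
    q = len(ex)
    m = 0
    eps = 1e-12
    for i in range(i0, i1):
        for j in range(j0, j1):
            for k in range(k0, k1):
                px = ox + i * dx
                py = oy + j * dx
                pz = oz + k * dx
                dpx = px - rox
                dpy = py - roy
                dpz = pz - roz
                dn = dpx * nxp + dpy * nyp + dpz * nzp
                for a in range(1, q):
                    en = (ex[a] * nxp + ey[a] * nyp + ez[a] * nzp) * dx
                    if en > -eps and en < eps:
                        continue
                    t = -dn / en
                    # t == 0 (node on the plate) is legal: the reconstruction
                    # falls back to the next node C; t == 1 belongs to the
                    # neighbour's own record
                    if t < 0.0 or t > 1.0 - 1e-9:
                        continue
                    # crossing point
                    vx = px + t * ex[a] * dx
                    vy = py + t * ey[a] * dx
                    vz = pz + t * ez[a] * dx
                    rx = vx - rox
                    ry = vy - roy
                    rz = vz - roz
                    s1 = rx * e1x + ry * e1y + rz * e1z
                    if s1 < 0.0 or s1 > span:
                        continue
                    s2 = rx * e2x + ry * e2y + rz * e2z
                    if s2 < 0.0 or s2 > chord:
                        continue
                    ci[m] = i
                    cj[m] = j
                    ck[m] = k
                    calpha[m] = a
                    ca[m] = t
                    if dn > 0.0:
                        cside[m] = 1.0
                    elif dn < 0.0:
                        cside[m] = -1.0
                    else:
                        # node exactly on the plate: the fluid side for this
                        # link is opposite the link direction
                        cside[m] = 1.0 if en < 0.0 else -1.0
                    cvx[m] = vx
                    cvy[m] = vy
                    cvz[m] = vz
                    cut[i, j, k, a] = True
                    m += 1
    return m


@njit(cache=True, inline="always")
def _trilinear(arr, gx, gy, gz):
    """Trilinear sample of a 3-D array at fractional grid coordinates."""
    nx, ny, nz = arr.shape
    i = int(np.floor(gx))
    j = int(np.floor(gy))
    k = int(np.floor(gz))
    if i < 0:
        i = 0
    elif i > nx - 2:
        i = nx - 2
    if j < 0:
        j = 0
    elif j > ny - 2:
        j = ny - 2
    if k < 0:
        k = 0
    elif k > nz - 2:
        k = nz - 2
    fx = gx - i
    fy = gy - j
    fz = gz - k
    c00 = arr[i, j, k] * (1 - fx) + arr[i + 1, j, k] * fx
    c10 = arr[i, j + 1, k] * (1 - fx) + arr[i + 1, j + 1, k] * fx
    c01 = arr[i, j, k + 1] * (1 - fx) + arr[i + 1, j, k + 1] * fx
    c11 = arr[i, j + 1, k + 1] * (1 - fx) + arr[i + 1, j + 1, k + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True, inline="always")
def _cell_straddles(gx, gy, gz, ox, oy, oz, dx,
                    rox, roy, roz, e1x, e1y, e1z, e2x, e2y, e2z,
                    span, chord, nxp, nyp, nzp):
    """Whether the trilinear cell at fractional coords straddles the rectangle."""
    i = int(np.floor(gx))
    j = int(np.floor(gy))
    k = int(np.floor(gz))
    pos = False
    neg = False
    for di in range(2):
        for dj in range(2):
            for dk in range(2):
                cx = ox + (i + di) * dx - rox
                cy = oy + (j + dj) * dx - roy
                cz = oz + (k + dk) * dx - roz
                s1 = cx * e1x + cy * e1y + cz * e1z
                if s1 < -dx or s1 > span + dx:
                    continue
                s2 = cx * e2x + cy * e2y + cz * e2z
                if s2 < -dx or s2 > chord + dx:
                    continue
                d = cx * nxp + cy * nyp + cz * nzp
                if d > 0:
                    pos = True
                else:
                    neg = True
    return pos and neg


@njit(cache=True)
def wall_pressures(
    p, ox, oy, oz, dx,
    ncross, cvx, cvy, cvz, cside,
    nxp, nyp, nzp, h1, h2,
    rox, roy, roz, e1x, e1y, e1z, e2x, e2y, e2z, span, chord,
    pvb_out,
):
    """Neumann wall pressure per crossing: second-order normal extrapolation.

    Probes at h1, h2 along the node-side normal; a probe whose interpolation
    cell straddles the plate is pushed outward by 0.1 dx until clear.
    """
    for m in range(ncross):
        sgn = cside[m]
        nx_ = sgn * nxp
        ny_ = sgn * nyp
        nz_ = sgn * nzp
        pr = np.empty(2)
        for ip in range(2):
            h = h1 if ip == 0 else h2
            for _ in range(11):
                qx = cvx[m] + h * nx_
                qy = cvy[m] + h * ny_
                qz = cvz[m] + h * nz_
                gx = (qx - ox) / dx
                gy = (qy - oy) / dx
                gz = (qz - oz) / dx
                if not _cell_straddles(
                    gx, gy, gz, ox, oy, oz, dx,
                    rox, roy, roz, e1x, e1y, e1z, e2x, e2y, e2z,
                    span, chord, nxp, nyp, nzp,
                ):
                    break
                h += 0.1 * dx
            pr[ip] = _trilinear(p, gx, gy, gz)
        pvb_out[m] = (h2 * h2 * pr[0] - h1 * h1 * pr[1]) / (h2 * h2 - h1 * h1)


@njit(cache=True)
def reconstruct_links(
    f, fnew, p, ux, uy, uz, tau,
    ex, ey, ez, w, opp,
    ncross, ci, cj, ck, calpha, ca, cvx, cvy, cvz, pvb, cut,
    wm, v0, hingex, hingey, hingez,
):
    """Virtual-flux reconstruction of the incoming distribution at each cut link.

    For the link from fluid node D along direction ``alpha`` (crossing the plate
    toward E), the value streaming back into D (direction ``opp[alpha]``) is
    rebuilt from the wall state: equilibrium at the crossing point, linear
    extrapolation to E against the anchor node (D, or C = D - e_alpha when the
    internal ratio a < 1/2 and C is usable), and the anchor's non-equilibrium
    part.  ``wm``/``v0`` give the plate's rigid-body velocity field
    ``u(x) = wm @ (x - hinge) + v0``.
    """
    nx, ny, nz, q = f.shape
    om = 1.0 - 1.0 / tau
    for m in range(ncross):
        i = ci[m]
        j = cj[m]
        k = ck[m]
        a = calpha[m]
        b = opp[a]
        # wall velocity at the crossing point
        rx = cvx[m] - hingex
        ry = cvy[m] - hingey
        rz = cvz[m] - hingez
        uwx = wm[0, 0] * rx + wm[0, 1] * ry + wm[0, 2] * rz + v0[0]
        uwy = wm[1, 0] * rx + wm[1, 1] * ry + wm[1, 2] * rz + v0[1]
        uwz = wm[2, 0] * rx + wm[2, 1] * ry + wm[2, 2] * rz + v0[2]
        uw2 = uwx * uwx + uwy * uwy + uwz * uwz
        euw = ex[b] * uwx + ey[b] * uwy + ez[b] * uwz
        peq_vb = w[b] * (pvb[m] + euw + 1.5 * euw * euw - 0.5 * uw2)
        # anchor node: D, or C = D - e_alpha when a < 1/2; the linear
        # extrapolation through (vb, anchor) keeps the anchor coefficient
        # -b/d in (-1, 0], which is stable even when most links of a node
        # are cut (two plates meeting in a narrow wedge)
        av = ca[m]
        ai = i
        aj = j
        ak = k
        d = av
        zeroth = False
        if av < 0.5:
            ci2 = i - ex[a]
            cj2 = j - ey[a]
            ck2 = k - ez[a]
            usable = (
                0 <= ci2 < nx
                and 0 <= cj2 < ny
                and 0 <= ck2 < nz
                and not cut[ci2, cj2, ck2, a]
            )
            if usable:
                ai = ci2
                aj = cj2
                ak = ck2
                d = av + 1.0
            else:
                # no usable anchor beyond D: zeroth-order wall extrapolation
                # (no self-feedback through the node's own pressure)
                zeroth = True
        pa_ = p[ai, aj, ak]
        uxa = ux[ai, aj, ak]
        uya = uy[ai, aj, ak]
        uza = uz[ai, aj, ak]
        eua = ex[b] * uxa + ey[b] * uya + ez[b] * uza
        u2a = uxa * uxa + uya * uya + uza * uza
        peq_a = w[b] * (pa_ + eua + 1.5 * eua * eua - 0.5 * u2a)
        pneq_a = f[ai, aj, ak, b] - peq_a
        if zeroth:
            peq_e = peq_vb
        else:
            bb = 1.0 - av
            peq_e = ((d + bb) / d) * peq_vb - (bb / d) * peq_a
        fnew[i, j, k, b] = peq_e + om * pneq_a


@njit(cache=True)
def momentum_exchange(f, fnew, tau, ex, ey, ez, w, opp, ncross, ci, cj, ck, calpha,
                      ca):
    """Momentum-exchange force on the plate, in lattice units (fa = 3 pa).

    Sums, over every cut directed link, the outgoing post-collision momentum
    and the reconstructed incoming momentum at the fluid node.  Records with
    a ~ 0 (node exactly on the plate) are skipped: their partner record on
    the other side is rejected at a ~ 1, so keeping them would leave the
    O(p) pressure part of the link unbalanced.
    """
    om = 1.0 - 1.0 / tau
    fx = 0.0
    fy = 0.0
    fz = 0.0
    for m in range(ncross):
        if ca[m] < 1e-8:
            continue
        i = ci[m]
        j = cj[m]
        k = ck[m]
        a = calpha[m]
        b = opp[a]
        p = 0.0
        ux = 0.0
        uy = 0.0
        uz = 0.0
        for c in range(27):
            v = f[i, j, k, c]
            p += v
            ux += ex[c] * v
            uy += ey[c] * v
            uz += ez[c] * v
        ux *= 3.0
        uy *= 3.0
        uz *= 3.0
        u2 = ux * ux + uy * uy + uz * uz
        eu = ex[a] * ux + ey[a] * uy + ez[a] * uz
        feq = w[a] * (p + eu + 1.5 * eu * eu - 0.5 * u2)
        fout = feq + om * (f[i, j, k, a] - feq)
        fin = fnew[i, j, k, b]
        fx += ex[a] * (fout + fin)
        fy += ey[a] * (fout + fin)
        fz += ez[a] * (fout + fin)
    return 3.0 * fx, 3.0 * fy, 3.0 * fz


@njit(cache=True)
def wall_velocity_probes(
    ux, uy, uz, ox, oy, oz, dx,
    npts, sx, sy, sz, sgn,
    nxp, nyp, nzp, h1, h2,
    rox, roy, roz, e1x, e1y, e1z, e2x, e2y, e2z, span, chord,
    u1_out, u2_out, h_eff,
):
    """Velocity probes at h1, h2 along the side-signed normal from surface points.

    Probes whose interpolation cell straddles the plate are pushed outward by
    0.1 dx; the distances actually used are returned in ``h_eff[:, 0:2]``.
    """
    for m in range(npts):
        nx_ = sgn[m] * nxp
        ny_ = sgn[m] * nyp
        nz_ = sgn[m] * nzp
        for ip in range(2):
            h = h1 if ip == 0 else h2
            gx = 0.0
            gy = 0.0
            gz = 0.0
            for _ in range(11):
                qx = sx[m] + h * nx_
                qy = sy[m] + h * ny_
                qz = sz[m] + h * nz_
                gx = (qx - ox) / dx
                gy = (qy - oy) / dx
                gz = (qz - oz) / dx
                if not _cell_straddles(
                    gx, gy, gz, ox, oy, oz, dx,
                    rox, roy, roz, e1x, e1y, e1z, e2x, e2y, e2z,
                    span, chord, nxp, nyp, nzp,
                ):
                    break
                h += 0.1 * dx
            h_eff[m, ip] = h
            if ip == 0:
                u1_out[m, 0] = _trilinear(ux, gx, gy, gz)
                u1_out[m, 1] = _trilinear(uy, gx, gy, gz)
                u1_out[m, 2] = _trilinear(uz, gx, gy, gz)
            else:
                u2_out[m, 0] = _trilinear(ux, gx, gy, gz)
                u2_out[m, 1] = _trilinear(uy, gx, gy, gz)
                u2_out[m, 2] = _trilinear(uz, gx, gy, gz)
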