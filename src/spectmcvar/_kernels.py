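"""Numba kernels: rotation-based projection and Monte-Carlo photon transport.

Conventions shared by all kernels:

* volumes are (nx, ny, nz); projection rotates in the (x, y) plane and the
  detector for a given angle sits at +y of the rotated frame, so axis 1 of
  the rotated volume is depth and detector pixels index (x, z);
* a world point p maps to rotated coordinates q = M^T p with
  M = [[c, s], [-s, c]] (the gather kernel computes out(q) = vol(M q));
  the outgoing ray direction toward the detector is (s, c, 0) in world axes;
* the adjoint of the gather rotation is the scatter rotation with identical
  bilinear weights, making <Hf, g> = <f, H^T g> exact to rounding;
* Gaussian blur uses a finite kernel (3.5 sigma) with zero padding and no
  edge renormalization, so it is exactly self-adjoint.
"""
from __future__ import annotations

import numpy as np
from numba import njit

F = {"fastmath": True, "cache": False}


@njit(**F)
def rotate_gather(vol, c, s):
    nx, ny, nz = vol.shape
    out = np.zeros_like(vol)
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    for i in range(nx):
        xo = i - cx
        for j in range(ny):
            yo = j - cy
            xs = c * xo + s * yo + cx
            ys = -s * xo + c * yo + cy
            x0 = int(np.floor(xs))
            y0 = int(np.floor(ys))
            fx = xs - x0
            fy = ys - y0
            for dxi in range(2):
                xi = x0 + dxi
                if xi < 0 or xi >= nx:
                    continue
                wx = fx if dxi == 1 else 1.0 - fx
                for dyi in range(2):
                    yi = y0 + dyi
                    if yi < 0 or yi >= ny:
                        continue
                    w = wx * (fy if dyi == 1 else 1.0 - fy)
                    if w == 0.0:
                        continue
                    for k in range(nz):
                        out[i, j, k] += w * vol[xi, yi, k]
    return out


@njit(**F)
def rotate_scatter(vol_rot, c, s, out):
    """Exact transpose of :func:`rotate_gather`; accumulates into ``out``."""
    nx, ny, nz = vol_rot.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    for i in range(nx):
        xo = i - cx
        for j in range(ny):
            yo = j - cy
            xs = c * xo + s * yo + cx
            ys = -s * xo + c * yo + cy
            x0 = int(np.floor(xs))
            y0 = int(np.floor(ys))
            fx = xs - x0
            fy = ys - y0
            for dxi in range(2):
                xi = x0 + dxi
                if xi < 0 or xi >= nx:
                    continue
                wx = fx if dxi == 1 else 1.0 - fx
                for dyi in range(2):
                    yi = y0 + dyi
                    if yi < 0 or yi >= ny:
                        continue
                    w = wx * (fy if dyi == 1 else 1.0 - fy)
                    if w == 0.0:
                        continue
                    for k in range(nz):
                        out[xi, yi, k] += w * vol_rot[i, j, k]


@njit(**F)
def _gauss_kernel(sigma):
    if sigma < 0.05:
        k = np.ones(1)
        return k
    r = int(np.ceil(3.5 * sigma))
    k = np.empty(2 * r + 1)
    ssum = 0.0
    for t in range(-r, r + 1):
        v = np.exp(-0.5 * (t / sigma) ** 2)
        k[t + r] = v
        ssum += v
    for t in range(2 * r + 1):
        k[t] /= ssum
    return k


@njit(**F)
def _blur_plane_accum(plane, su, sv, out):
    """out += separable Gaussian blur of plane (zero-padded convolution)."""
    nu, nv = plane.shape
    ku = _gauss_kernel(su)
    kv = _gauss_kernel(sv)
    ru = (ku.size - 1) // 2
    rv = (kv.size - 1) // 2
    if ru == 0 and rv == 0:
        for i in range(nu):
            for j in range(nv):
                out[i, j] += plane[i, j]
        return
    tmp = np.zeros((nu, nv))
    for i in range(nu):
        for t in range(-ru, ru + 1):
            ii = i + t
            if ii < 0 or ii >= nu:
                continue
            w = ku[t + ru]
            for j in range(nv):
                tmp[i, j] += w * plane[ii, j]
    for i in range(nu):
        for j in range(nv):
            acc = 0.0
            for t in range(-rv, rv + 1):
                jj = j + t
                if jj < 0 or jj >= nv:
                    continue
                acc += kv[t + rv] * tmp[i, jj]
            out[i, j] += acc


@njit(**F)
def _blur_plane_to(plane, su, sv, out):
    """out = blur(plane) (overwrites)."""
    out[:, :] = 0.0
    _blur_plane_accum(plane, su, sv, out)


@njit(**F)
def forward_core(act, att, coss, sins, sig_u, sig_v, invw, out):
    """Attenuated, depth-dependently blurred rotation projector.

    act: (nx, ny, nz); att: (na, nx, ny, nz) attenuation factors;
    sig_u/sig_v: (na, ny) PSF sigmas in pixel units per depth plane;
    invw: (na, nx, ny) reciprocal column sums of the rotation weights —
    normalizing by them makes every voxel contribute exactly unit mass
    at every angle (mass conservation holds even for a point source at
    the rotation fixed point); out: (na, nx, nz) accumulated expected
    counts (caller scales by time and sensitivity).
    """
    na = att.shape[0]
    nx, ny, nz = act.shape
    scaled = np.empty_like(act)
    for a in range(na):
        for i in range(nx):
            for j in range(ny):
                w = invw[a, i, j]
                for k in range(nz):
                    scaled[i, j, k] = act[i, j, k] * w
        rot = rotate_gather(scaled, coss[a], sins[a])
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    rot[i, j, k] *= att[a, i, j, k]
        for j in range(ny):
            _blur_plane_accum(rot[:, j, :], sig_u[a, j], sig_v[a, j], out[a])


@njit(**F)
def adjoint_core(proj, att, coss, sins, sig_u, sig_v, invw, out_vol):
    """Exact transpose of :func:`forward_core`; accumulates into out_vol."""
    na = att.shape[0]
    nx = att.shape[1]
    ny = att.shape[2]
    nz = att.shape[3]
    tmp = np.empty((nx, ny, nz))
    back = np.empty((nx, ny, nz))
    plane = np.empty((nx, nz))
    for a in range(na):
        for j in range(ny):
            _blur_plane_to(proj[a], sig_u[a, j], sig_v[a, j], plane)
            for i in range(nx):
                for k in range(nz):
                    tmp[i, j, k] = plane[i, k] * att[a, i, j, k]
        back[:, :, :] = 0.0
        rotate_scatter(tmp, coss[a], sins[a], back)
        for i in range(nx):
            for j in range(ny):
                w = invw[a, i, j]
                for k in range(nz):
                    out_vol[i, j, k] += back[i, j, k] * w


@njit(**F)
def depth_blur_sum(stack, sig_u, sig_v, out):
    """Collapse a (ny, nx, nz) depth-binned deposit into one (nx, nz) map."""
    ny = stack.shape[0]
    for j in range(ny):
        _blur_plane_accum(stack[j], sig_u[j], sig_v[j], out)


# ---------------------------------------------------------------------------
# Monte-Carlo transport
# ---------------------------------------------------------------------------


@njit(inline="always", **F)
def _lerp_table(tab, e, e_min, e_step):
    x = (e - e_min) / e_step
    if x <= 0.0:
        return tab[0]
    n = tab.shape[0]
    if x >= n - 1:
        return tab[n - 1]
    i = int(x)
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(inline="always", **F)
def _trilinear_f32(vol, gx, gy, gz):
    nx, ny, nz = vol.shape
    if gx < 0.0 or gx > nx - 1 or gy < 0.0 or gy > ny - 1 or gz < 0.0 or gz > nz - 1:
        return -1.0
    x0 = int(gx)
    y0 = int(gy)
    z0 = int(gz)
    if x0 == nx - 1:
        x0 -= 1
    if y0 == ny - 1:
        y0 -= 1
    if z0 == nz - 1:
        z0 -= 1
    fx = gx - x0
    fy = gy - y0
    fz = gz - z0
    c000 = vol[x0, y0, z0]
    c100 = vol[x0 + 1, y0, z0]
    c010 = vol[x0, y0 + 1, z0]
    c110 = vol[x0 + 1, y0 + 1, z0]
    c001 = vol[x0, y0, z0 + 1]
    c101 = vol[x0 + 1, y0, z0 + 1]
    c011 = vol[x0, y0 + 1, z0 + 1]
    c111 = vol[x0 + 1, y0 + 1, z0 + 1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(inline="always", **F)
def _kn_diff(e, cos_t):
    a = e / 511.0
    kap = 1.0 / (1.0 + a * (1.0 - cos_t))
    return 0.5 * kap * kap * (kap + 1.0 / kap - (1.0 - cos_t * cos_t))


@njit(inline="always", **F)
def _deposit(dep, ch, a, gy, gx, gz, val):
    ny = dep.shape[2]
    nx = dep.shape[3]
    nz = dep.shape[4]
    j = int(gy + 0.5)
    if j < 0:
        j = 0
    elif j >= ny:
        j = ny - 1
    x0 = int(np.floor(gx))
    z0 = int(np.floor(gz))
    fx = gx - x0
    fz = gz - z0
    for dxi in range(2):
        xi = x0 + dxi
        if xi < 0 or xi >= nx:
            continue
        wx = fx if dxi == 1 else 1.0 - fx
        for dzi in range(2):
            zi = z0 + dzi
            if zi < 0 or zi >= nz:
                continue
            dep[ch, a, j, xi, zi] += np.float32(val * wx * (fz if dzi == 1 else 1.0 - fz))


@njit(**F)
def transport_kernel(
    cdf, nx, ny, nz, dx, dy, dz,
    mu208, mu_max,
    e0, e_min, e_step, ktab, cftab, skntab, wintab,
    coss, sins, attab, invw,
    n_hist, seed, max_order, e_cut,
    dep, order_wsum,
):
    """Photon histories with next-event estimation toward every angle.

    Channel layout of ``dep`` (nchan, na, ny, nx, nz): channel 0 receives
    window-0 counts from unscattered photons, channel 1 window-0 counts from
    scattered photons, channel 1+w counts of window w >= 1. Deposits are
    per-history expected counts; the caller scales by activity * time *
    sensitivity / n_hist and applies the depth-dependent PSF blur.
    """
    np.random.seed(seed)
    na = coss.shape[0]
    nwin = wintab.shape[1]
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    cz = (nz - 1) / 2.0
    hx = nx * dx / 2.0 + dx
    hy = ny * dy / 2.0 + dy
    hz = nz * dz / 2.0 + dz
    nvox = nx * ny * nz
    p0 = np.empty(nwin)
    for w in range(nwin):
        p0[w] = _lerp_table(wintab[:, w], e0, e_min, e_step)
    for _ in range(n_hist):
        # emission voxel via inverse-CDF, uniform position within the voxel
        u = np.random.random()
        lo = 0
        hi = nvox - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        iz = lo % nz
        iy = (lo // nz) % ny
        ix = lo // (nz * ny)
        # emission at the voxel center: the MC forward is then an unbiased
        # stochastic estimator of the same discrete operator the analytic
        # projector implements (activity as a point cloud at voxel centers)
        X = (ix - cx) * dx
        Y = (iy - cy) * dy
        Z = (iz - cz) * dz

        # next-event estimation for the unscattered photon, using exactly the
        # rotation weights of the analytic projector: emission voxel v
        # contributes att(q) at each rotated grid point q whose bilinear
        # source point falls within one voxel of v, so the expectation of
        # this tally reproduces the discrete analytic operator identically
        xo = ix - cx
        yo = iy - cy
        for a in range(na):
            c = coss[a]
            s = sins[a]
            tx = c * xo - s * yo + cx
            ty = s * xo + c * yo + cy
            qx0 = int(np.floor(tx)) - 1
            qy0 = int(np.floor(ty)) - 1
            for qx in range(qx0, qx0 + 4):
                if qx < 0 or qx >= nx:
                    continue
                sx = c * (qx - cx)
                for qy in range(qy0, qy0 + 4):
                    if qy < 0 or qy >= ny:
                        continue
                    wx = 1.0 - abs(sx + s * (qy - cy) - xo)
                    if wx <= 0.0:
                        continue
                    wy = 1.0 - abs(-s * (qx - cx) + c * (qy - cy) - yo)
                    if wy <= 0.0:
                        continue
                    val0 = wx * wy * invw[a, ix, iy] * attab[a, qx, qy, iz]
                    if val0 <= 0.0:
                        continue
                    for w in range(nwin):
                        if p0[w] <= 0.0:
                            continue
                        ch = 0 if w == 0 else 1 + w
                        dep[ch, a, qy, qx, iz] += np.float32(val0 * p0[w])
                        if w == 0:
                            order_wsum[0] += val0 * p0[w]

        # isotropic initial direction
        mu_d = 2.0 * np.random.random() - 1.0
        phi = 2.0 * np.pi * np.random.random()
        st = np.sqrt(max(0.0, 1.0 - mu_d * mu_d))
        ux = st * np.cos(phi)
        uy = st * np.sin(phi)
        uz = mu_d

        E = e0
        order = 0
        alive = True
        while alive and order < max_order:
            # Woodcock tracking to the next real interaction
            mu_maj = _lerp_table(ktab, E, e_min, e_step) * mu_max
            while True:
                step = -np.log(np.random.random() + 1e-300) / mu_maj
                X += ux * step
                Y += uy * step
                Z += uz * step
                if abs(X) > hx or abs(Y) > hy or abs(Z) > hz:
                    alive = False
                    break
                vx = int(np.floor(X / dx + cx + 0.5))
                vy = int(np.floor(Y / dy + cy + 0.5))
                vz = int(np.floor(Z / dz + cz + 0.5))
                if vx < 0 or vx >= nx or vy < 0 or vy >= ny or vz < 0 or vz >= nz:
                    continue
                if np.random.random() * mu_max < mu208[vx, vy, vz]:
                    break
            if not alive:
                break
            # interaction type
            if np.random.random() >= _lerp_table(cftab, E, e_min, e_step):
                break  # photoelectric absorption

            # next-event estimation for the photon scattered toward each head
            skn = _lerp_table(skntab, E, e_min, e_step)
            for a in range(na):
                c = coss[a]
                s = sins[a]
                cpsi = ux * s + uy * c
                Ea = E / (1.0 + E / 511.0 * (1.0 - cpsi))
                if Ea < e_min:
                    continue
                pany = 0.0
                for w in range(nwin):
                    pany += _lerp_table(wintab[:, w], Ea, e_min, e_step)
                if pany <= 1e-12:
                    continue
                gx = (c * X - s * Y) / dx + cx
                gy = (s * X + c * Y) / dy + cy
                gz = Z / dz + cz
                att0 = _trilinear_f32(attab[a], gx, gy, gz)
                if att0 <= 0.0:
                    continue
                kE = _lerp_table(ktab, Ea, e_min, e_step)
                base = 4.0 * np.pi * _kn_diff(E, cpsi) / skn * att0 ** kE
                for w in range(nwin):
                    p = _lerp_table(wintab[:, w], Ea, e_min, e_step)
                    if p <= 0.0:
                        continue
                    ch = 1 if w == 0 else 1 + w
                    _deposit(dep, ch, a, gy, gx, gz, base * p)
                    if w == 0 and order + 1 <= max_order:
                        order_wsum[order + 1] += base * p

            # analog Compton scatter (Klein-Nishina rejection sampling)
            aE = E / 511.0
            while True:
                ct = 2.0 * np.random.random() - 1.0
                kap = 1.0 / (1.0 + aE * (1.0 - ct))
                f = 0.5 * kap * kap * (kap + 1.0 / kap - (1.0 - ct * ct))
                if np.random.random() < f:
                    break
            E = E * kap
            order += 1
            # rotate direction by (theta, phi) about the current axis
            sint = np.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * np.pi * np.random.random()
            sp = np.sin(phi)
            cp = np.cos(phi)
            if abs(uz) > 0.99999:
                nux = sint * cp
                nuy = sint * sp
                nuz = ct * (1.0 if uz > 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = ux * ct + sint * (ux * uz * cp - uy * sp) / den
                nuy = uy * ct + sint * (uy * uz * cp + ux * sp) / den
                nuz = uz * ct - sint * den * cp
            ux, uy, uz = nux, nuy, nuz
            if E < e_cut:
                break
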