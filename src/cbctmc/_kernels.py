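"""Numba kernels: voxel ray traversal, Woodcock flights, Compton/Rayleigh
sampling, forced-detection scoring and FDK backprojection.

All kernels are single-threaded and seeded explicitly so runs are
reproducible.  Distances in cm, energies in keV.  Phantom arrays are
indexed [ix, iy, iz]; detector rasters [iv, iu].
"""

from __future__ import annotations

import numpy as np
from numba import njit

ELECTRON_REST_KEV = 510.998950
HC_KEV_ANGSTROM = 12.398420


@njit(cache=True, inline="always")
def _interp_uniform(e, e0, de, row):
    """Linear interpolation on a uniform energy grid, clamped at the ends."""
    f = (e - e0) / de
    n = row.shape[0]
    if f <= 0.0:
        return row[0]
    if f >= n - 1:
        return row[n - 1]
    i = int(f)
    t = f - i
    return row[i] * (1.0 - t) + row[i + 1] * t



@njit(cache=True, inline="always")
def _rand(st):
    """xorshift128+ step on a 2-element uint64 state; uniform in [0, 1)."""
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    st[1] = s1
    out = (st[0] + st[1]) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return float(out >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _seed_state(st, key):
    """splitmix64 expansion of a 64-bit key into the xorshift state."""
    z = np.uint64(key)
    for i in range(2):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = z
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        st[i] = x ^ (x >> np.uint64(31))
    if st[0] == 0 and st[1] == 0:
        st[0] = np.uint64(1)


@njit(cache=True)
def _ray_box(px, py, pz, dx, dy, dz, lo, hi):
    """Entry/exit parameters of a ray with an axis-aligned box; returns
    (tmin, tmax) with tmin > tmax when the ray misses."""
    tmin = -1.0e30
    tmax = 1.0e30
    p = (px, py, pz)
    d = (dx, dy, dz)
    for a in range(3):
        if abs(d[a]) < 1.0e-12:
            if p[a] < lo[a] or p[a] > hi[a]:
                return 1.0, 0.0
        else:
            t1 = (lo[a] - p[a]) / d[a]
            t2 = (hi[a] - p[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmin < 0.0:
        tmin = 0.0
    return tmin, tmax


@njit(cache=True)
def _rho_path(px, py, pz, dx, dy, dz, mat, rho, origin, voxel, rho_path):
    """Accumulate per-material radiological density path (g/cm^2) along a
    ray from its box entry to exit, via incremental voxel traversal."""
    nx, ny, nz = mat.shape
    lo = origin
    hi = (origin[0] + nx * voxel[0], origin[1] + ny * voxel[1],
          origin[2] + nz * voxel[2])
    for m in range(rho_path.shape[0]):
        rho_path[m] = 0.0
    tmin, tmax = _ray_box(px, py, pz, dx, dy, dz, lo, hi)
    if tmin >= tmax:
        return
    eps = 1.0e-9 * (tmax - tmin)
    t = tmin + eps
    x = px + t * dx
    y = py + t * dy
    z = pz + t * dz
    ix = int((x - lo[0]) / voxel[0])
    iy = int((y - lo[1]) / voxel[1])
    iz = int((z - lo[2]) / voxel[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    stepx = 1 if dx > 0 else -1
    stepy = 1 if dy > 0 else -1
    stepz = 1 if dz > 0 else -1
    big = 1.0e30
    if abs(dx) > 1e-12:
        tdx = abs(voxel[0] / dx)
        nxt = lo[0] + (ix + (1 if dx > 0 else 0)) * voxel[0]
        tx = (nxt - px) / dx
    else:
        tdx = big
        tx = big
    if abs(dy) > 1e-12:
        tdy = abs(voxel[1] / dy)
        nxt = lo[1] + (iy + (1 if dy > 0 else 0)) * voxel[1]
        ty = (nxt - py) / dy
    else:
        tdy = big
        ty = big
    if abs(dz) > 1e-12:
        tdz = abs(voxel[2] / dz)
        nxt = lo[2] + (iz + (1 if dz > 0 else 0)) * voxel[2]
        tz = (nxt - pz) / dz
    else:
        tdz = big
        tz = big
    maxiter = nx + ny + nz + 4
    for _ in range(maxiter):
        # next crossing
        if tx <= ty and tx <= tz:
            tnext = tx
        elif ty <= tz:
            tnext = ty
        else:
            tnext = tz
        if tnext > tmax:
            tnext = tmax
        seg = tnext - t
        if seg > 0.0:
            rho_path[mat[ix, iy, iz]] += rho[ix, iy, iz] * seg
        t = tnext
        if t >= tmax - 1e-12:
            return
        if tx <= ty and tx <= tz:
            ix += stepx
            tx += tdx
            if ix < 0 or ix >= nx:
                return
        elif ty <= tz:
            iy += stepy
            ty += tdy
            if iy < 0 or iy >= ny:
                return
        else:
            iz += stepz
            tz += tdz
            if iz < 0 or iz >= nz:
                return


@njit(cache=True, inline="always")
def _tau(rho_path, e, e0, de, matt_total):
    s = 0.0
    for m in range(rho_path.shape[0]):
        if rho_path[m] > 0.0:
            s += rho_path[m] * _interp_uniform(e, e0, de, matt_total[m])
    return s


@njit(cache=True)
def _sample_compton(e_kev, st):
    """Free-electron Klein-Nishina sampling; returns (cos_theta, e_out)."""
    k = e_kev / ELECTRON_REST_KEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if _rand(st) * (a1 + a2) < a1:
            eps = eps_min * np.exp(a1 * _rand(st))
        else:
            eps = np.sqrt(eps_min * eps_min
                          + (1.0 - eps_min * eps_min) * _rand(st))
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if _rand(st) <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            cost = 1.0 - t
            return cost, eps * e_kev


@njit(cache=True)
def _sample_rayleigh(e_kev, x2_grid, cum, st):
    """Coherent-scatter polar angle via the squared-form-factor table plus
    Thomson rejection; returns cos_theta."""
    lam = HC_KEV_ANGSTROM / e_kev
    x2max = 1.0 / (lam * lam)  # x = sin(theta/2)/lambda, theta = pi
    n = x2_grid.shape[0]
    # cumulative value at x2max
    j = np.searchsorted(x2_grid, x2max)
    if j >= n:
        cmax = cum[n - 1]
    elif j == 0:
        cmax = cum[0] * (x2max / max(x2_grid[0], 1e-30))
    else:
        f = (x2max - x2_grid[j - 1]) / (x2_grid[j] - x2_grid[j - 1])
        cmax = cum[j - 1] + f * (cum[j] - cum[j - 1])
    for _ in range(1000):
        target = _rand(st) * cmax
        i = np.searchsorted(cum, target)
        if i <= 0:
            x2 = x2_grid[0] * target / max(cum[0], 1e-30)
        elif i >= n:
            x2 = x2_grid[n - 1]
        else:
            f = (target - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-30)
            x2 = x2_grid[i - 1] + f * (x2_grid[i] - x2_grid[i - 1])
        cost = 1.0 - 2.0 * x2 * lam * lam
        if cost < -1.0:
            cost = -1.0
        if _rand(st) <= 0.5 * (1.0 + cost * cost):
            return cost
    return 1.0


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    """Rotate unit vector u by polar angle (cos_theta) about itself with
    azimuth phi; standard transport frame rotation."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(ux * ux + uy * uy)
        vx = (ux * uz * cphi - uy * sphi) / denom
        vy = (uy * uz * cphi + ux * sphi) / denom
        vz = -denom * cphi
        wx = ux * cost + sint * vx
        wy = uy * cost + sint * vy
        wz = uz * cost + sint * vz
    else:
        wx = sint * cphi
        wy = sint * sphi
        wz = cost if uz > 0 else -cost
    norm = np.sqrt(wx * wx + wy * wy + wz * wz)
    return wx / norm, wy / norm, wz / norm


@njit(cache=True)
def siddon_primary_kernel(mat, rho, origin, voxel, src, det_c, e_u, e_v, e_n,
                          det_w, det_h, nu, nv, energies, weights,
                          e0, de, matt_total):
    """Noiseless primary and blank projections by exact voxel traversal.

    Rays go from the source through every detector pixel center; blank is
    the spectrum-weighted unattenuated energy fluence with inverse-square
    and obliquity factors (sdd-normalized)."""
    nm = matt_total.shape[0]
    prim = np.zeros((nv, nu))
    blank = np.zeros((nv, nu))
    rho_path = np.zeros(nm)
    sdd2 = 0.0
    for a in range(3):
        sdd2 += (det_c[a] - src[a]) ** 2
    pu = det_w / nu
    pv = det_h / nv
    for iv in range(nv):
        for iu in range(nu):
            tx = det_c[0] + ((iu + 0.5) * pu - det_w / 2) * e_u[0] \
                + ((iv + 0.5) * pv - det_h / 2) * e_v[0]
            ty = det_c[1] + ((iu + 0.5) * pu - det_w / 2) * e_u[1] \
                + ((iv + 0.5) * pv - det_h / 2) * e_v[1]
            tz = det_c[2] + ((iu + 0.5) * pu - det_w / 2) * e_u[2] \
                + ((iv + 0.5) * pv - det_h / 2) * e_v[2]
            dx = tx - src[0]
            dy = ty - src[1]
            dz = tz - src[2]
            dist = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= dist
            dy /= dist
            dz /= dist
            cosobl = abs(dx * e_n[0] + dy * e_n[1] + dz * e_n[2])
            w0 = cosobl * sdd2 / (dist * dist)
            _rho_path(src[0], src[1], src[2], dx, dy, dz, mat, rho,
                      origin, voxel, rho_path)
            b = 0.0
            p = 0.0
            for s in range(energies.shape[0]):
                e = energies[s]
                term = weights[s] * e * w0
                b += term
                p += term * np.exp(-_tau(rho_path, e, e0, de, matt_total))
            blank[iv, iu] = b
            prim[iv, iu] = p
    return prim, blank


@njit(cache=True)
def mc_projection_kernel(mat, rho, origin, voxel, src, det_c, e_u, e_v, e_n,
                         det_w, det_h, nu, nv, energies, cdf,
                         e0, de, matt_total, matt_photo, matt_incoh, matt_coh,
                         rayl_x2, rayl_cum, rho_max,
                         n_histories, n_split, rr_factor, kappa, cutoff_kev,
                         coherent_on, seed):
    """Forced-detection Monte Carlo estimate of primary and scatter signal.

    Each history launches one photon from the source at a uniformly sampled
    detector pixel center.  The primary contribution is scored
    deterministically (attenuated line integral).  Interactions are found
    with Woodcock tracking (optionally path-stretched by kappa); at each
    scattering vertex the photon is split (n_split daughters at the first
    vertex, rr_factor afterwards): daughters aimed at the detector are
    scored with forced detection and terminated, the rest play Russian
    roulette with survival 1/rr_factor.

    Returns (prim, prim_sq, scat, scat_sq) raw per-history sums.
    """
    nm = matt_total.shape[0]
    prim = np.zeros((nv, nu))
    prim_sq = np.zeros((nv, nu))
    scat = np.zeros((nv, nu))
    scat_sq = np.zeros((nv, nu))
    rho_path = np.zeros(nm)
    nx, ny, nz = mat.shape
    lo = origin
    hi = (origin[0] + nx * voxel[0], origin[1] + ny * voxel[1],
          origin[2] + nz * voxel[2])
    sdd2 = 0.0
    for a in range(3):
        sdd2 += (det_c[a] - src[a]) ** 2
    pu = det_w / nu
    pv = det_h / nv
    ns = energies.shape[0]
    # photon stack: x, y, z, dx, dy, dz, E, w, first(0/1)
    cap = 2048
    stack = np.zeros((cap, 9))
    rngst = np.zeros(2, dtype=np.uint64)
    for _h in range(n_histories):
        # counter-based per-history stream: histories stay coupled across
        # reruns with a slightly perturbed phantom (common random numbers)
        _seed_state(rngst, np.uint64(seed) * np.uint64(0x51A3F28D) + np.uint64(_h))
        # spectrum line
        if ns == 1:
            e_start = energies[0]
        else:
            r = _rand(rngst)
            si = np.searchsorted(cdf, r)
            if si >= ns:
                si = ns - 1
            e_start = energies[si]
        iu = int(_rand(rngst) * nu)
        if iu >= nu:
            iu = nu - 1
        iv = int(_rand(rngst) * nv)
        if iv >= nv:
            iv = nv - 1
        du = (iu + 0.5) * pu - det_w / 2
        dv = (iv + 0.5) * pv - det_h / 2
        tx = det_c[0] + du * e_u[0] + dv * e_v[0]
        ty = det_c[1] + du * e_u[1] + dv * e_v[1]
        tz = det_c[2] + du * e_u[2] + dv * e_v[2]
        dx = tx - src[0]
        dy = ty - src[1]
        dz = tz - src[2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= dist
        dy /= dist
        dz /= dist
        cosobl = abs(dx * e_n[0] + dy * e_n[1] + dz * e_n[2])
        w0 = cosobl * sdd2 / (dist * dist)
        # primary forced-detection score
        _rho_path(src[0], src[1], src[2], dx, dy, dz, mat, rho, origin,
                  voxel, rho_path)
        contrib = w0 * e_start * np.exp(
            -_tau(rho_path, e_start, e0, de, matt_total))
        prim[iv, iu] += contrib
        prim_sq[iv, iu] += contrib * contrib
        # scatter transport
        nstack = 1
        stack[0, 0] = src[0]
        stack[0, 1] = src[1]
        stack[0, 2] = src[2]
        stack[0, 3] = dx
        stack[0, 4] = dy
        stack[0, 5] = dz
        stack[0, 6] = e_start
        stack[0, 7] = w0
        stack[0, 8] = 1.0
        while nstack > 0:
            nstack -= 1
            px = stack[nstack, 0]
            py = stack[nstack, 1]
            pz = stack[nstack, 2]
            ux = stack[nstack, 3]
            uy = stack[nstack, 4]
            uz = stack[nstack, 5]
            en = stack[nstack, 6]
            w = stack[nstack, 7]
            first = stack[nstack, 8] > 0.5
            # majorant at this energy
            mu_max = 0.0
            for m in range(nm):
                v = rho_max[m] * _interp_uniform(en, e0, de, matt_total[m])
                if v > mu_max:
                    mu_max = v
            if mu_max <= 0.0:
                continue
            tmin, tmax = _ray_box(px, py, pz, ux, uy, uz, lo, hi)
            if tmin >= tmax:
                continue
            s = tmin
            mu_star = mu_max / (1.0 + kappa)
            alive = True
            while alive:
                step = -np.log(_rand(rngst)) / mu_star
                if kappa > 0.0:
                    w *= (mu_max / mu_star) * np.exp(-(mu_max - mu_star) * step)
                s += step
                if s >= tmax:
                    alive = False
                    break
                x = px + s * ux
                y = py + s * uy
                z = pz + s * uz
                ix = int((x - lo[0]) / voxel[0])
                iy = int((y - lo[1]) / voxel[1])
                iz = int((z - lo[2]) / voxel[2])
                if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                    alive = False
                    break
                m = mat[ix, iy, iz]
                rloc = rho[ix, iy, iz]
                mu_loc = rloc * _interp_uniform(en, e0, de, matt_total[m])
                if _rand(rngst) * mu_max >= mu_loc:
                    continue  # fictitious interaction
                # real interaction: choose channel
                mu_pe = rloc * _interp_uniform(en, e0, de, matt_photo[m])
                mu_co = rloc * _interp_uniform(en, e0, de, matt_coh[m])
                mu_in = mu_loc - mu_pe - mu_co
                if mu_in < 0.0:
                    mu_in = 0.0
                tot = mu_pe + mu_in + mu_co
                if tot <= 0.0:
                    alive = False
                    break
                xi = _rand(rngst) * tot
                if xi < mu_pe:
                    alive = False  # photoelectric absorption, no electrons
                    break
                is_compton = xi < mu_pe + mu_in
                if not is_compton and not coherent_on:
                    continue  # coherent channel disabled: treat as fictitious
                nsplit = n_split if first else rr_factor
                wd = w / nsplit
                for _k in range(nsplit):
                    if is_compton:
                        cost, e_new = _sample_compton(en, rngst)
                    else:
                        cost = _sample_rayleigh(en, rayl_x2, rayl_cum[m], rngst)
                        e_new = en
                    if e_new < cutoff_kev:
                        continue
                    phi = 2.0 * np.pi * _rand(rngst)
                    ndx, ndy, ndz = _rotate(ux, uy, uz, cost, phi)
                    # detector-plane intersection test
                    denom = ndx * e_n[0] + ndy * e_n[1] + ndz * e_n[2]
                    aimed = False
                    if denom < -1.0e-9:  # heading toward the detector plane
                        tplane = ((det_c[0] - x) * e_n[0]
                                  + (det_c[1] - y) * e_n[1]
                                  + (det_c[2] - z) * e_n[2]) / denom
                        if tplane > 0.0:
                            hx = x + tplane * ndx - det_c[0]
                            hy = y + tplane * ndy - det_c[1]
                            hz = z + tplane * ndz - det_c[2]
                            uu = hx * e_u[0] + hy * e_u[1] + hz * e_u[2]
                            vv = hx * e_v[0] + hy * e_v[1] + hz * e_v[2]
                            if (-det_w / 2 <= uu < det_w / 2
                                    and -det_h / 2 <= vv < det_h / 2):
                                aimed = True
                                ju = int((uu + det_w / 2) / pu)
                                jv = int((vv + det_h / 2) / pv)
                                if ju >= nu:
                                    ju = nu - 1
                                if jv >= nv:
                                    jv = nv - 1
                                _rho_path(x, y, z, ndx, ndy, ndz, mat, rho,
                                          origin, voxel, rho_path)
                                sc = wd * e_new * np.exp(
                                    -_tau(rho_path, e_new, e0, de, matt_total))
                                scat[jv, ju] += sc
                                scat_sq[jv, ju] += sc * sc
                    if not aimed:
                        # Russian roulette for non-aimed daughters
                        if _rand(rngst) * rr_factor < 1.0:
                            if nstack < cap:
                                stack[nstack, 0] = x
                                stack[nstack, 1] = y
                                stack[nstack, 2] = z
                                stack[nstack, 3] = ndx
                                stack[nstack, 4] = ndy
                                stack[nstack, 5] = ndz
                                stack[nstack, 6] = e_new
                                stack[nstack, 7] = wd * rr_factor
                                stack[nstack, 8] = 0.0
                                nstack += 1
                alive = False  # parent consumed by splitting
    return prim, prim_sq, scat, scat_sq


@njit(cache=True)
def fdk_backproject(filtered, angles_rad, sad, sdd, det_w, det_h,
                    nx, ny, nz, vx, vy, vz, ox, oy, oz):
    """Distance-weighted cone-beam backprojection on the virtual detector
    through the isocenter.  ``filtered`` is (n_angles, nv, nu) already
    cosine-weighted, arc-weighted and ramp-filtered; detector coordinates
    are scaled by sad/sdd inside."""
    na, nv, nu = filtered.shape
    scale = sad / sdd
    w_iso = det_w * scale
    h_iso = det_h * scale
    pu = w_iso / nu
    pv = h_iso / nv
    vol = np.zeros((nx, ny, nz))
    dbeta = np.zeros(na)
    for i in range(na):
        # half-open uniform schedule
        if na > 1:
            dbeta[i] = angles_rad[1] - angles_rad[0]
        else:
            dbeta[i] = 2.0 * np.pi
    for ia in range(na):
        b = angles_rad[ia]
        sb = np.sin(b)
        cb = np.cos(b)
        proj = filtered[ia]
        db = dbeta[ia]
        for ix in range(nx):
            x = ox + (ix + 0.5) * vx
            for iy in range(ny):
                y = oy + (iy + 0.5) * vy
                # component of voxel toward source direction (-sin b, cos b)
                t = -x * sb + y * cb
                dist = sad - t
                if dist < 1.0e-6:
                    continue
                u = sad * (x * cb + y * sb) / dist
                fu = (u + w_iso / 2) / pu - 0.5
                iu0 = int(np.floor(fu))
                au = fu - iu0
                if iu0 < -1 or iu0 > nu - 1:
                    continue
                w2 = sad * sad / (dist * dist)
                for iz in range(nz):
                    zc = oz + (iz + 0.5) * vz
                    v = sad * zc / dist
                    fv = (v + h_iso / 2) / pv - 0.5
                    iv0 = int(np.floor(fv))
                    av = fv - iv0
                    if iv0 < -1 or iv0 > nv - 1:
                        continue
                    # bilinear with zero outside
                    v00 = proj[iv0, iu0] if (0 <= iv0 < nv and 0 <= iu0 < nu) else 0.0
                    v01 = proj[iv0, iu0 + 1] if (0 <= iv0 < nv and 0 <= iu0 + 1 < nu) else 0.0
                    v10 = proj[iv0 + 1, iu0] if (0 <= iv0 + 1 < nv and 0 <= iu0 < nu) else 0.0
                    v11 = proj[iv0 + 1, iu0 + 1] if (0 <= iv0 + 1 < nv and 0 <= iu0 + 1 < nu) else 0.0
                    val = (v00 * (1 - au) * (1 - av) + v01 * au * (1 - av)
                           + v10 * (1 - au) * av + v11 * au * av)
                    vol[ix, iy, iz] += db * w2 * val
    return vol
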