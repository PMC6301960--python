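"""Numba kernels: membrane surface queries, grid-accelerated cell forces, exposure tests.

All lengths are in micrometres, times in hours. The lateral domain is periodic in
x and y (minimum-image convention); z is open. Membrane kinds are encoded as
integers: 0 flat, 1 sinusoidal bumps (separable product), 2 sinusoidal grooves
(1D), 3 fiber grid (upper envelope of orthogonal arrays of half-embedded
cylinders whose crowns rise one fiber thickness above the z=0 base plane).
"""

import numpy as np
from numba import njit

MKIND_FLAT = 0
MKIND_SIN2D = 1
MKIND_SIN1D = 2
MKIND_FIBER = 3

_FD_STEP = 1e-3  # finite-difference step for the fiber-grid gradient, um


@njit(cache=True)
def mem_height(kind, amp, lam, thick, period, dom_x, dom_y, x, y):
    x = x % dom_x
    y = y % dom_y
    if kind == MKIND_FLAT:
        return 0.0
    if kind == MKIND_SIN2D:
        k = 2.0 * np.pi / lam
        return 0.5 * amp * np.sin(k * x) * np.sin(k * y)
    if kind == MKIND_SIN1D:
        k = 2.0 * np.pi / lam
        return 0.5 * amp * np.sin(k * x)
    # fiber grid: axes of one cylinder family run along y at x = m*period,
    # the orthogonal family along x at y = m*period. Fibers are half-embedded
    # cylinders with axis in the base plane and radius = thick, so the crown
    # rises one fiber thickness above z = 0 and the height field is continuous.
    r = thick
    ax = x % period
    if period - ax < ax:
        ax = period - ax
    ay = y % period
    if period - ay < ay:
        ay = period - ay
    h = 0.0
    if ax < r:
        h = np.sqrt(r * r - ax * ax)
    if ay < r:
        h2 = np.sqrt(r * r - ay * ay)
        if h2 > h:
            h = h2
    return h


@njit(cache=True)
def mem_grad(kind, amp, lam, thick, period, dom_x, dom_y, x, y):
    """(dh/dx, dh/dy); analytic for flat/sinusoidal, central differences for fibers."""
    if kind == MKIND_FLAT:
        return 0.0, 0.0
    if kind == MKIND_SIN2D:
        k = 2.0 * np.pi / lam
        xw = x % dom_x
        yw = y % dom_y
        gx = 0.5 * amp * k * np.cos(k * xw) * np.sin(k * yw)
        gy = 0.5 * amp * k * np.sin(k * xw) * np.cos(k * yw)
        return gx, gy
    if kind == MKIND_SIN1D:
        k = 2.0 * np.pi / lam
        xw = x % dom_x
        return 0.5 * amp * k * np.cos(k * xw), 0.0
    hxp = mem_height(kind, amp, lam, thick, period, dom_x, dom_y, x + _FD_STEP, y)
    hxm = mem_height(kind, amp, lam, thick, period, dom_x, dom_y, x - _FD_STEP, y)
    hyp = mem_height(kind, amp, lam, thick, period, dom_x, dom_y, x, y + _FD_STEP)
    hym = mem_height(kind, amp, lam, thick, period, dom_x, dom_y, x, y - _FD_STEP)
    return (hxp - hxm) / (2.0 * _FD_STEP), (hyp - hym) / (2.0 * _FD_STEP)


@njit(cache=True)
def mem_height_arr(kind, amp, lam, thick, period, dom_x, dom_y, xs, ys, out):
    for i in range(xs.shape[0]):
        out[i] = mem_height(kind, amp, lam, thick, period, dom_x, dom_y, xs[i], ys[i])


@njit(cache=True)
def mem_normal(kind, amp, lam, thick, period, dom_x, dom_y, x, y):
    gx, gy = mem_grad(kind, amp, lam, thick, period, dom_x, dom_y, x, y)
    nz = 1.0
    norm = np.sqrt(gx * gx + gy * gy + nz * nz)
    return -gx / norm, -gy / norm, nz / norm


@njit(cache=True)
def directional_radius(a, c, uz2):
    """Support radius of an (a, a, c) ellipsoid along a unit direction with uz^2 = uz2."""
    return a * c / np.sqrt(c * c * (1.0 - uz2) + a * a * uz2)


@njit(cache=True)
def _build_grid(pos, dom_x, dom_y, bin_size, bin_size_z):
    """Counting-sort cells into a periodic (x, y) x clamped-z uniform grid.

    The vertical bin size may differ from the lateral one (vertical interaction
    reach is much shorter once corneocytes flatten). Returns
    (order, bin_start, nx, ny, nz, bsx, bsy, bsz, zmin): cells sorted by bin id
    with bin_start giving CSR-style offsets.
    """
    n = pos.shape[0]
    nx = max(1, int(dom_x / bin_size))
    ny = max(1, int(dom_y / bin_size))
    bsx = dom_x / nx
    bsy = dom_y / ny
    zmin = 1e30
    zmax = -1e30
    for i in range(n):
        z = pos[i, 2]
        if z < zmin:
            zmin = z
        if z > zmax:
            zmax = z
    if n == 0:
        zmin = 0.0
        zmax = 0.0
    nz = max(1, int((zmax - zmin) / bin_size_z) + 1)
    bsz = bin_size_z
    nbins = nx * ny * nz
    binid = np.empty(n, np.int64)
    for i in range(n):
        ix = int((pos[i, 0] % dom_x) / bsx)
        if ix >= nx:
            ix = nx - 1
        iy = int((pos[i, 1] % dom_y) / bsy)
        if iy >= ny:
            iy = ny - 1
        iz = int((pos[i, 2] - zmin) / bsz)
        if iz >= nz:
            iz = nz - 1
        if iz < 0:
            iz = 0
        binid[i] = (ix * ny + iy) * nz + iz
    counts = np.zeros(nbins + 1, np.int64)
    for i in range(n):
        counts[binid[i] + 1] += 1
    for b in range(nbins):
        counts[b + 1] += counts[b]
    order = np.empty(n, np.int64)
    cursor = counts.copy()
    for i in range(n):
        b = binid[i]
        order[cursor[b]] = i
        cursor[b] += 1
    return order, counts, nx, ny, nz, bsx, bsy, bsz, zmin


@njit(cache=True)
def compute_forces(pos, aa, cc, state, anchor, ids,
                   mkind, amp, lam, thick, period, dom_x, dom_y,
                   k_rep, k_adh, adh_range, k_mem, k_anchor,
                   count_radius, stem_code, corneo_code):
    """Total force on every cell plus the neighbour count within count_radius.

    Pairwise law: linear repulsion k_rep*(R-d) inside contact (R = sum of
    direction-dependent ellipsoid radii), linear adhesion ramping from k_adh at
    contact to 0 at R+adh_range. Membrane: linear repulsion along the surface
    normal when the vertical clearance is below the cell's vertical semi-axis;
    anchored stems feel an additional linear spring to their on-surface anchor.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    ncount = np.zeros(n, np.int64)
    if n == 0:
        return F, ncount
    rmax = np.empty(n)
    amax = 0.0
    cmax = 0.0
    for i in range(n):
        r = aa[i] if aa[i] > cc[i] else cc[i]
        rmax[i] = r
        if r > amax:
            amax = r
        if cc[i] > cmax:
            cmax = cc[i]
    bin_size = 2.0 * amax + adh_range
    if bin_size < count_radius:
        bin_size = count_radius
    # vertical reach of any pair is at most c_i + c_j + adh_range
    bin_size_z = 2.0 * cmax + adh_range
    if bin_size_z < count_radius:
        bin_size_z = count_radius
    order, bin_start, nx, ny, nz, bsx, bsy, bsz, zmin = _build_grid(
        pos, dom_x, dom_y, bin_size, bin_size_z)
    cr2 = count_radius * count_radius
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ai = aa[i]
        ci = cc[i]
        ix = int((xi % dom_x) / bsx)
        if ix >= nx:
            ix = nx - 1
        iy = int((yi % dom_y) / bsy)
        if iy >= ny:
            iy = ny - 1
        iz = int((zi - zmin) / bsz)
        if iz >= nz:
            iz = nz - 1
        if iz < 0:
            iz = 0
        for ox in range(-1, 2):
            jx = (ix + ox) % nx
            for oy in range(-1, 2):
                jy = (iy + oy) % ny
                for oz in range(-1, 2):
                    jz = iz + oz
                    if jz < 0 or jz >= nz:
                        continue
                    b = (jx * ny + jy) * nz + jz
                    for s in range(bin_start[b], bin_start[b + 1]):
                        j = order[s]
                        if j == i:
                            continue
                        dx = xi - pos[j, 0]
                        dx -= dom_x * np.rint(dx / dom_x)
                        dy = yi - pos[j, 1]
                        dy -= dom_y * np.rint(dy / dom_y)
                        dz = zi - pos[j, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 < cr2:
                            ncount[i] += 1
                        lim = rmax[i] + rmax[j] + adh_range
                        if d2 >= lim * lim:
                            continue
                        if d2 < 1e-12:
                            # coincident centers: deterministic hash-seeded
                            # push-apart, antisymmetric in (i, j), never NaN
                            lo = min(ids[i], ids[j])
                            hi = max(ids[i], ids[j])
                            h = (lo * 2654435761 + hi * 40503) & 1023
                            ang = 2.0 * np.pi * h / 1024.0
                            sgn = 1.0 if ids[i] > ids[j] else -1.0
                            F[i, 0] += sgn * k_rep * ai * np.cos(ang)
                            F[i, 1] += sgn * k_rep * ai * np.sin(ang)
                            continue
                        d = np.sqrt(d2)
                        uz2 = (dz * dz) / d2
                        R = directional_radius(ai, ci, uz2) + directional_radius(
                            aa[j], cc[j], uz2)
                        if d >= R + adh_range:
                            continue
                        if d < R:
                            mag = k_rep * (R - d)
                        else:
                            mag = -k_adh * (1.0 - (d - R) / adh_range)
                        inv = mag / d
                        F[i, 0] += inv * dx
                        F[i, 1] += inv * dy
                        F[i, 2] += inv * dz
        # membrane contact + stem anchoring; penetration is measured along the
        # surface normal (perpendicular clearance = vertical gap * n_z) so that
        # steep fiber flanks produce bounded, laterally directed forces
        gap = zi - mem_height(mkind, amp, lam, thick, period, dom_x, dom_y, xi, yi)
        nxv, nyv, nzv = mem_normal(mkind, amp, lam, thick, period,
                                   dom_x, dom_y, xi, yi)
        perp = gap * nzv
        if perp < ci:
            mag = k_mem * (ci - perp)
            F[i, 0] += mag * nxv
            F[i, 1] += mag * nyv
            F[i, 2] += mag * nzv
        if state[i] == stem_code:
            ax = anchor[i, 0]
            ay = anchor[i, 1]
            az = mem_height(mkind, amp, lam, thick, period, dom_x, dom_y, ax, ay)
            dxan = ax - xi
            dxan -= dom_x * np.rint(dxan / dom_x)
            dyan = ay - yi
            dyan -= dom_y * np.rint(dyan / dom_y)
            F[i, 0] += k_anchor * dxan
            F[i, 1] += k_anchor * dyan
            F[i, 2] += k_anchor * (az - zi)
    return F, ncount


@njit(cache=True)
def exposure_mask(pos, state, dom_x, dom_y, cone_height, corneo_code):
    """True for corneocytes with no other cell centre inside a 45-degree upward
    cone of the given height above them (surface-exposure rule); False for
    blocked corneocytes and for all non-corneocytes."""
    n = pos.shape[0]
    out = np.zeros(n, np.bool_)
    if n == 0:
        return out
    order, bin_start, nx, ny, nz, bsx, bsy, bsz, zmin = _build_grid(
        pos, dom_x, dom_y, cone_height, cone_height)
    for i in range(n):
        if state[i] != corneo_code:
            continue
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ix = int((xi % dom_x) / bsx)
        if ix >= nx:
            ix = nx - 1
        iy = int((yi % dom_y) / bsy)
        if iy >= ny:
            iy = ny - 1
        iz = int((zi - zmin) / bsz)
        if iz >= nz:
            iz = nz - 1
        if iz < 0:
            iz = 0
        exposed = True
        for ox in range(-1, 2):
            jx = (ix + ox) % nx
            for oy in range(-1, 2):
                jy = (iy + oy) % ny
                for oz in range(0, 2):
                    jz = iz + oz
                    if jz >= nz:
                        continue
                    b = (jx * ny + jy) * nz + jz
                    for s in range(bin_start[b], bin_start[b + 1]):
                        j = order[s]
                        if j == i:
                            continue
                        dz = pos[j, 2] - zi
                        if dz <= 0.0 or dz > cone_height:
                            continue
                        dx = pos[j, 0] - xi
                        dx -= dom_x * np.rint(dx / dom_x)
                        dy = pos[j, 1] - yi
                        dy -= dom_y * np.rint(dy / dom_y)
                        if dx * dx + dy * dy <= dz * dz:
                            exposed = False
                            break
                    if not exposed:
                        break
                if not exposed:
                    break
            if not exposed:
                break
        out[i] = exposed
    return out
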