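"""Numba kernels: tiling geometry, vertex forces, and FIRE descent.

All kernels operate on flat corner arrays (see
:class:`vertexclosure.tissue._FlatTopology`): corners grouped per cell in
cycle order, with minimum-image edge vectors taken corner-to-corner.  The
hot loops are written as plain loops so numba compiles them to tight
machine code; the Python layer owns all topology surgery.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# FIRE status codes
CONVERGED = 0
MAX_ITER = 1
NEED_T1 = 2


@njit(cache=True)
def _geometry(pos, lx, ly, cell_start, corner_v, areas, perims, edge_vec, corner_len):
    ncell = cell_start.size - 1
    for c in range(ncell):
        k0, k1 = cell_start[c], cell_start[c + 1]
        area = 0.0
        perim = 0.0
        # unwrapped coordinate of current corner relative to corner k0
        rx = 0.0
        ry = 0.0
        for k in range(k0, k1):
            vk = corner_v[k]
            kn = k + 1 if k + 1 < k1 else k0
            vn = corner_v[kn]
            ex = pos[vn, 0] - pos[vk, 0]
            ey = pos[vn, 1] - pos[vk, 1]
            ex -= lx * np.round(ex / lx)
            ey -= ly * np.round(ey / ly)
            edge_vec[k, 0] = ex
            edge_vec[k, 1] = ey
            l = np.sqrt(ex * ex + ey * ey)
            corner_len[k] = l
            perim += l
            # shoelace on unwrapped relative coordinates
            nx_ = rx + ex
            ny_ = ry + ey
            area += rx * ny_ - nx_ * ry
            rx = nx_
            ry = ny_
        areas[c] = 0.5 * area
        perims[c] = perim


@njit(cache=True)
def _forces_energy(
    pos, lx, ly, cell_start, corner_v, p0c, ka, kp, a0,
    force, areas, perims, edge_vec, corner_len,
):
    """Fill ``force`` with -dE/dr and return (energy, max |force| component)."""
    _geometry(pos, lx, ly, cell_start, corner_v, areas, perims, edge_vec, corner_len)
    force[:] = 0.0
    energy = 0.0
    ncell = cell_start.size - 1
    for c in range(ncell):
        k0, k1 = cell_start[c], cell_start[c + 1]
        da = areas[c] - a0
        dp = perims[c] - p0c[c]
        energy += 0.5 * ka * da * da + 0.5 * kp * dp * dp
        fa = ka * da
        fp = kp * dp
        for k in range(k0, k1):
            v = corner_v[k]
            kp_idx = k - 1 if k - 1 >= k0 else k1 - 1
            epx = edge_vec[kp_idx, 0]
            epy = edge_vec[kp_idx, 1]
            ecx = edge_vec[k, 0]
            ecy = edge_vec[k, 1]
            # area gradient: dA/dr_v = 0.5 * (s_y, -s_x), s = r_next - r_prev
            sx = epx + ecx
            sy = epy + ecy
            gax = 0.5 * sy
            gay = -0.5 * sx
            # perimeter gradient: unit(prev edge) - unit(current edge)
            lp = corner_len[kp_idx]
            lc = corner_len[k]
            gpx = 0.0
            gpy = 0.0
            if lp > 1e-14:
                gpx += epx / lp
                gpy += epy / lp
            if lc > 1e-14:
                gpx -= ecx / lc
                gpy -= ecy / lc
            force[v, 0] -= fa * gax + fp * gpx
            force[v, 1] -= fa * gay + fp * gpy
    maxf = 0.0
    for v in range(force.shape[0]):
        if abs(force[v, 0]) > maxf:
            maxf = abs(force[v, 0])
        if abs(force[v, 1]) > maxf:
            maxf = abs(force[v, 1])
    return energy, maxf


@njit(cache=True)
def _maxf(force):
    m = 0.0
    for v in range(force.shape[0]):
        if abs(force[v, 0]) > m:
            m = abs(force[v, 0])
        if abs(force[v, 1]) > m:
            m = abs(force[v, 1])
    return m


@njit(cache=True)
def _has_short(corner_len, pin):
    for k in range(corner_len.size):
        if corner_len[k] < pin:
            return True
    return False


@njit(cache=True)
def _apply_pins(
    force, vel, corner_v, corner_next, corner_cell, corner_len,
    perims, p0c, kp, pin, tension_floor,
):
    """Merge the dynamics of vertex pairs joined by collapsed edges.

    An edge contracted to numerically zero length under positive tension
    is a stable rosette vertex: the tension term makes the energy
    non-smooth there (linear in the separation), which would stall any
    descent.  Such pairs move with their mean force and velocity, i.e.
    as one merged vertex.  Pairs whose junction tension is below
    ``-tension_floor`` want to re-extend with a meaningful force (that
    lowers the energy linearly) and are left free; tensions inside
    ``(-tension_floor, 0]`` carry no physical drive and would otherwise
    make the residual creep for millions of iterations.
    """
    n = corner_len.size
    # collect contractile collapsed pairs once
    pa = np.empty(n, np.int64)
    pb = np.empty(n, np.int64)
    npairs = 0
    for k in range(n):
        if corner_len[k] >= pin:
            continue
        a = corner_v[k]
        b = corner_v[corner_next[k]]
        if a >= b:
            continue  # handle each edge once, via one of its half-edges
        c1 = corner_cell[k]
        # find the partner half-edge to identify the second cell
        c2 = -1
        for j in range(n):
            if (
                j != k
                and corner_v[j] == b
                and corner_v[corner_next[j]] == a
                and corner_len[j] < pin
            ):
                c2 = corner_cell[j]
                break
        tension = kp * (perims[c1] - p0c[c1])
        if c2 >= 0:
            tension += kp * (perims[c2] - p0c[c2])
        if tension <= -tension_floor:
            continue
        pa[npairs] = a
        pb[npairs] = b
        npairs += 1
    if npairs == 0:
        return
    # pairwise averaging, iterated so that chains of collapsed edges
    # (multi-vertex rosettes) converge to their common group mean
    for _ in range(60):
        changed = False
        for i in range(npairs):
            a = pa[i]
            b = pb[i]
            fx = 0.5 * (force[a, 0] + force[b, 0])
            fy = 0.5 * (force[a, 1] + force[b, 1])
            if (
                abs(force[a, 0] - fx) > 1e-15
                or abs(force[a, 1] - fy) > 1e-15
            ):
                changed = True
            force[a, 0] = fx
            force[b, 0] = fx
            force[a, 1] = fy
            force[b, 1] = fy
            vx = 0.5 * (vel[a, 0] + vel[b, 0])
            vy = 0.5 * (vel[a, 1] + vel[b, 1])
            vel[a, 0] = vx
            vel[b, 0] = vx
            vel[a, 1] = vy
            vel[b, 1] = vy
        if not changed:
            break


@njit(cache=True)
def _min_edge(corner_len, skip):
    best = 1e300
    best_k = -1
    for k in range(corner_len.size):
        if skip[k]:
            continue
        if corner_len[k] < best:
            best = corner_len[k]
            best_k = k
    return best, best_k


@njit(cache=True)
def _fire(
    pos, vel, lx, ly, cell_start, corner_v, corner_cell, p0c, ka, kp, a0,
    tol, max_iter, dt0, dt_max, f_inc, f_dec, alpha0, f_alpha, n_min,
    t1_threshold, check_every, skip, pin, pin_tension_floor,
):
    """Energy-monotone FIRE descent.

    Returns (status, iterations, energy, residual, flip_corner).  Descent
    is strictly monotone: a step that raises the energy is reverted and
    the timestep cut, so accepted iterates never increase E.  When
    ``t1_threshold > 0`` the shortest non-skipped edge is checked every
    ``check_every`` iterations and the kernel hands control back to the
    caller (status NEED_T1) for the topology flip.
    """
    nv = pos.shape[0]
    ncell = cell_start.size - 1
    ncorn = corner_v.size
    force = np.zeros((nv, 2))
    areas = np.empty(ncell)
    perims = np.empty(ncell)
    edge_vec = np.empty((ncorn, 2))
    corner_len = np.empty(ncorn)
    pos_prev = np.empty_like(pos)
    force_prev = np.empty_like(force)
    corner_next = np.empty(ncorn, np.int64)
    for c in range(ncell):
        for k in range(cell_start[c], cell_start[c + 1]):
            corner_next[k] = k + 1 if k + 1 < cell_start[c + 1] else cell_start[c]

    energy, maxf = _forces_energy(
        pos, lx, ly, cell_start, corner_v, p0c, ka, kp, a0,
        force, areas, perims, edge_vec, corner_len,
    )
    if pin > 0.0 and _has_short(corner_len, pin):
        _apply_pins(force, vel, corner_v, corner_next, corner_cell,
                    corner_len, perims, p0c, kp, pin, pin_tension_floor)
        maxf = _maxf(force)
    if maxf < tol:
        return CONVERGED, 0, energy, maxf, -1
    dt = dt0
    dt_min = dt0 * 1e-3
    alpha = alpha0
    n_pos = 0
    it = 0
    while it < max_iter:
        it += 1
        # FIRE velocity mixing
        p = 0.0
        vnorm = 0.0
        fnorm = 0.0
        for v in range(nv):
            p += force[v, 0] * vel[v, 0] + force[v, 1] * vel[v, 1]
            vnorm += vel[v, 0] ** 2 + vel[v, 1] ** 2
            fnorm += force[v, 0] ** 2 + force[v, 1] ** 2
        if p > 0.0:
            vnorm = np.sqrt(vnorm)
            fnorm = np.sqrt(fnorm)
            if fnorm > 0.0:
                mix = alpha * vnorm / fnorm
                for v in range(nv):
                    vel[v, 0] = (1.0 - alpha) * vel[v, 0] + mix * force[v, 0]
                    vel[v, 1] = (1.0 - alpha) * vel[v, 1] + mix * force[v, 1]
            n_pos += 1
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            vel[:] = 0.0
            dt = max(dt * f_dec, dt_min)
            alpha = alpha0
            n_pos = 0
        # semi-implicit Euler trial step
        pos_prev[:] = pos
        force_prev[:] = force
        e_prev = energy
        maxf_prev = maxf
        for v in range(nv):
            vel[v, 0] += dt * force[v, 0]
            vel[v, 1] += dt * force[v, 1]
            pos[v, 0] += dt * vel[v, 0]
            pos[v, 1] += dt * vel[v, 1]
        energy, maxf = _forces_energy(
            pos, lx, ly, cell_start, corner_v, p0c, ka, kp, a0,
            force, areas, perims, edge_vec, corner_len,
        )
        if pin > 0.0 and _has_short(corner_len, pin):
            _apply_pins(force, vel, corner_v, corner_next, corner_cell,
                        corner_len, perims, p0c, kp, pin, pin_tension_floor)
            maxf = _maxf(force)
        if energy > e_prev + 1e-12 * (1.0 + abs(e_prev)):
            # uphill step: revert and restart descent with a smaller dt
            pos[:] = pos_prev
            force[:] = force_prev
            energy = e_prev
            maxf = maxf_prev
            vel[:] = 0.0
            dt = max(dt * f_dec, dt_min)
            alpha = alpha0
            n_pos = 0
            continue
        if maxf < tol:
            return CONVERGED, it, energy, maxf, -1
        if t1_threshold > 0.0 and it % check_every == 0:
            shortest, k = _min_edge(corner_len, skip)
            if k >= 0 and shortest < t1_threshold:
                return NEED_T1, it, energy, maxf, k
    return MAX_ITER, it, energy, maxf, -1


# ---------------------------------------------------------------------------
# Python wrappers
# ---------------------------------------------------------------------------

def geometry_arrays(state, topo):
    """(areas, perimeters, edge vectors) for alive cells, in topo order."""
    ncell = topo.n_cells
    ncorn = topo.n_corners
    areas = np.empty(ncell)
    perims = np.empty(ncell)
    edge_vec = np.empty((ncorn, 2))
    corner_len = np.empty(ncorn)
    _geometry(
        state.vertices, state.box.lx, state.box.ly,
        topo.cell_start, topo.corner_vertex,
        areas, perims, edge_vec, corner_len,
    )
    return areas, perims, edge_vec


def pinned_residual(state, topo, p0c, ka, kp, a0, pin, tension_floor):
    """Rosette-aware force residual: max |component| after merging the
    dynamics of vertex pairs joined by collapsed contractile edges."""
    nv = state.vertices.shape[0]
    force = np.zeros((nv, 2))
    vel = np.zeros((nv, 2))
    areas = np.empty(topo.n_cells)
    perims = np.empty(topo.n_cells)
    edge_vec = np.empty((topo.n_corners, 2))
    corner_len = np.empty(topo.n_corners)
    _, maxf = _forces_energy(
        state.vertices, state.box.lx, state.box.ly,
        topo.cell_start, topo.corner_vertex, p0c, ka, kp, a0,
        force, areas, perims, edge_vec, corner_len,
    )
    if pin > 0.0 and _has_short(corner_len, pin):
        _apply_pins(force, vel, topo.corner_vertex, topo.corner_next,
                    topo.corner_cell, corner_len, perims, p0c, kp, pin,
                    tension_floor)
        maxf = _maxf(force)
    return maxf


def forces_energy(state, topo, p0c, ka, kp, a0):
    """(force array over all vertex rows, energy, max-component residual)."""
    nv = state.vertices.shape[0]
    force = np.zeros((nv, 2))
    areas = np.empty(topo.n_cells)
    perims = np.empty(topo.n_cells)
    edge_vec = np.empty((topo.n_corners, 2))
    corner_len = np.empty(topo.n_corners)
    energy, maxf = _forces_energy(
        state.vertices, state.box.lx, state.box.ly,
        topo.cell_start, topo.corner_vertex, p0c, ka, kp, a0,
        force, areas, perims, edge_vec, corner_len,
    )
    return force, energy, maxf
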