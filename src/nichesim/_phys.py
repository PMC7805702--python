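"""Impulse-based 2D rigid-body kernels.

This is the concrete physics backend behind the world module: circles and
oriented boxes under gravity, sequential-impulse contact resolution with
Coulomb friction and Baumgarte positional stabilisation.  All functions are
numba-compiled and operate on flat arrays so that the whole episode loop can
run inside compiled code.

Conventions (fixed for the whole package):
  * origin bottom-left, y increases upward, gravity acts along -y;
  * angles in radians, counterclockwise positive;
  * "clockwise" torque therefore has a negative sign.

Body layout: index 0 = prey (circle), 1 = predator (circle), 2.. = placed
objects (oriented rectangles).  Static field tiles are axis-aligned squares
kept in a separate array and take part in collisions with infinite mass.

Shape kinds: 0 = circle (half[i,0] is the radius), 1 = box, 2 = board
(half[i] are the half extents).
"""

import numpy as np
from numba import njit

# Solver constants.  BETA is the Baumgarte positional-correction factor,
# SLOP the penetration allowed before correction kicks in, ITERS the number
# of sequential-impulse sweeps per step.
BETA = 0.2
SLOP = 0.05
ITERS = 10
MAX_CONTACTS = 2048

KIND_CIRCLE = 0
KIND_BOX = 1
KIND_BOARD = 2


@njit(cache=True, inline="always")
def _cross(ax, ay, bx, by):
    return ax * by - ay * bx


@njit(cache=True, inline="always")
def _rot(angle):
    c = np.cos(angle)
    s = np.sin(angle)
    return c, s


@njit(cache=True)
def aabb_of(kind, px, py, angle, hx, hy):
    """Axis-aligned bounds (xmin, ymin, xmax, ymax) of one body."""
    if kind == KIND_CIRCLE:
        return px - hx, py - hx, px + hx, py + hx
    c, s = _rot(angle)
    ex = abs(c) * hx + abs(s) * hy
    ey = abs(s) * hx + abs(c) * hy
    return px - ex, py - ey, px + ex, py + ey


@njit(cache=True)
def overlap_circle_circle(ax, ay, ra, bx, by, rb):
    dx = bx - ax
    dy = by - ay
    r = ra + rb
    return dx * dx + dy * dy < r * r


@njit(cache=True)
def overlap_circle_obb(cx, cy, r, px, py, angle, hx, hy):
    c, s = _rot(angle)
    dx = cx - px
    dy = cy - py
    lx = c * dx + s * dy
    ly = -s * dx + c * dy
    qx = min(max(lx, -hx), hx)
    qy = min(max(ly, -hy), hy)
    ex = lx - qx
    ey = ly - qy
    return ex * ex + ey * ey < r * r


@njit(cache=True)
def overlap_obb_obb(pax, pay, aa, hax, hay, pbx, pby, ab, hbx, hby):
    """Separating-axis test for two oriented rectangles (boolean only)."""
    ca, sa = _rot(aa)
    cb, sb = _rot(ab)
    dx = pbx - pax
    dy = pby - pay
    # d in A frame
    dax = ca * dx + sa * dy
    day = -sa * dx + ca * dy
    # C = RotA^T RotB
    c00 = ca * cb + sa * sb
    c01 = -ca * sb + sa * cb
    c10 = -sa * cb + ca * sb
    c11 = sa * sb + ca * cb
    a00 = abs(c00)
    a01 = abs(c01)
    a10 = abs(c10)
    a11 = abs(c11)
    if abs(dax) > hax + a00 * hbx + a01 * hby:
        return False
    if abs(day) > hay + a10 * hbx + a11 * hby:
        return False
    # d in B frame
    dbx = cb * dx + sb * dy
    dby = -sb * dx + cb * dy
    if abs(dbx) > hbx + a00 * hax + a10 * hay:
        return False
    if abs(dby) > hby + a01 * hax + a11 * hay:
        return False
    return True


@njit(cache=True)
def _clip_segment(v, d, nx, ny, offset):
    """Clip a 2-point segment to the half-plane n.p <= offset.

    v: (2,2) points, d: (2,) depths carried along.  Returns point count and
    writes results back into v/d.
    """
    out = np.empty((2, 2))
    outd = np.empty(2)
    n = 0
    d0 = nx * v[0, 0] + ny * v[0, 1] - offset
    d1 = nx * v[1, 0] + ny * v[1, 1] - offset
    if d0 <= 0.0:
        out[n, 0] = v[0, 0]
        out[n, 1] = v[0, 1]
        outd[n] = d[0]
        n += 1
    if d1 <= 0.0:
        out[n, 0] = v[1, 0]
        out[n, 1] = v[1, 1]
        outd[n] = d[1]
        n += 1
    if d0 * d1 < 0.0 and n < 2:
        t = d0 / (d0 - d1)
        out[n, 0] = v[0, 0] + t * (v[1, 0] - v[0, 0])
        out[n, 1] = v[0, 1] + t * (v[1, 1] - v[0, 1])
        outd[n] = d[0] + t * (d[1] - d[0])
        n += 1
    for i in range(n):
        v[i, 0] = out[i, 0]
        v[i, 1] = out[i, 1]
        d[i] = outd[i]
    return n


@njit(cache=True)
def _box_box_manifold(prx, pry, ar, hrx, hry, pix, piy, ai, hix, hiy,
                      axis, sign, pts, depths):
    """Reference-face clipping for two overlapping OBBs.

    The reference box is (pr, ar, hr); `axis` (0 or 1) and `sign` select its
    reference face.  Writes up to two contact points (on the incident box)
    and penetration depths; the contact normal is the outward reference-face
    normal, returned as (n, nx, ny).
    """
    cr, sr = _rot(ar)
    if axis == 0:
        fnx = cr * sign
        fny = sr * sign
        snx = -sr
        sny = cr
        hface = hrx
        hside = hry
    else:
        fnx = -sr * sign
        fny = cr * sign
        snx = cr
        sny = sr
        hface = hry
        hside = hrx
    front = prx * fnx + pry * fny + hface
    side = prx * snx + pry * sny
    neg_side = -side + hside
    pos_side = side + hside

    # incident edge: the face of the incident box most anti-parallel to fn
    ci, si = _rot(ai)
    # -RotI^T fn
    nlx = -(ci * fnx + si * fny)
    nly = -(-si * fnx + ci * fny)
    v = np.empty((2, 2))
    if abs(nlx) > abs(nly):
        sgn = 1.0 if nlx > 0.0 else -1.0
        v[0, 0] = sgn * hix
        v[0, 1] = -hiy
        v[1, 0] = sgn * hix
        v[1, 1] = hiy
    else:
        sgn = 1.0 if nly > 0.0 else -1.0
        v[0, 0] = -hix
        v[0, 1] = sgn * hiy
        v[1, 0] = hix
        v[1, 1] = sgn * hiy
    for k in range(2):
        lx = v[k, 0]
        ly = v[k, 1]
        v[k, 0] = pix + ci * lx - si * ly
        v[k, 1] = piy + si * lx + ci * ly

    dcarry = np.zeros(2)
    if _clip_segment(v, dcarry, -snx, -sny, neg_side) < 2:
        return 0, fnx, fny
    if _clip_segment(v, dcarry, snx, sny, pos_side) < 2:
        return 0, fnx, fny

    n = 0
    for k in range(2):
        sep = fnx * v[k, 0] + fny * v[k, 1] - front
        if sep <= 0.0:
            pts[n, 0] = v[k, 0]
            pts[n, 1] = v[k, 1]
            depths[n] = -sep
            n += 1
    return n, fnx, fny


@njit(cache=True)
def collide_obb_obb(pax, pay, aa, hax, hay, pbx, pby, ab, hbx, hby,
                    pts, depths):
    """Contact manifold between OBB A and OBB B.

    Returns (count, nx, ny) with the normal pointing from A to B.
    """
    ca, sa = _rot(aa)
    cb, sb = _rot(ab)
    dx = pbx - pax
    dy = pby - pay
    dax = ca * dx + sa * dy
    day = -sa * dx + ca * dy
    dbx = cb * dx + sb * dy
    dby = -sb * dx + cb * dy
    c00 = ca * cb + sa * sb
    c01 = -ca * sb + sa * cb
    c10 = -sa * cb + ca * sb
    c11 = sa * sb + ca * cb
    a00 = abs(c00)
    a01 = abs(c01)
    a10 = abs(c10)
    a11 = abs(c11)

    fa_x = abs(dax) - hax - (a00 * hbx + a01 * hby)
    if fa_x > 0.0:
        return 0, 0.0, 0.0
    fa_y = abs(day) - hay - (a10 * hbx + a11 * hby)
    if fa_y > 0.0:
        return 0, 0.0, 0.0
    fb_x = abs(dbx) - hbx - (a00 * hax + a10 * hay)
    if fb_x > 0.0:
        return 0, 0.0, 0.0
    fb_y = abs(dby) - hby - (a01 * hax + a11 * hay)
    if fb_y > 0.0:
        return 0, 0.0, 0.0

    # best (least-penetrating) axis, with a bias toward keeping the current
    # choice to avoid jitter (box2d-lite convention)
    REL = 0.95
    ABS = 0.01
    best = 0  # 0: A x-face, 1: A y-face, 2: B x-face, 3: B y-face
    sep = fa_x
    if fa_y > REL * sep + ABS * hay:
        best = 1
        sep = fa_y
    if fb_x > REL * sep + ABS * hbx:
        best = 2
        sep = fb_x
    if fb_y > REL * sep + ABS * hby:
        best = 3
        sep = fb_y

    if best == 0:
        sign = 1.0 if dax > 0.0 else -1.0
        n, nx, ny = _box_box_manifold(pax, pay, aa, hax, hay,
                                      pbx, pby, ab, hbx, hby, 0, sign,
                                      pts, depths)
        return n, nx, ny
    elif best == 1:
        sign = 1.0 if day > 0.0 else -1.0
        n, nx, ny = _box_box_manifold(pax, pay, aa, hax, hay,
                                      pbx, pby, ab, hbx, hby, 1, sign,
                                      pts, depths)
        return n, nx, ny
    elif best == 2:
        sign = 1.0 if dbx < 0.0 else -1.0  # toward A
        n, nx, ny = _box_box_manifold(pbx, pby, ab, hbx, hby,
                                      pax, pay, aa, hax, hay, 0, sign,
                                      pts, depths)
        return n, -nx, -ny
    else:
        sign = 1.0 if dby < 0.0 else -1.0
        n, nx, ny = _box_box_manifold(pbx, pby, ab, hbx, hby,
                                      pax, pay, aa, hax, hay, 1, sign,
                                      pts, depths)
        return n, -nx, -ny


@njit(cache=True)
def collide_circle_obb(cx, cy, r, px, py, angle, hx, hy):
    """Contact between circle A and OBB B.

    Returns (hit, nx, ny, pointx, pointy, depth); normal from circle to box.
    """
    c, s = _rot(angle)
    dx = cx - px
    dy = cy - py
    lx = c * dx + s * dy
    ly = -s * dx + c * dy
    qx = min(max(lx, -hx), hx)
    qy = min(max(ly, -hy), hy)
    inside = (qx == lx) and (qy == ly)
    if inside:
        # circle center inside the box: push out along least-penetrated axis
        mx = hx - abs(lx)
        my = hy - abs(ly)
        if mx < my:
            qx = hx if lx > 0.0 else -hx
        else:
            qy = hy if ly > 0.0 else -hy
    ex = lx - qx
    ey = ly - qy
    d2 = ex * ex + ey * ey
    if not inside and d2 >= r * r:
        return False, 0.0, 0.0, 0.0, 0.0, 0.0
    dist = np.sqrt(d2)
    if dist < 1e-12:
        nlx, nly = 0.0, 1.0
        dist = 0.0
    else:
        nlx = ex / dist
        nly = ey / dist
    if inside:
        nlx = -nlx
        nly = -nly
        depth = r + dist
    else:
        depth = r - dist
    # world-frame normal pointing from box surface toward the circle center;
    # flip so it runs circle -> box
    wnx = c * nlx - s * nly
    wny = s * nlx + c * nly
    pxw = px + c * qx - s * qy
    pyw = py + s * qx + c * qy
    return True, -wnx, -wny, pxw, pyw, depth


@njit(cache=True)
def step_world(pos, angle, vel, angvel, inv_m, inv_I, kind, active, half,
               tiles, tile_half, walls, dt, gravity_y, mu, restitution,
               torque_acc, flags):
    """Advance the world by one timestep of dt seconds.

    Integrates gravity and queued torques, builds the contact set (bodies
    against bodies, static tiles, and static boundary walls), resolves it
    with sequential impulses, then integrates positions.  `walls` is an
    (nw, 4) array of axis-aligned static boxes (cx, cy, hx, hy) that bound
    the field; they collide but are neither sensed nor counted as field
    tiles.  `torque_acc` is consumed and cleared.  `flags` (int64[3])
    receives [prey-predator contact, prey bottom-contact, predator
    bottom-contact]; bottom contact means a touch point within ±45° of
    straight down against a tile or placed object (walls do not qualify).
    flags[3]/flags[4] record whether the prey/predator touched any placed
    object (at any angle) during the step.
    """
    nb = pos.shape[0]
    nt = tiles.shape[0]
    nw = walls.shape[0]

    # 1. integrate forces
    for i in range(nb):
        if active[i] and inv_m[i] > 0.0:
            vel[i, 1] += gravity_y * dt
            angvel[i] += torque_acc[i] * inv_I[i] * dt
        torque_acc[i] = 0.0

    # 2. contact generation
    cia = np.empty(MAX_CONTACTS, np.int64)
    cib = np.empty(MAX_CONTACTS, np.int64)  # -1 => static tile
    cn = np.empty((MAX_CONTACTS, 2))
    cp = np.empty((MAX_CONTACTS, 2))
    cd = np.empty(MAX_CONTACTS)
    nc = 0

    pts = np.empty((2, 2))
    depths = np.empty(2)

    lo = np.empty((nb, 2))
    hi = np.empty((nb, 2))
    for i in range(nb):
        if active[i]:
            x0, y0, x1, y1 = aabb_of(kind[i], pos[i, 0], pos[i, 1],
                                     angle[i], half[i, 0], half[i, 1])
            lo[i, 0] = x0
            lo[i, 1] = y0
            hi[i, 0] = x1
            hi[i, 1] = y1

    for i in range(nb):
        if not active[i]:
            continue
        for j in range(i + 1, nb):
            if not active[j]:
                continue
            if (lo[i, 0] > hi[j, 0] or lo[j, 0] > hi[i, 0]
                    or lo[i, 1] > hi[j, 1] or lo[j, 1] > hi[i, 1]):
                continue
            if kind[i] == KIND_CIRCLE and kind[j] == KIND_CIRCLE:
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                rsum = half[i, 0] + half[j, 0]
                d2 = dx * dx + dy * dy
                if d2 < rsum * rsum and nc < MAX_CONTACTS:
                    dist = np.sqrt(d2)
                    if dist < 1e-12:
                        nx, ny = 0.0, 1.0
                        dist = 0.0
                    else:
                        nx = dx / dist
                        ny = dy / dist
                    depth = rsum - dist
                    cia[nc] = i
                    cib[nc] = j
                    cn[nc, 0] = nx
                    cn[nc, 1] = ny
                    cp[nc, 0] = pos[i, 0] + nx * (half[i, 0] - 0.5 * depth)
                    cp[nc, 1] = pos[i, 1] + ny * (half[i, 0] - 0.5 * depth)
                    cd[nc] = depth
                    nc += 1
            elif kind[i] == KIND_CIRCLE:
                hit, nx, ny, pxw, pyw, depth = collide_circle_obb(
                    pos[i, 0], pos[i, 1], half[i, 0],
                    pos[j, 0], pos[j, 1], angle[j], half[j, 0], half[j, 1])
                if hit and nc < MAX_CONTACTS:
                    cia[nc] = i
                    cib[nc] = j
                    cn[nc, 0] = nx
                    cn[nc, 1] = ny
                    cp[nc, 0] = pxw
                    cp[nc, 1] = pyw
                    cd[nc] = depth
                    nc += 1
            elif kind[j] == KIND_CIRCLE:
                hit, nx, ny, pxw, pyw, depth = collide_circle_obb(
                    pos[j, 0], pos[j, 1], half[j, 0],
                    pos[i, 0], pos[i, 1], angle[i], half[i, 0], half[i, 1])
                if hit and nc < MAX_CONTACTS:
                    cia[nc] = i
                    cib[nc] = j
                    cn[nc, 0] = -nx  # flip: helper returns circle->box
                    cn[nc, 1] = -ny
                    cp[nc, 0] = pxw
                    cp[nc, 1] = pyw
                    cd[nc] = depth
                    nc += 1
            else:
                n, nx, ny = collide_obb_obb(
                    pos[i, 0], pos[i, 1], angle[i], half[i, 0], half[i, 1],
                    pos[j, 0], pos[j, 1], angle[j], half[j, 0], half[j, 1],
                    pts, depths)
                for k in range(n):
                    if nc < MAX_CONTACTS:
                        cia[nc] = i
                        cib[nc] = j
                        cn[nc, 0] = nx
                        cn[nc, 1] = ny
                        cp[nc, 0] = pts[k, 0]
                        cp[nc, 1] = pts[k, 1]
                        cd[nc] = depths[k]
                        nc += 1

        # body vs static tiles
        for t in range(nt):
            tx = tiles[t, 0]
            ty = tiles[t, 1]
            if (lo[i, 0] > tx + tile_half or tx - tile_half > hi[i, 0]
                    or lo[i, 1] > ty + tile_half
                    or ty - tile_half > hi[i, 1]):
                continue
            if kind[i] == KIND_CIRCLE:
                hit, nx, ny, pxw, pyw, depth = collide_circle_obb(
                    pos[i, 0], pos[i, 1], half[i, 0],
                    tx, ty, 0.0, tile_half, tile_half)
                if hit and nc < MAX_CONTACTS:
                    cia[nc] = i
                    cib[nc] = -1 - t
                    cn[nc, 0] = nx
                    cn[nc, 1] = ny
                    cp[nc, 0] = pxw
                    cp[nc, 1] = pyw
                    cd[nc] = depth
                    nc += 1
            else:
                n, nx, ny = collide_obb_obb(
                    pos[i, 0], pos[i, 1], angle[i], half[i, 0], half[i, 1],
                    tx, ty, 0.0, tile_half, tile_half,
                    pts, depths)
                for k in range(n):
                    if nc < MAX_CONTACTS:
                        cia[nc] = i
                        cib[nc] = -1 - t
                        cn[nc, 0] = nx
                        cn[nc, 1] = ny
                        cp[nc, 0] = pts[k, 0]
                        cp[nc, 1] = pts[k, 1]
                        cd[nc] = depths[k]
                        nc += 1

        # body vs boundary walls
        for t in range(nw):
            wx = walls[t, 0]
            wy = walls[t, 1]
            whx = walls[t, 2]
            why = walls[t, 3]
            if (lo[i, 0] > wx + whx or wx - whx > hi[i, 0]
                    or lo[i, 1] > wy + why or wy - why > hi[i, 1]):
                continue
            if kind[i] == KIND_CIRCLE:
                hit, nx, ny, pxw, pyw, depth = collide_circle_obb(
                    pos[i, 0], pos[i, 1], half[i, 0],
                    wx, wy, 0.0, whx, why)
                if hit and nc < MAX_CONTACTS:
                    cia[nc] = i
                    cib[nc] = -1 - nt - t
                    cn[nc, 0] = nx
                    cn[nc, 1] = ny
                    cp[nc, 0] = pxw
                    cp[nc, 1] = pyw
                    cd[nc] = depth
                    nc += 1
            else:
                n, nx, ny = collide_obb_obb(
                    pos[i, 0], pos[i, 1], angle[i], half[i, 0], half[i, 1],
                    wx, wy, 0.0, whx, why, pts, depths)
                for k in range(n):
                    if nc < MAX_CONTACTS:
                        cia[nc] = i
                        cib[nc] = -1 - nt - t
                        cn[nc, 0] = nx
                        cn[nc, 1] = ny
                        cp[nc, 0] = pts[k, 0]
                        cp[nc, 1] = pts[k, 1]
                        cd[nc] = depths[k]
                        nc += 1

    # 3. sequential impulse solver
    bias = np.empty(nc)
    pn = np.zeros(nc)
    pt = np.zeros(nc)
    inv_dt = 1.0 / dt
    for c in range(nc):
        b = BETA * inv_dt * max(cd[c] - SLOP, 0.0)
        if restitution > 0.0:
            i = cia[c]
            j = cib[c]
            rax = cp[c, 0] - pos[i, 0]
            ray = cp[c, 1] - pos[i, 1]
            rvx = -vel[i, 0] + angvel[i] * ray
            rvy = -vel[i, 1] - angvel[i] * rax
            if j >= 0:
                rbx = cp[c, 0] - pos[j, 0]
                rby = cp[c, 1] - pos[j, 1]
                rvx += vel[j, 0] - angvel[j] * rby
                rvy += vel[j, 1] + angvel[j] * rbx
            vn0 = rvx * cn[c, 0] + rvy * cn[c, 1]
            if vn0 < -1.0:
                b = max(b, -restitution * vn0)
        bias[c] = b

    for _ in range(ITERS):
        for c in range(nc):
            i = cia[c]
            j = cib[c]
            nx = cn[c, 0]
            ny = cn[c, 1]
            rax = cp[c, 0] - pos[i, 0]
            ray = cp[c, 1] - pos[i, 1]
            ima = inv_m[i]
            iIa = inv_I[i]
            if j >= 0:
                rbx = cp[c, 0] - pos[j, 0]
                rby = cp[c, 1] - pos[j, 1]
                imb = inv_m[j]
                iIb = inv_I[j]
                rvx = vel[j, 0] - angvel[j] * rby - vel[i, 0] + angvel[i] * ray
                rvy = vel[j, 1] + angvel[j] * rbx - vel[i, 1] - angvel[i] * rax
            else:
                rbx = 0.0
                rby = 0.0
                imb = 0.0
                iIb = 0.0
                rvx = -vel[i, 0] + angvel[i] * ray
                rvy = -vel[i, 1] - angvel[i] * rax
            vn = rvx * nx + rvy * ny
            cra = _cross(rax, ray, nx, ny)
            crb = _cross(rbx, rby, nx, ny)
            kn = ima + imb + cra * cra * iIa + crb * crb * iIb
            if kn > 0.0:
                dpn = (bias[c] - vn) / kn
                pn0 = pn[c]
                pn[c] = max(pn0 + dpn, 0.0)
                dpn = pn[c] - pn0
                px = dpn * nx
                py = dpn * ny
                vel[i, 0] -= px * ima
                vel[i, 1] -= py * ima
                angvel[i] -= iIa * _cross(rax, ray, px, py)
                if j >= 0:
                    vel[j, 0] += px * imb
                    vel[j, 1] += py * imb
                    angvel[j] += iIb * _cross(rbx, rby, px, py)

            # friction along the tangent
            tx = -ny
            ty = nx
            if j >= 0:
                rvx = vel[j, 0] - angvel[j] * rby - vel[i, 0] + angvel[i] * ray
                rvy = vel[j, 1] + angvel[j] * rbx - vel[i, 1] - angvel[i] * rax
            else:
                rvx = -vel[i, 0] + angvel[i] * ray
                rvy = -vel[i, 1] - angvel[i] * rax
            vt = rvx * tx + rvy * ty
            cta = _cross(rax, ray, tx, ty)
            ctb = _cross(rbx, rby, tx, ty)
            kt = ima + imb + cta * cta * iIa + ctb * ctb * iIb
            if kt > 0.0:
                dpt = -vt / kt
                max_pt = mu * pn[c]
                pt0 = pt[c]
                pt[c] = min(max(pt0 + dpt, -max_pt), max_pt)
                dpt = pt[c] - pt0
                px = dpt * tx
                py = dpt * ty
                vel[i, 0] -= px * ima
                vel[i, 1] -= py * ima
                angvel[i] -= iIa * _cross(rax, ray, px, py)
                if j >= 0:
                    vel[j, 0] += px * imb
                    vel[j, 1] += py * imb
                    angvel[j] += iIb * _cross(rbx, rby, px, py)

    # 4. integrate positions
    for i in range(nb):
        if active[i] and inv_m[i] > 0.0:
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            angle[i] += angvel[i] * dt

    # 5. contact flags
    for k in range(5):
        flags[k] = 0
    for c in range(nc):
        i = cia[c]
        j = cib[c]
        if (i == 0 and j == 1) or (i == 1 and j == 0):
            flags[0] = 1
        for agent in range(2):
            # supports are placed objects and field tiles, not walls
            other_is_support = False
            touches_object = False
            if i == agent:
                other_is_support = j >= 2 or (-nt <= j <= -1)
                touches_object = j >= 2
            elif j == agent:
                other_is_support = i >= 2
                touches_object = i >= 2
            else:
                continue
            if touches_object:
                flags[3 + agent] = 1
            if other_is_support:
                dx = cp[c, 0] - pos[agent, 0]
                dy = cp[c, 1] - pos[agent, 1]
                if dy < 0.0 and abs(dx) <= -dy:
                    flags[1 + agent] = 1
    return nc


@njit(cache=True)
def placement_clear(px, py, ang, hx, hy,
                    pos, angle, kind, active, half,
                    tiles, tile_half, field_w, field_h):
    """True iff an OBB at the given pose lies fully inside the field and
    overlaps no tile, placed object, or agent body."""
    c, s = _rot(ang)
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            cx = px + c * sx * hx - s * sy * hy
            cy = py + s * sx * hx + c * sy * hy
            if cx < 0.0 or cx > field_w or cy < 0.0 or cy > field_h:
                return False
    for t in range(tiles.shape[0]):
        if overlap_obb_obb(px, py, ang, hx, hy,
                           tiles[t, 0], tiles[t, 1], 0.0,
                           tile_half, tile_half):
            return False
    for i in range(pos.shape[0]):
        if not active[i]:
            continue
        if kind[i] == KIND_CIRCLE:
            if overlap_circle_obb(pos[i, 0], pos[i, 1], half[i, 0],
                                  px, py, ang, hx, hy):
                return False
        else:
            if overlap_obb_obb(px, py, ang, hx, hy,
                               pos[i, 0], pos[i, 1], angle[i],
                               half[i, 0], half[i, 1]):
                return False
    return True
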