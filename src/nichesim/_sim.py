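"""Compiled kernels for sensing, the prey controller, and whole episodes.

The Python-level operations in :mod:`nichesim.agents` and
:mod:`nichesim.evaluation` are thin wrappers over these functions, and
``episode_kernel`` fuses the same per-step sequence (sense -> forward ->
decode -> act; predator policy; physics step; capture bookkeeping) into one
compiled loop so that evolutionary runs are fast.  Both paths execute the
identical arithmetic, which the test suite checks step for step.
"""

import numpy as np
from numba import njit

from ._phys import (KIND_BOARD, KIND_BOX, placement_clear, step_world)

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def sense_kernel(prey_x, prey_y, pred_x, pred_y,
                 pos, kind, active, tiles, f_prey, remaining, budget):
    """12-dimensional prey input vector.

    Layout: [n_tiles, n_boxes, n_boards,
             com_tiles(2), com_boxes(2), com_boards(2),
             predator_offset(2), remaining/B].
    Per-class centres of mass are over members whose centres lie within
    ``f_prey`` of the prey, relative to the prey; a class with no member in
    range contributes a zero vector, as does an out-of-range predator.
    """
    x = np.zeros(12)
    f2 = f_prey * f_prey
    nt = 0
    tx = 0.0
    ty = 0.0
    for t in range(tiles.shape[0]):
        dx = tiles[t, 0] - prey_x
        dy = tiles[t, 1] - prey_y
        if dx * dx + dy * dy <= f2:
            nt += 1
            tx += dx
            ty += dy
    nbox = 0
    bx = 0.0
    by = 0.0
    nbrd = 0
    rx = 0.0
    ry = 0.0
    for i in range(2, pos.shape[0]):
        if not active[i]:
            continue
        dx = pos[i, 0] - prey_x
        dy = pos[i, 1] - prey_y
        if dx * dx + dy * dy <= f2:
            if kind[i] == KIND_BOX:
                nbox += 1
                bx += dx
                by += dy
            elif kind[i] == KIND_BOARD:
                nbrd += 1
                rx += dx
                ry += dy
    x[0] = nt
    x[1] = nbox
    x[2] = nbrd
    if nt > 0:
        x[3] = tx / nt
        x[4] = ty / nt
    if nbox > 0:
        x[5] = bx / nbox
        x[6] = by / nbox
    if nbrd > 0:
        x[7] = rx / nbrd
        x[8] = ry / nbrd
    dx = pred_x - prey_x
    dy = pred_y - prey_y
    if dx * dx + dy * dy <= f2:
        x[9] = dx
        x[10] = dy
    x[11] = remaining / budget
    return x


@njit(cache=True)
def forward_kernel(w1, w2, x):
    """Fully connected 12 -> H -> 7 network.

    ``w1`` is (H, 13) with the bias in the last column, ``w2`` is (7, H+1).
    Sigmoid on the hidden layer and on outputs 1, 2, 5, 6, 7; the two
    object-type outputs (3 and 4) stay linear, since only their comparison
    is used.
    """
    h = w1.shape[0]
    hid = np.empty(h)
    for i in range(h):
        s = w1[i, 12]
        for j in range(12):
            s += w1[i, j] * x[j]
        hid[i] = 1.0 / (1.0 + np.exp(-s))
    o = np.empty(7)
    for i in range(7):
        s = w2[i, h]
        for j in range(h):
            s += w2[i, j] * hid[j]
        if i == 2 or i == 3:
            o[i] = s
        else:
            o[i] = 1.0 / (1.0 + np.exp(-s))
    return o


@njit(cache=True)
def insert_object_kernel(pos, angle, vel, angvel, inv_m, inv_I, kind,
                         active, half, obj_kind, x, y, ang, hx, hy, density):
    """Activate the first free object slot with the given pose; returns the
    slot index or -1 when the cap is exhausted."""
    for i in range(2, pos.shape[0]):
        if not active[i]:
            m = density * (2.0 * hx) * (2.0 * hy)
            inertia = m * ((2.0 * hx) ** 2 + (2.0 * hy) ** 2) / 12.0
            pos[i, 0] = x
            pos[i, 1] = y
            angle[i] = ang
            vel[i, 0] = 0.0
            vel[i, 1] = 0.0
            angvel[i] = 0.0
            kind[i] = obj_kind
            half[i, 0] = hx
            half[i, 1] = hy
            inv_m[i] = 1.0 / m
            inv_I[i] = 1.0 / inertia
            active[i] = True
            return i
    return -1


@njit(cache=True)
def episode_kernel(pos, angle, vel, angvel, inv_m, inv_I, kind, active,
                   half, torque_acc, flags, tiles, tile_half, walls,
                   dt, gravity_y, mu, restitution, density, torque_factor,
                   field_w, field_h,
                   w1, w2, n_steps,
                   f_prey, l_prey, budget,
                   prey_coeff, pred_coeff, f_pred,
                   jump_mag, jump_cos, jump_sin, steps_per_second,
                   box_half, board_hx, board_hy,
                   prey_start_x, prey_start_y, pred_start_x, pred_start_y):
    """Run one fitness-evaluation episode in compiled code.

    Mutates the world arrays in place and returns the capture count.  The
    per-step order is: prey senses and acts (torque + optional placement),
    the scripted predator chases and may jump, physics advances, and a
    prey-predator touch increments the capture count and teleports both
    agents back to their episode starts.
    """
    captures = 0
    last_jump = -steps_per_second
    for t in range(n_steps):
        n_obj = 0
        for i in range(2, pos.shape[0]):
            if active[i]:
                n_obj += 1
        remaining = budget - n_obj

        x = sense_kernel(pos[0, 0], pos[0, 1], pos[1, 0], pos[1, 1],
                         pos, kind, active, tiles, f_prey,
                         float(remaining), float(budget))
        o = forward_kernel(w1, w2, x)

        # prey torque: speed-damped kgf·m magnitude, converted to engine N·m
        speed = np.sqrt(vel[0, 0] ** 2 + vel[0, 1] ** 2)
        mag = prey_coeff / (speed + 1.0) * torque_factor
        if o[0] > 0.5:
            torque_acc[0] -= mag  # clockwise
        else:
            torque_acc[0] += mag

        # prey placement
        if o[1] > 0.5 and remaining > 0:
            r = l_prey * o[4]
            theta = TWO_PI * o[5]
            rot = TWO_PI * o[6]
            ox = pos[0, 0] + r * np.cos(theta)
            oy = pos[0, 1] + r * np.sin(theta)
            if o[2] > o[3]:
                okind = KIND_BOX
                hx = box_half
                hy = box_half
            else:
                okind = KIND_BOARD
                hx = board_hx
                hy = board_hy
            if placement_clear(ox, oy, rot, hx, hy, pos, angle, kind,
                               active, half, tiles, tile_half,
                               field_w, field_h):
                insert_object_kernel(pos, angle, vel, angvel, inv_m, inv_I,
                                     kind, active, half, okind,
                                     ox, oy, rot, hx, hy, density)

        # scripted predator
        dx = pos[0, 0] - pos[1, 0]
        dy = pos[0, 1] - pos[1, 1]
        dist2 = dx * dx + dy * dy
        if dist2 <= f_pred * f_pred:
            pspeed = np.sqrt(vel[1, 0] ** 2 + vel[1, 1] ** 2)
            pmag = pred_coeff / (pspeed + 1.0) * torque_factor
            if dx > 0.0:
                torque_acc[1] -= pmag  # prey to the right: clockwise
            else:
                torque_acc[1] += pmag
            # jump only when stuck in placed objects: bottom supported AND
            # touching a box/board, at most once per simulated second
            if (flags[2] == 1 and flags[4] == 1
                    and t - last_jump >= steps_per_second):
                sign = 1.0 if dx > 0.0 else -1.0
                vel[1, 0] += sign * jump_mag * jump_cos * inv_m[1]
                vel[1, 1] += jump_mag * jump_sin * inv_m[1]
                last_jump = t

        step_world(pos, angle, vel, angvel, inv_m, inv_I, kind, active,
                   half, tiles, tile_half, walls, dt, gravity_y, mu,
                   restitution, torque_acc, flags)

        if flags[0] == 1:
            captures += 1
            pos[0, 0] = prey_start_x
            pos[0, 1] = prey_start_y
            pos[1, 0] = pred_start_x
            pos[1, 1] = pred_start_y
            for i in range(2):
                angle[i] = 0.0
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                angvel[i] = 0.0
    return captures
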