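"""Numba kernels: the per-step numerics of the spindle model.

Every physical formula lives here exactly once, as an ``@njit`` function
that is called both by the engine loop and directly by unit tests.  All
kernels operate on plain NumPy arrays; the state layout is

* ``ctr (n_ch, 3)``   chromosome-pair centres (um),
* ``axis (n_ch, 3)``  unit sister-axis vectors (KT1 = ctr + sep/2 * axis),
* ``sep (n_ch,)``     sister separations (um),
* ``mt_pole (n_mt,)`` nucleating pole of each MT (0 -> -x, 1 -> +x),
* ``mt_dir (n_mt, 3)`` unit direction, ``mt_len (n_mt,)`` length,
* ``mt_grow (n_mt,)`` growth state, ``mt_att (n_mt,)`` attached flat-KT
  index (``2*pair + slot``) or -1.

Randomness uses numba's global ``np.random`` stream; call :func:`seed_rng`
once per replicate before any stochastic kernel.

Attachment classes are encoded as integers:
0 unattached, 1 monotelic, 2 syntelic, 3 amphitelic, 4 merotelic.
"""

import numpy as np
from numba import njit

UNATTACHED, MONOTELIC, SYNTELIC, AMPHITELIC, MEROTELIC = 0, 1, 2, 3, 4

#: margin (um) kept between a pair centre (plus half separation) and the wall
WALL_MARGIN = 0.3
#: regularisation floor (um) for the inter-chromosome distance
STERIC_FLOOR = 0.1
#: hard bounds on sister separation (um)
SEP_MIN, SEP_MAX = 0.2, 2.5


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------

@njit(cache=True)
def polar_ejection_force(x, A_pe, L):
    """Ejection-force magnitude A_pe * exp(-x/L) at distance x from a pole."""
    return A_pe * np.exp(-x / L)


@njit(cache=True)
def spring_force(x, K, l0):
    """Signed Hookean spring force K*(x - l0) at extension x."""
    return K * (x - l0)


@njit(cache=True)
def boundary_force(x, A_boundary, L):
    """Inward boundary-repulsion magnitude at distance x from the wall."""
    return A_boundary * np.exp(-x / L)


@njit(cache=True)
def syntelic_detach_rate(F, R_detach, F0):
    """Force-dependent detachment rate R_detach * exp(F/F0) (1/s)."""
    return R_detach * np.exp(F / F0)


@njit(cache=True)
def merotelic_detach_rate(F, n_i, n_j, beta, R_detach, F0, beta_sign):
    """Merotelic detachment rate R_detach*(n_i/n_j)*exp(F/F0)*exp(s*beta).

    ``n_i`` counts MTs on this KT from the considered MT's own pole, ``n_j``
    from the opposite pole; ``beta`` is the angle between the KT->tip vector
    and the KT->sister axis; ``s = beta_sign`` is -1 for the exp(-beta) form.
    """
    return R_detach * (n_i / n_j) * np.exp(F / F0) * np.exp(beta_sign * beta)


@njit(cache=True)
def loaded_rescue_probability(F_depol, f_s):
    """Per-step rescue probability 1 - exp(-F/f_s) of a loaded shrinking MT."""
    return 1.0 - np.exp(-F_depol / f_s)


@njit(cache=True)
def loaded_catastrophe_rate(l_mt, R_cat):
    """Length-dependent catastrophe rate R_cat * l_mt (1/s) of a loaded MT."""
    return R_cat * l_mt


@njit(cache=True)
def event_probability(rate, dt):
    """Per-step probability 1 - exp(-rate*dt) from an exponential waiting time."""
    return 1.0 - np.exp(-rate * dt)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rand_unit_vector():
    while True:
        x = np.random.normal(0.0, 1.0)
        y = np.random.normal(0.0, 1.0)
        z = np.random.normal(0.0, 1.0)
        n = np.sqrt(x * x + y * y + z * z)
        if n > 1e-12:
            return x / n, y / n, z / n


@njit(cache=True)
def kt_positions(ctr, axis, sep, out):
    """Fill ``out (2*n_ch, 3)`` with KT positions; slot 0 at +axis side."""
    n_ch = ctr.shape[0]
    for i in range(n_ch):
        h = 0.5 * sep[i]
        for d in range(3):
            out[2 * i, d] = ctr[i, d] + h * axis[i, d]
            out[2 * i + 1, d] = ctr[i, d] - h * axis[i, d]


@njit(cache=True)
def max_len_inside(ax, ay, az, ux, uy, uz, r_cell):
    """Largest length l with |a + l*u| <= r_cell (anchor a inside the cell)."""
    au = ax * ux + ay * uy + az * uz
    aa = ax * ax + ay * ay + az * az
    disc = au * au + r_cell * r_cell - aa
    if disc < 0.0:
        return 0.0
    return -au + np.sqrt(disc)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

@njit(cache=True)
def init_pairs(n_ch, r_cell, d_cent, r_kt, l_cohesion, ctr, axis, sep):
    """Place pair centres uniformly in the cell sphere, rejecting positions
    within ``r_kt`` of either centrosome; random sister-axis orientations.

    Returns 0 on success, -1 if the rejection-sampling retry cap is hit.
    """
    n_ch = ctr.shape[0]
    rmax = r_cell - WALL_MARGIN - 0.5 * l_cohesion
    for i in range(n_ch):
        placed = False
        for _ in range(10000):
            x = (2.0 * np.random.random() - 1.0) * rmax
            y = (2.0 * np.random.random() - 1.0) * rmax
            z = (2.0 * np.random.random() - 1.0) * rmax
            if x * x + y * y + z * z > rmax * rmax:
                continue
            da = (x + d_cent) ** 2 + y * y + z * z
            db = (x - d_cent) ** 2 + y * y + z * z
            if da < r_kt * r_kt or db < r_kt * r_kt:
                continue
            ctr[i, 0], ctr[i, 1], ctr[i, 2] = x, y, z
            placed = True
            break
        if not placed:
            return -1
        ux, uy, uz = _rand_unit_vector()
        axis[i, 0], axis[i, 1], axis[i, 2] = ux, uy, uz
        sep[i] = l_cohesion
    return 0


@njit(cache=True)
def init_mts(n_mt_per_pole, mt_pole, mt_dir, mt_len, mt_grow, mt_att):
    n_mt = mt_pole.shape[0]
    for m in range(n_mt):
        mt_pole[m] = 0 if m < n_mt_per_pole else 1
        ux, uy, uz = _rand_unit_vector()
        mt_dir[m, 0], mt_dir[m, 1], mt_dir[m, 2] = ux, uy, uz
        mt_len[m] = 0.0
        mt_grow[m] = True
        mt_att[m] = -1


# ---------------------------------------------------------------------------
# bookkeeping: occupancy counts and classification
# ---------------------------------------------------------------------------

@njit(cache=True)
def kt_pole_counts(mt_att, mt_pole, n_ch, counts):
    """Fill ``counts (2*n_ch, 2)`` with per-KT attached-MT counts per pole."""
    counts[:, :] = 0
    for m in range(mt_att.shape[0]):
        k = mt_att[m]
        if k >= 0:
            counts[k, mt_pole[m]] += 1


@njit(cache=True)
def classify_all(counts, classes):
    """Five-way classification of every pair from the occupancy table.

    Merotely (either sister attached to both poles) takes precedence; then
    syntelic (both sisters, one pole), amphitelic (both sisters, opposite
    poles exclusively), monotelic, unattached.
    """
    n_ch = classes.shape[0]
    for i in range(n_ch):
        a0 = counts[2 * i, 0]
        b0 = counts[2 * i, 1]
        a1 = counts[2 * i + 1, 0]
        b1 = counts[2 * i + 1, 1]
        s0 = a0 + b0
        s1 = a1 + b1
        if (a0 > 0 and b0 > 0) or (a1 > 0 and b1 > 0):
            classes[i] = MEROTELIC
        elif s0 > 0 and s1 > 0:
            if (a0 > 0 and a1 > 0) or (b0 > 0 and b1 > 0):
                classes[i] = SYNTELIC
            else:
                classes[i] = AMPHITELIC
        elif s0 > 0 or s1 > 0:
            classes[i] = MONOTELIC
        else:
            classes[i] = UNATTACHED


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def assemble_forces(ctr, axis, sep, mt_pole, mt_len, mt_att,
                    r_cell, d_cent, A_pe, L, K_kmt_kt, l_kmt_kt, f_push,
                    K_cohesion, l_cohesion, A_ch_ch, A_boundary,
                    body_force, kt_force, kmt_force, mt_load):
    """Evaluate all force terms for the current configuration.

    Outputs (overwritten in place):
    ``body_force (n_ch, 3)`` net force on each chromosome body, including
    its two KTs' spring forces; ``kt_force (2*n_ch, 3)`` per-KT force (kMT
    springs + cohesion share); ``kmt_force (2*n_ch, 3)`` the kMT-spring part
    alone (used for torque-free axis alignment); ``mt_load (n_mt,)`` signed
    kMT spring force K*(x - l0) for attached MTs (0 for free MTs), whose
    magnitude feeds the detachment rates and whose tensile part feeds the
    rescue correction.
    """
    n_ch = ctr.shape[0]
    n_mt = mt_pole.shape[0]
    body_force[:, :] = 0.0
    kt_force[:, :] = 0.0
    kmt_force[:, :] = 0.0
    mt_load[:] = 0.0

    kt = np.empty((2 * n_ch, 3))
    kt_positions(ctr, axis, sep, kt)

    # kMT-KT attachment springs (tip re-aimed at the KT: tip distance from
    # the KT along the pole->KT line is |d - l|)
    for m in range(n_mt):
        k = mt_att[m]
        if k < 0:
            continue
        px = -d_cent if mt_pole[m] == 0 else d_cent
        dx = kt[k, 0] - px
        dy = kt[k, 1]
        dz = kt[k, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            continue
        # signed extension: positive = tip short of the KT (tension, pulls
        # the KT poleward); negative = tip at/past the plate (push, bounded
        # by the plate push cap f_push)
        f = spring_force(d - mt_len[m], K_kmt_kt, l_kmt_kt)
        if f < -f_push:
            f = -f_push
        mt_load[m] = f
        kmt_force[k, 0] += -f * dx / d
        kmt_force[k, 1] += -f * dy / d
        kmt_force[k, 2] += -f * dz / d

    for k in range(2 * n_ch):
        for c in range(3):
            kt_force[k, c] = kmt_force[k, c]

    # sister cohesion spring
    for i in range(n_ch):
        f = spring_force(sep[i], K_cohesion, l_cohesion)
        for c in range(3):
            kt_force[2 * i, c] += -f * axis[i, c]
            kt_force[2 * i + 1, c] += f * axis[i, c]

    # body terms: polar ejection (both poles), boundary, steric, KT sum
    for i in range(n_ch):
        for pole in range(2):
            px = -d_cent if pole == 0 else d_cent
            rx = ctr[i, 0] - px
            ry = ctr[i, 1]
            rz = ctr[i, 2]
            r = np.sqrt(rx * rx + ry * ry + rz * rz)
            if r < 1e-9:
                continue
            f = polar_ejection_force(r, A_pe, L)
            body_force[i, 0] += f * rx / r
            body_force[i, 1] += f * ry / r
            body_force[i, 2] += f * rz / r
        rn = np.sqrt(ctr[i, 0] ** 2 + ctr[i, 1] ** 2 + ctr[i, 2] ** 2)
        if rn > 1e-9:
            xw = r_cell - rn
            if xw < 0.0:
                xw = 0.0
            f = boundary_force(xw, A_boundary, L)
            body_force[i, 0] -= f * ctr[i, 0] / rn
            body_force[i, 1] -= f * ctr[i, 1] / rn
            body_force[i, 2] -= f * ctr[i, 2] / rn
        for c in range(3):
            body_force[i, c] += kt_force[2 * i, c] + kt_force[2 * i + 1, c]

    # O(n^2) inter-chromosome inverse-square repulsion
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            rx = ctr[i, 0] - ctr[j, 0]
            ry = ctr[i, 1] - ctr[j, 1]
            rz = ctr[i, 2] - ctr[j, 2]
            r = np.sqrt(rx * rx + ry * ry + rz * rz)
            if r < STERIC_FLOOR:
                r = STERIC_FLOOR
            f = A_ch_ch / (r * r)
            fx, fy, fz = f * rx / r, f * ry / r, f * rz / r
            body_force[i, 0] += fx
            body_force[i, 1] += fy
            body_force[i, 2] += fz
            body_force[j, 0] -= fx
            body_force[j, 1] -= fy
            body_force[j, 2] -= fz


# ---------------------------------------------------------------------------
# motion (overdamped)
# ---------------------------------------------------------------------------

@njit(cache=True)
def move_chromosomes(ctr, axis, sep, mt_pole, mt_att, body_force, kt_force,
                     kmt_force, r_cell, gamma_ch, dt):
    """First-order overdamped update of pair centres, separations and axes.

    ``kmt_force (2*n_ch, 3)`` holds the kMT-spring part of each KT's force
    (no cohesion); when both sisters carry attachments the sister axis is
    re-aligned with the resultant of the opposing pulls.  Positions are
    clipped so every KT stays inside the cell.
    """
    n_ch = ctr.shape[0]
    inv = dt / gamma_ch
    for i in range(n_ch):
        for d in range(3):
            ctr[i, d] += body_force[i, d] * inv
        # sister separation driven by the axial component of the KT forces
        frel = 0.0
        for d in range(3):
            frel += (kt_force[2 * i, d] - kt_force[2 * i + 1, d]) * axis[i, d]
        sep[i] += frel * inv
        if sep[i] < SEP_MIN:
            sep[i] = SEP_MIN
        elif sep[i] > SEP_MAX:
            sep[i] = SEP_MAX
        # torque-free axis: align with the resultant of opposing kMT pulls
        tx = kmt_force[2 * i, 0] - kmt_force[2 * i + 1, 0]
        ty = kmt_force[2 * i, 1] - kmt_force[2 * i + 1, 1]
        tz = kmt_force[2 * i, 2] - kmt_force[2 * i + 1, 2]
        tn = np.sqrt(tx * tx + ty * ty + tz * tz)
        if tn > 1e-9:
            n0 = 0
            n1 = 0
            for m in range(mt_att.shape[0]):
                if mt_att[m] == 2 * i:
                    n0 += 1
                elif mt_att[m] == 2 * i + 1:
                    n1 += 1
            if n0 > 0 and n1 > 0:
                axis[i, 0] = tx / tn
                axis[i, 1] = ty / tn
                axis[i, 2] = tz / tn
        # keep both KTs inside the cell
        rmax = r_cell - WALL_MARGIN - 0.5 * sep[i]
        rn = np.sqrt(ctr[i, 0] ** 2 + ctr[i, 1] ** 2 + ctr[i, 2] ** 2)
        if rn > rmax:
            sc = rmax / rn
            ctr[i, 0] *= sc
            ctr[i, 1] *= sc
            ctr[i, 2] *= sc


# ---------------------------------------------------------------------------
# microtubule dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def step_mts(ctr, axis, sep, mt_pole, mt_dir, mt_len, mt_grow, mt_att,
             r_cell, d_cent, v_g, v_s, f_r, f_c, f_s, R_cat, R_cat_free,
             K_kmt_kt, l_kmt_kt, dt):
    """Advance MT lengths and growth states by one step.

    Free MTs grow/shrink, switch with the constant rates ``f_r``/``f_c``
    (exponential waiting times) and are re-nucleated in a fresh random
    direction when fully shrunk.  Attached MTs are re-aimed at their KT and
    use the load-corrected switching: rescue with per-step probability
    1 - exp(-F/f_s) and catastrophe at the length-dependent rate
    ``R_cat * l``.  Tips never leave the cell.
    """
    n_ch = ctr.shape[0]
    kt = np.empty((2 * n_ch, 3))
    kt_positions(ctr, axis, sep, kt)
    for m in range(mt_pole.shape[0]):
        px = -d_cent if mt_pole[m] == 0 else d_cent
        k = mt_att[m]
        if k < 0:
            if mt_grow[m]:
                mt_len[m] += v_g * dt
                cat = f_c + loaded_catastrophe_rate(mt_len[m], R_cat_free)
                if np.random.random() < event_probability(cat, dt):
                    mt_grow[m] = False
            else:
                mt_len[m] -= v_s * dt
                if mt_len[m] <= 0.0:
                    mt_len[m] = 0.0
                    ux, uy, uz = _rand_unit_vector()
                    mt_dir[m, 0], mt_dir[m, 1], mt_dir[m, 2] = ux, uy, uz
                    mt_grow[m] = True
                elif np.random.random() < event_probability(f_r, dt):
                    mt_grow[m] = True
        else:
            dx = kt[k, 0] - px
            dy = kt[k, 1]
            dz = kt[k, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > 1e-9:
                mt_dir[m, 0] = dx / d
                mt_dir[m, 1] = dy / d
                mt_dir[m, 2] = dz / d
            if mt_grow[m]:
                mt_len[m] += v_g * dt
                rate = loaded_catastrophe_rate(mt_len[m], R_cat)
                if np.random.random() < event_probability(rate, dt):
                    mt_grow[m] = False
            else:
                mt_len[m] -= v_s * dt
                if mt_len[m] < 0.0:
                    mt_len[m] = 0.0
            if not mt_grow[m]:
                tension = spring_force(d - mt_len[m], K_kmt_kt, l_kmt_kt)
                if tension < 0.0:
                    tension = 0.0
                if np.random.random() < loaded_rescue_probability(tension, f_s):
                    mt_grow[m] = True
        # clip the tip at the cell boundary along the MT ray
        lmax = max_len_inside(px, 0.0, 0.0, mt_dir[m, 0], mt_dir[m, 1],
                              mt_dir[m, 2], r_cell)
        if mt_len[m] > lmax:
            mt_len[m] = lmax


# ---------------------------------------------------------------------------
# search and capture
# ---------------------------------------------------------------------------

@njit(cache=True)
def search_and_capture(ctr, axis, sep, mt_pole, mt_dir, mt_len, mt_grow,
                       mt_att, counts, classes, d_cent, r_kt, p_capture,
                       n_max, l_kmt_kt):
    """Attach free MTs passing within ``r_kt`` of an eligible kinetochore.

    Eligibility: the pair is not amphitelic (bi-oriented pairs accept no new
    attachments) and the KT is below its occupancy cap.  A capturing MT is
    converted to end-on: re-aimed at the KT with the spring starting at rest.
    At most one attachment per MT per step; the nearest eligible KT wins.
    Returns the number of new attachments.
    """
    n_ch = ctr.shape[0]
    n_kt = 2 * n_ch
    kt = np.empty((n_kt, 3))
    kt_positions(ctr, axis, sep, kt)
    r2 = r_kt * r_kt
    n_new = 0
    for m in range(mt_pole.shape[0]):
        if mt_att[m] >= 0 or mt_len[m] <= 0.0:
            continue
        px = -d_cent if mt_pole[m] == 0 else d_cent
        ux, uy, uz = mt_dir[m, 0], mt_dir[m, 1], mt_dir[m, 2]
        l = mt_len[m]
        best_k = -1
        best_d2 = r2
        for k in range(n_kt):
            if classes[k >> 1] == AMPHITELIC:
                continue
            if counts[k, 0] + counts[k, 1] >= n_max:
                continue
            wx = kt[k, 0] - px
            wy = kt[k, 1]
            wz = kt[k, 2]
            t = wx * ux + wy * uy + wz * uz
            if t < 0.0:
                t = 0.0
            elif t > l:
                t = l
            ex = wx - t * ux
            ey = wy - t * uy
            ez = wz - t * uz
            d2 = ex * ex + ey * ey + ez * ez
            if d2 <= best_d2:
                best_d2 = d2
                best_k = k
        if best_k >= 0 and np.random.random() < p_capture:
            k = best_k
            dx = kt[k, 0] - px
            dy = kt[k, 1]
            dz = kt[k, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-9:
                continue
            mt_att[m] = k
            mt_dir[m, 0] = dx / d
            mt_dir[m, 1] = dy / d
            mt_dir[m, 2] = dz / d
            mt_len[m] = d - l_kmt_kt if d > l_kmt_kt else 0.0
            counts[k, mt_pole[m]] += 1
            # an attachment may change the pair's class mid-step; refresh it
            i = k >> 1
            a0 = counts[2 * i, 0]
            b0 = counts[2 * i, 1]
            a1 = counts[2 * i + 1, 0]
            b1 = counts[2 * i + 1, 1]
            if (a0 > 0 and b0 > 0) or (a1 > 0 and b1 > 0):
                classes[i] = MEROTELIC
            elif (a0 + b0) > 0 and (a1 + b1) > 0:
                if (a0 > 0 and a1 > 0) or (b0 > 0 and b1 > 0):
                    classes[i] = SYNTELIC
                else:
                    classes[i] = AMPHITELIC
            else:
                classes[i] = MONOTELIC
            n_new += 1
    return n_new


# ---------------------------------------------------------------------------
# error correction
# ---------------------------------------------------------------------------

@njit(cache=True)
def apply_error_correction(ctr, axis, sep, mt_pole, mt_len, mt_att,
                           counts, classes, d_cent, K_kmt_kt, l_kmt_kt, f_push,
                           R_detach, F0, beta_sign, dt):
    """Sample force-dependent detachments for one step.

    Amphitelic pairs are exempt (inter-KT tension stabilises them).  An MT
    on a dual-pole (merotelic) KT detaches at the occupancy- and angle-
    weighted rate; every other attached MT (syntelic, monotelic, and the
    singly-attached sister of a merotelic pair) uses the plain force-
    dependent rate.  Rates are evaluated on a frozen snapshot of the
    occupancy table, then detachments applied.  Returns the number detached.
    """
    n_ch = ctr.shape[0]
    n_mt = mt_pole.shape[0]
    kt = np.empty((2 * n_ch, 3))
    kt_positions(ctr, axis, sep, kt)
    detach = np.zeros(n_mt, dtype=np.bool_)
    for m in range(n_mt):
        k = mt_att[m]
        if k < 0:
            continue
        i = k >> 1
        if classes[i] == AMPHITELIC:
            continue
        pole = mt_pole[m]
        px = -d_cent if pole == 0 else d_cent
        dx = kt[k, 0] - px
        dy = kt[k, 1]
        dz = kt[k, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        F = spring_force(d - mt_len[m], K_kmt_kt, l_kmt_kt)
        if F < -f_push:
            F = -f_push
        F = np.abs(F)
        n_i = counts[k, pole]
        n_j = counts[k, 1 - pole]
        if n_i > 0 and n_j > 0:
            # dual-pole KT: angle between KT->tip and the KT->sister axis
            s = 2 * i + 1 if k == 2 * i else 2 * i
            tipx = px + mt_len[m] * dx / d if d > 1e-9 else px
            tipy = mt_len[m] * dy / d if d > 1e-9 else 0.0
            tipz = mt_len[m] * dz / d if d > 1e-9 else 0.0
            vx = tipx - kt[k, 0]
            vy = tipy - kt[k, 1]
            vz = tipz - kt[k, 2]
            vn = np.sqrt(vx * vx + vy * vy + vz * vz)
            wx = kt[s, 0] - kt[k, 0]
            wy = kt[s, 1] - kt[k, 1]
            wz = kt[s, 2] - kt[k, 2]
            wn = np.sqrt(wx * wx + wy * wy + wz * wz)
            if vn > 1e-9 and wn > 1e-9:
                c = (vx * wx + vy * wy + vz * wz) / (vn * wn)
                if c > 1.0:
                    c = 1.0
                elif c < -1.0:
                    c = -1.0
                beta = np.arccos(c)
            else:
                beta = 0.5 * np.pi
            rate = merotelic_detach_rate(F, n_i, n_j, beta, R_detach, F0,
                                         beta_sign)
        else:
            rate = syntelic_detach_rate(F, R_detach, F0)
        if np.random.random() < event_probability(rate, dt):
            detach[m] = True
    n_det = 0
    for m in range(n_mt):
        if detach[m]:
            counts[mt_att[m], mt_pole[m]] -= 1
            mt_att[m] = -1
            n_det += 1
    return n_det
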