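"""Compiled inner loops: the Metropolis sampler and distance-map accumulation.

The sampler advances a single chain in place.  Moves (all with symmetric
proposal densities, angles uniform in (-amp, +amp]):

* crankshaft -- rotate the loci strictly between two chain points about the
  axis through those points.  All rods in the segment rotate rigidly, so
  only the two boundary joints change bending energy.
* pivot / arm rotation -- rotate one terminal segment.  Untethered (or
  centromere-free) sides pivot about a random axis through the boundary
  locus; in telomere mode the segment instead rotates about the axis through
  the origin and the boundary locus, which preserves every norm (so the
  moved telomere stays exactly on the sphere) and every rod length.
* rigid rotation -- rotate the whole chain about a random axis through the
  nucleus centre; only the clustering energy can change.

Hard constraints (confinement, excluded volume) reject the proposal
outright; finite energy differences go through the Metropolis ratio
min(1, exp(-beta dE)).  Tether modes: 0 = none, 1 = centromere,
2 = telomeres.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_mcmc", "pair_stats_intra", "pair_stats_inter"]


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, c, s, px, py, pz):
    """Rodrigues rotation of p about unit axis u."""
    dot = ux * px + uy * py + uz * pz
    cx = uy * pz - uz * py
    cy = uz * px - ux * pz
    cz = ux * py - uy * px
    k = (1.0 - c) * dot
    return (
        px * c + cx * s + ux * k,
        py * c + cy * s + uy * k,
        pz * c + cz * s + uz * k,
    )


@njit(cache=True, inline="always")
def _joint_pts(ax, ay, az, bx, by, bz, cx, cy, cz, g):
    """g * (1 - cos) for the joint at b formed by rods a->b and b->c."""
    t1x = bx - ax
    t1y = by - ay
    t1z = bz - az
    t2x = cx - bx
    t2y = cy - by
    t2z = cz - bz
    n1 = np.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
    n2 = np.sqrt(t2x * t2x + t2y * t2y + t2z * t2z)
    d = (t1x * t2x + t1y * t2y + t1z * t2z) / (n1 * n2)
    return g * (1.0 - d)


@njit(cache=True, inline="always")
def _clust_term(nu, mux, muy, muz, px, py, pz):
    n = np.sqrt(px * px + py * py + pz * pz)
    return -nu * (mux * px + muy * py + muz * pz) / n


@njit(cache=True)
def _random_unit():
    while True:
        vx = np.random.normal(0.0, 1.0)
        vy = np.random.normal(0.0, 1.0)
        vz = np.random.normal(0.0, 1.0)
        n = np.sqrt(vx * vx + vy * vy + vz * vz)
        if n > 1e-12:
            return vx / n, vy / n, vz / n


@njit(cache=True)
def _ev_cross_ok(x, scratch, lo, hi, ev_min2, window):
    """Hard-sphere check between moved loci [lo, hi) (in scratch) and the rest."""
    n = x.shape[0]
    for m in range(lo, hi):
        for q in range(n):
            if lo <= q < hi:
                continue
            dq = m - q
            if dq < 0:
                dq = -dq
            if dq <= window:
                continue
            dx = scratch[m, 0] - x[q, 0]
            dy = scratch[m, 1] - x[q, 1]
            dz = scratch[m, 2] - x[q, 2]
            if dx * dx + dy * dy + dz * dz < ev_min2:
                return False
    return True


@njit(cache=True)
def _renormalize(x, b, mode, cen, radius):
    """Rebuild the chain from its anchor with exact rod lengths.

    Caps floating-point drift from composed rotations; tethered loci are
    re-projected onto the sphere (residual perturbations ~1e-12 relative).
    """
    n = x.shape[0]
    anchor = cen if mode == 1 else 0
    if mode >= 1:
        r = np.sqrt(x[anchor, 0] ** 2 + x[anchor, 1] ** 2 + x[anchor, 2] ** 2)
        f = radius / r
        x[anchor, 0] *= f
        x[anchor, 1] *= f
        x[anchor, 2] *= f
    for m in range(anchor, n - 1):
        tx = x[m + 1, 0] - x[m, 0]
        ty = x[m + 1, 1] - x[m, 1]
        tz = x[m + 1, 2] - x[m, 2]
        f = b / np.sqrt(tx * tx + ty * ty + tz * tz)
        x[m + 1, 0] = x[m, 0] + tx * f
        x[m + 1, 1] = x[m, 1] + ty * f
        x[m + 1, 2] = x[m, 2] + tz * f
    for m in range(anchor, 0, -1):
        tx = x[m - 1, 0] - x[m, 0]
        ty = x[m - 1, 1] - x[m, 1]
        tz = x[m - 1, 2] - x[m, 2]
        f = b / np.sqrt(tx * tx + ty * ty + tz * tz)
        x[m - 1, 0] = x[m, 0] + tx * f
        x[m - 1, 1] = x[m, 1] + ty * f
        x[m - 1, 2] = x[m, 2] + tz * f
    if mode == 2:
        for m in (0, n - 1):
            r = np.sqrt(x[m, 0] ** 2 + x[m, 1] ** 2 + x[m, 2] ** 2)
            f = radius / r
            x[m, 0] *= f
            x[m, 1] *= f
            x[m, 2] *= f


@njit(cache=True)
def run_mcmc(
    x,
    g_beta,
    radius,
    mode,
    cen,
    nu,
    mux,
    muy,
    muz,
    n_total,
    n_burn,
    thin,
    seed,
    p_crank,
    p_pivot,
    amp_init,
    tune,
    tune_interval,
    acc_lo,
    acc_hi,
    ev_enabled,
    ev_min,
    ev_window,
    renorm_interval,
    bond,
):
    """Run the Metropolis chain in place; return the thinned ensemble.

    Returns ``(out, acc_by_move, att_by_move, amps, acc_post, att_post)``.
    One "sample" is one attempted Metropolis step; the first ``n_burn``
    steps are discarded and the remainder thinned by ``thin``.
    """
    np.random.seed(seed)
    n = x.shape[0]
    n_ret = (n_total - n_burn) // thin
    out = np.empty((n_ret, n, 3))
    scratch = np.empty((n, 3))
    amps = np.empty(3)
    for m in range(3):
        amps[m] = amp_init
    att = np.zeros(3, dtype=np.int64)
    acc = np.zeros(3, dtype=np.int64)
    att_w = np.zeros(3, dtype=np.int64)
    acc_w = np.zeros(3, dtype=np.int64)
    att_post = 0
    acc_post = 0
    ret_i = 0
    r2max = (radius * (1.0 + 1e-9)) ** 2
    ev_min2 = ev_min * ev_min

    for step in range(n_total):
        u = np.random.random()
        if u < p_crank:
            mt = 0
        elif u < p_crank + p_pivot:
            mt = 1
        else:
            mt = 2
        accepted = False

        if mt == 0:
            # ---- crankshaft -------------------------------------------------
            i = np.random.randint(0, n - 2)
            j = np.random.randint(i + 2, n)
            ok = not (mode == 1 and (i < cen) and (cen < j))
            if ok:
                ax = x[j, 0] - x[i, 0]
                ay = x[j, 1] - x[i, 1]
                az = x[j, 2] - x[i, 2]
                axl = np.sqrt(ax * ax + ay * ay + az * az)
                ok = axl > 1e-9
            if ok:
                ux = ax / axl
                uy = ay / axl
                uz = az / axl
                ang = (2.0 * np.random.random() - 1.0) * amps[0]
                c = np.cos(ang)
                s = np.sin(ang)
                feasible = True
                for m in range(i + 1, j):
                    px = x[m, 0] - x[i, 0]
                    py = x[m, 1] - x[i, 1]
                    pz = x[m, 2] - x[i, 2]
                    rx, ry, rz = _rotate(ux, uy, uz, c, s, px, py, pz)
                    nx = x[i, 0] + rx
                    ny = x[i, 1] + ry
                    nz = x[i, 2] + rz
                    if nx * nx + ny * ny + nz * nz > r2max:
                        feasible = False
                        break
                    scratch[m, 0] = nx
                    scratch[m, 1] = ny
                    scratch[m, 2] = nz
                if feasible and ev_enabled:
                    feasible = _ev_cross_ok(x, scratch, i + 1, j, ev_min2, ev_window)
                if feasible:
                    e_old = 0.0
                    e_new = 0.0
                    if i >= 1:
                        e_old += _joint_pts(
                            x[i - 1, 0], x[i - 1, 1], x[i - 1, 2],
                            x[i, 0], x[i, 1], x[i, 2],
                            x[i + 1, 0], x[i + 1, 1], x[i + 1, 2], g_beta)
                        e_new += _joint_pts(
                            x[i - 1, 0], x[i - 1, 1], x[i - 1, 2],
                            x[i, 0], x[i, 1], x[i, 2],
                            scratch[i + 1, 0], scratch[i + 1, 1], scratch[i + 1, 2],
                            g_beta)
                    if j <= n - 2:
                        e_old += _joint_pts(
                            x[j - 1, 0], x[j - 1, 1], x[j - 1, 2],
                            x[j, 0], x[j, 1], x[j, 2],
                            x[j + 1, 0], x[j + 1, 1], x[j + 1, 2], g_beta)
                        e_new += _joint_pts(
                            scratch[j - 1, 0], scratch[j - 1, 1], scratch[j - 1, 2],
                            x[j, 0], x[j, 1], x[j, 2],
                            x[j + 1, 0], x[j + 1, 1], x[j + 1, 2], g_beta)
                    de = e_new - e_old
                    if de <= 0.0 or np.random.random() < np.exp(-de):
                        for m in range(i + 1, j):
                            x[m, 0] = scratch[m, 0]
                            x[m, 1] = scratch[m, 1]
                            x[m, 2] = scratch[m, 2]
                        accepted = True

        elif mt == 1:
            # ---- pivot (modes 0/1) or arm rotation (mode 2) -----------------
            side = np.random.randint(0, 2)
            if mode == 0:
                k = np.random.randint(1, n) if side == 0 else np.random.randint(0, n - 1)
                valid = True
            elif mode == 1:
                if side == 0:
                    valid = cen >= 1
                    k = np.random.randint(1, cen + 1) if valid else 0
                else:
                    valid = cen <= n - 2
                    k = np.random.randint(cen, n - 1) if valid else 0
            else:
                k = np.random.randint(1, n) if side == 0 else np.random.randint(0, n - 1)
                valid = True
            if valid:
                lo = 0 if side == 0 else k + 1
                hi = k if side == 0 else n
                ang = (2.0 * np.random.random() - 1.0) * amps[1]
                c = np.cos(ang)
                s = np.sin(ang)
                feasible = True
                if mode == 2:
                    # axis through origin along x[k]: norms preserved
                    axl = np.sqrt(x[k, 0] ** 2 + x[k, 1] ** 2 + x[k, 2] ** 2)
                    if axl < 1e-9:
                        feasible = False
                    else:
                        ux = x[k, 0] / axl
                        uy = x[k, 1] / axl
                        uz = x[k, 2] / axl
                        for m in range(lo, hi):
                            rx, ry, rz = _rotate(
                                ux, uy, uz, c, s, x[m, 0], x[m, 1], x[m, 2])
                            scratch[m, 0] = rx
                            scratch[m, 1] = ry
                            scratch[m, 2] = rz
                else:
                    ux, uy, uz = _random_unit()
                    for m in range(lo, hi):
                        px = x[m, 0] - x[k, 0]
                        py = x[m, 1] - x[k, 1]
                        pz = x[m, 2] - x[k, 2]
                        rx, ry, rz = _rotate(ux, uy, uz, c, s, px, py, pz)
                        nx = x[k, 0] + rx
                        ny = x[k, 1] + ry
                        nz = x[k, 2] + rz
                        if nx * nx + ny * ny + nz * nz > r2max:
                            feasible = False
                            break
                        scratch[m, 0] = nx
                        scratch[m, 1] = ny
                        scratch[m, 2] = nz
                if feasible and ev_enabled:
                    feasible = _ev_cross_ok(x, scratch, lo, hi, ev_min2, ev_window)
                if feasible:
                    de = 0.0
                    if 1 <= k <= n - 2:
                        if side == 0:
                            de += _joint_pts(
                                scratch[k - 1, 0], scratch[k - 1, 1], scratch[k - 1, 2],
                                x[k, 0], x[k, 1], x[k, 2],
                                x[k + 1, 0], x[k + 1, 1], x[k + 1, 2], g_beta)
                            de -= _joint_pts(
                                x[k - 1, 0], x[k - 1, 1], x[k - 1, 2],
                                x[k, 0], x[k, 1], x[k, 2],
                                x[k + 1, 0], x[k + 1, 1], x[k + 1, 2], g_beta)
                        else:
                            de += _joint_pts(
                                x[k - 1, 0], x[k - 1, 1], x[k - 1, 2],
                                x[k, 0], x[k, 1], x[k, 2],
                                scratch[k + 1, 0], scratch[k + 1, 1], scratch[k + 1, 2],
                                g_beta)
                            de -= _joint_pts(
                                x[k - 1, 0], x[k - 1, 1], x[k - 1, 2],
                                x[k, 0], x[k, 1], x[k, 2],
                                x[k + 1, 0], x[k + 1, 1], x[k + 1, 2], g_beta)
                    if mode == 2 and nu > 0.0:
                        tel = 0 if side == 0 else n - 1
                        de += _clust_term(
                            nu, mux, muy, muz,
                            scratch[tel, 0], scratch[tel, 1], scratch[tel, 2])
                        de -= _clust_term(
                            nu, mux, muy, muz, x[tel, 0], x[tel, 1], x[tel, 2])
                    if de <= 0.0 or np.random.random() < np.exp(-de):
                        for m in range(lo, hi):
                            x[m, 0] = scratch[m, 0]
                            x[m, 1] = scratch[m, 1]
                            x[m, 2] = scratch[m, 2]
                        accepted = True

        else:
            # ---- rigid rotation about the nucleus centre --------------------
            ux, uy, uz = _random_unit()
            ang = (2.0 * np.random.random() - 1.0) * amps[2]
            c = np.cos(ang)
            s = np.sin(ang)
            de = 0.0
            if nu > 0.0 and mode >= 1:
                if mode == 1:
                    rx, ry, rz = _rotate(ux, uy, uz, c, s,
                                         x[cen, 0], x[cen, 1], x[cen, 2])
                    de += _clust_term(nu, mux, muy, muz, rx, ry, rz)
                    de -= _clust_term(nu, mux, muy, muz,
                                      x[cen, 0], x[cen, 1], x[cen, 2])
                else:
                    for tel in (0, n - 1):
                        rx, ry, rz = _rotate(ux, uy, uz, c, s,
                                             x[tel, 0], x[tel, 1], x[tel, 2])
                        de += _clust_term(nu, mux, muy, muz, rx, ry, rz)
                        de -= _clust_term(nu, mux, muy, muz,
                                          x[tel, 0], x[tel, 1], x[tel, 2])
            if de <= 0.0 or np.random.random() < np.exp(-de):
                for m in range(n):
                    rx, ry, rz = _rotate(ux, uy, uz, c, s,
                                         x[m, 0], x[m, 1], x[m, 2])
                    x[m, 0] = rx
                    x[m, 1] = ry
                    x[m, 2] = rz
                accepted = True

        att[mt] += 1
        att_w[mt] += 1
        if accepted:
            acc[mt] += 1
            acc_w[mt] += 1
        if step >= n_burn:
            att_post += 1
            if accepted:
                acc_post += 1

        if tune and step < n_burn and (step + 1) % tune_interval == 0:
            for m in range(3):
                if att_w[m] > 0:
                    rate = acc_w[m] / att_w[m]
                    if rate > acc_hi:
                        amps[m] = min(amps[m] * 1.15, np.pi)
                    elif rate < acc_lo:
                        amps[m] = max(amps[m] * 0.85, 1e-3)
                att_w[m] = 0
                acc_w[m] = 0

        if renorm_interval > 0 and (step + 1) % renorm_interval == 0:
            _renormalize(x, bond, mode, cen, radius)

        if step >= n_burn and (step - n_burn + 1) % thin == 0 and ret_i < n_ret:
            for m in range(n):
                out[ret_i, m, 0] = x[m, 0]
                out[ret_i, m, 1] = x[m, 1]
                out[ret_i, m, 2] = x[m, 2]
            ret_i += 1

    return out, acc, att, amps, acc_post, att_post


# ---------------------------------------------------------------------------
# Distance-map accumulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def pair_stats_intra(P):
    """Mean and SD of |x_i - x_j| over samples, same chain. P: (S, N, 3)."""
    S, N, _ = P.shape
    mean = np.zeros((N, N))
    m2 = np.zeros((N, N))
    for s in range(S):
        for i in range(N):
            for j in range(i + 1, N):
                dx = P[s, i, 0] - P[s, j, 0]
                dy = P[s, i, 1] - P[s, j, 1]
                dz = P[s, i, 2] - P[s, j, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                mean[i, j] += d
                m2[i, j] += d * d
    for i in range(N):
        for j in range(i + 1, N):
            mu = mean[i, j] / S
            var = m2[i, j] / S - mu * mu
            if var < 0.0:
                var = 0.0
            mean[i, j] = mu
            mean[j, i] = mu
            m2[i, j] = np.sqrt(var)
            m2[j, i] = m2[i, j]
    return mean, m2


@njit(cache=True)
def pair_stats_inter(PA, PB):
    """Mean and SD of |x_i^A - x_j^B| over index-paired samples."""
    S, NA, _ = PA.shape
    NB = PB.shape[1]
    mean = np.zeros((NA, NB))
    m2 = np.zeros((NA, NB))
    for s in range(S):
        for i in range(NA):
            for j in range(NB):
                dx = PA[s, i, 0] - PB[s, j, 0]
                dy = PA[s, i, 1] - PB[s, j, 1]
                dz = PA[s, i, 2] - PB[s, j, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                mean[i, j] += d
                m2[i, j] += d * d
    for i in range(NA):
        for j in range(NB):
            mu = mean[i, j] / S
            var = m2[i, j] / S - mu * mu
            if var < 0.0:
                var = 0.0
            mean[i, j] = mu
            m2[i, j] = np.sqrt(var)
    return mean, m2
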