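"""Compiled inner loop of the learning simulation.

The multi-million-step runs make a per-step Python implementation
impractical, so the whole step — trajectory, place rates, head-direction
gating, adaptation, gain/threshold iteration, Hebbian learning and rate-map
accumulation — is fused into one numba kernel. Randomness is consumed from
pre-drawn arrays (one heading-turn angle and one rotation-axis angle per
step), which keeps the kernel bit-reproducible and lets the pure-numpy
module functions be tested against it draw for draw.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_core"]


@njit(cache=True)
def _rotate_heading(h, theta, phi):
    """Rotate unit vector h by theta about a perpendicular axis at angle phi.

    Mirrors trajectory.perp_basis: the helper axis is the coordinate axis
    least aligned with h.
    """
    # helper = unit vector along argmin |h|
    a0, a1, a2 = abs(h[0]), abs(h[1]), abs(h[2])
    ax = np.zeros(3)
    if a0 <= a1 and a0 <= a2:
        ax[0] = 1.0
    elif a1 <= a2:
        ax[1] = 1.0
    else:
        ax[2] = 1.0
    e1 = np.empty(3)
    e1[0] = h[1] * ax[2] - h[2] * ax[1]
    e1[1] = h[2] * ax[0] - h[0] * ax[2]
    e1[2] = h[0] * ax[1] - h[1] * ax[0]
    n = np.sqrt(e1[0] ** 2 + e1[1] ** 2 + e1[2] ** 2)
    e1 /= n
    e2 = np.empty(3)
    e2[0] = h[1] * e1[2] - h[2] * e1[1]
    e2[1] = h[2] * e1[0] - h[0] * e1[2]
    e2[2] = h[0] * e1[1] - h[1] * e1[0]
    axis = np.cos(phi) * e1 + np.sin(phi) * e2
    cx = axis[1] * h[2] - axis[2] * h[1]
    cy = axis[2] * h[0] - axis[0] * h[2]
    cz = axis[0] * h[1] - axis[1] * h[0]
    ct, st = np.cos(theta), np.sin(theta)
    out = np.empty(3)
    out[0] = h[0] * ct + cx * st
    out[1] = h[1] * ct + cy * st
    out[2] = h[2] * ct + cz * st
    n = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2)
    return out / n


@njit(cache=True)
def run_core(
    n_steps,
    pos,  # (3,) initial position, modified in place conceptually
    head,  # (3,) initial heading (unit)
    turn_angles,  # (n_steps,) N(0, sigma_h) draws
    axis_phis,  # (n_steps,) U(0, 2pi) draws
    step_len,
    box,  # (3,)
    centers,  # (N_inp, 3)
    sigma_p,
    W,  # (N_mec, N_inp), modified
    W_coll,  # (N_mec, N_mec)
    theta,  # (N_mec, 3)
    c,
    nu,
    rho_coll,
    tau,
    b1,  # (N_mec,) per-unit fast adaptation rates
    b2,  # (N_mec,)
    b3,
    b4,
    eps,
    eta,
    a0,
    s0,
    band_tol,
    max_iter,
    g0,
    mu0,
    checkpoints,  # (n_ck,) strictly increasing step indices (1-based)
    grid_shape,  # (3,) voxel counts
    traj_stride,  # store every k-th position (0 disables)
):
    """Run the full learning loop; returns per-checkpoint interval rate-map
    sums, occupancy, final weights and control-loop statistics."""
    n_mec = W.shape[0]
    n_inp = W.shape[1]
    n_ck = len(checkpoints)
    nx, ny, nz = grid_shape[0], grid_shape[1], grid_shape[2]
    nvox = nx * ny * nz

    maps = np.zeros((n_ck, n_mec, nvox))
    occ = np.zeros((n_ck, nvox))
    g_ck = np.empty(n_ck)
    mu_ck = np.empty(n_ck)
    nonconv = np.zeros(n_ck, dtype=np.int64)
    a_sum = np.zeros(n_ck)
    s_sum = np.zeros(n_ck)

    n_traj = n_steps // traj_stride + 1 if traj_stride > 0 else 0
    traj = np.zeros((n_traj, 3))
    alpha = np.zeros(n_mec)
    beta = np.zeros(n_mec)
    h_in = np.zeros(n_mec)
    psi = np.zeros(n_mec)
    psi_bar = np.zeros(n_mec)
    r_bar = np.zeros(n_inp)
    delay = np.zeros((tau, n_mec))
    r = np.empty(n_inp)
    g = g0
    mu = mu0
    ck = 0
    inv_2sp2 = 1.0 / (2.0 * sigma_p * sigma_p)

    for t in range(n_steps):
        if t > 0:
            head = _rotate_heading(head, turn_angles[t], axis_phis[t])
            for d in range(3):
                pos[d] = pos[d] + step_len * head[d]
                if pos[d] < 0.0:
                    pos[d] = -pos[d]
                    head[d] = -head[d]
                elif pos[d] > box[d]:
                    pos[d] = 2.0 * box[d] - pos[d]
                    head[d] = -head[d]

        if traj_stride > 0 and t % traj_stride == 0:
            traj[t // traj_stride, 0] = pos[0]
            traj[t // traj_stride, 1] = pos[1]
            traj[t // traj_stride, 2] = pos[2]

        # place rates
        for j in range(n_inp):
            dx = pos[0] - centers[j, 0]
            dy = pos[1] - centers[j, 1]
            dz = pos[2] - centers[j, 2]
            r[j] = np.exp(-(dx * dx + dy * dy + dz * dz) * inv_2sp2)

        # adaptation from previous step's input
        for i in range(n_mec):
            na = alpha[i] + b1[i] * (h_in[i] - beta[i] - alpha[i])
            beta[i] = beta[i] + b2[i] * (h_in[i] - beta[i])
            alpha[i] = na

        # gain/threshold iteration on current alpha; on cap-out the rates
        # come from the least-violating iterate, while (g, mu) carry on from
        # the last iterate so warm-started steps keep making progress
        best_viol = 1e300
        best_g = g
        best_mu = mu
        converged = False
        for k in range(max_iter + 1):
            a_cur = 0.0
            ss = 0.0
            for i in range(n_mec):
                x = alpha[i] - mu
                if x > 0.0:
                    p = 0.6366197723675814 * np.arctan(g * x)  # 2/pi
                else:
                    p = 0.0
                psi[i] = p
                a_cur += p
                ss += p * p
            a_cur /= n_mec
            if ss > 0.0:
                s_cur = (a_cur * n_mec) ** 2 / (n_mec * ss)
            else:
                s_cur = s0  # silent: neutral sparsity, move threshold only
            viol_a = abs(a_cur - a0) / a0
            viol_s = abs(s_cur - s0) / s0
            viol = viol_a if viol_a > viol_s else viol_s
            if viol < best_viol:
                best_viol = viol
                best_g = g
                best_mu = mu
            if viol <= band_tol:
                converged = True
                break
            if k == max_iter:
                break
            mu = mu + b3 * (a_cur - a0)
            g = g + b4 * g * (s_cur - s0)
        if not converged:
            for i in range(n_mec):
                x = alpha[i] - best_mu
                psi[i] = 0.6366197723675814 * np.arctan(best_g * x) if x > 0.0 else 0.0
            nonconv[ck] += 1

        # total input for the next adaptation update, from the pre-update
        # weights and the delayed population rates
        slot = t % tau
        psi_del = delay[slot].copy()  # psi from t - tau (zeros early on)
        for i in range(n_mec):
            cosg = theta[i, 0] * head[0] + theta[i, 1] * head[1] + theta[i, 2] * head[2]
            f = c + (1.0 - c) * np.exp(nu * (cosg - 1.0))
            acc = 0.0
            for j in range(n_inp):
                acc += W[i, j] * r[j]
            if rho_coll > 0.0:
                cc = 0.0
                for k2 in range(n_mec):
                    cc += W_coll[i, k2] * psi_del[k2]
                acc += rho_coll * cc
            h_in[i] = f * acc
        delay[slot] = psi

        # Hebbian update with running-mean subtraction + row normalization
        for i in range(n_mec):
            acc = 0.0
            for j in range(n_inp):
                w = W[i, j] + eps * (psi[i] * r[j] - psi_bar[i] * r_bar[j])
                W[i, j] = w
                acc += w * w
            acc = np.sqrt(acc)
            if acc > 0.0:
                for j in range(n_inp):
                    W[i, j] /= acc
        for i in range(n_mec):
            psi_bar[i] += eta * (psi[i] - psi_bar[i])
        for j in range(n_inp):
            r_bar[j] += eta * (r[j] - r_bar[j])

        # rate-map accumulation
        ix = int(pos[0] / box[0] * nx)
        if ix >= nx:
            ix = nx - 1
        iy = int(pos[1] / box[1] * ny)
        if iy >= ny:
            iy = ny - 1
        iz = int(pos[2] / box[2] * nz)
        if iz >= nz:
            iz = nz - 1
        vox = (ix * ny + iy) * nz + iz
        occ[ck, vox] += 1.0
        ps = 0.0
        ss = 0.0
        for i in range(n_mec):
            maps[ck, i, vox] += psi[i]
            ps += psi[i]
            ss += psi[i] * psi[i]
        a_sum[ck] += ps / n_mec
        s_sum[ck] += (ps * ps) / (n_mec * ss) if ss > 0 else 0.0

        if t % 1000 == 0:
            ok = True
            for i in range(n_mec):
                if not np.isfinite(psi[i]) or not np.isfinite(alpha[i]):
                    ok = False
            if not ok:
                return maps, occ, g_ck, mu_ck, nonconv, a_sum, s_sum, traj, t

        if t + 1 == checkpoints[ck]:
            g_ck[ck] = g
            mu_ck[ck] = mu
            if ck + 1 < n_ck:
                ck += 1

    return maps, occ, g_ck, mu_ck, nonconv, a_sum, s_sum, traj, -1
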