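"""Fixed collateral (recurrent) weights.

Each output unit is temporarily assigned an auxiliary field position (drawn
among the place-field centers). The weight from unit k to unit i is strong
when both units' preferred directions align with the line from k's field to
i's field and when i's field sits roughly one transmission-delay flight
(l = v * tau) downstream of k's field:

    W_ik = [ f_theta_i(omega_ik) f_theta_k(omega_ik) exp(-d_ki^2 / 2 sigma_f^2) - kappa ]_+

with omega_ik the unit vector from field k to field i and d_ki the distance
between field i and field k displaced by l along omega_ik. Rows are then
L2-normalized; the diagonal is forced to zero.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .mec_dynamics import hd_tuning

__all__ = ["build_collateral", "choose_aux_positions"]


def choose_aux_positions(centers: np.ndarray, n_mec: int, rng: np.random.Generator) -> np.ndarray:
    """Pick one auxiliary field per output unit among the place centers."""
    idx = rng.choice(len(centers), size=n_mec, replace=n_mec > len(centers))
    return centers[idx]


def build_collateral(
    aux_positions: np.ndarray,
    theta: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    logger=None,
):
    """Construct the (n_mec, n_mec) collateral weight matrix.

    Coincident auxiliary fields have an undefined connecting direction; a
    uniformly random one is substituted (and logged). With ``kappa >= 1``
    every pre-normalization weight is zero and a ValueError is raised.
    """
    pos = np.asarray(aux_positions, dtype=float)
    n = len(pos)
    ell = cfg.v * cfg.tau_delay * cfg.dt / cfg.L
    diff = pos[:, None, :] - pos[None, :, :]  # diff[i,k] = field_i - field_k
    dist = np.linalg.norm(diff, axis=2)
    coincident = (dist < 1e-12) & ~np.eye(n, dtype=bool)
    if coincident.any():
        if logger is not None:
            logger(f"collateral: {int(coincident.sum())} coincident aux pairs, random directions used")
        if rng is None:
            rng = np.random.default_rng(0)
    omega = np.zeros_like(diff)
    nz = dist > 1e-12
    omega[nz] = diff[nz] / dist[nz][:, None]
    if coincident.any():
        v = rng.standard_normal((int(coincident.sum()), 3))
        omega[coincident] = v / np.linalg.norm(v, axis=1, keepdims=True)

    # per-pair tuning factors f_theta_i(omega_ik) and f_theta_k(omega_ik)
    cosg_i = np.einsum("id,ikd->ik", theta, omega)
    cosg_k = np.einsum("kd,ikd->ik", theta, omega)
    f_i = cfg.c + (1.0 - cfg.c) * np.exp(cfg.nu * (cosg_i - 1.0))
    f_k = cfg.c + (1.0 - cfg.c) * np.exp(cfg.nu * (cosg_k - 1.0))

    # distance between field i and field k displaced by l along omega_ik;
    # since the offset is parallel to the connecting line this is |dist - l|
    d_ki = dist - ell
    W = f_i * f_k * np.exp(-(d_ki**2) / (2.0 * cfg.sigma_f**2)) - cfg.kappa
    np.clip(W, 0.0, None, out=W)
    np.fill_diagonal(W, 0.0)

    norms = np.linalg.norm(W, axis=1, keepdims=True)
    if np.all(norms == 0):
        raise ValueError("degenerate collateral matrix: all weights zero (kappa too large?)")
    zero_rows = norms[:, 0] == 0
    if zero_rows.any() and logger is not None:
        logger(f"collateral: {int(zero_rows.sum())} rows with no suprathreshold weights left at zero")
    norms[norms == 0] = 1.0
    return W / norms
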