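"""Single-step dynamics of the would-be grid units.

Input summation with head-direction gating and delayed collateral drive,
two-variable firing-rate adaptation, a rectified-arctangent transfer
function, and the iterative gain/threshold control that clamps mean activity
and sparsity to their targets (a0 = 0.1, s0 = 0.3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "hd_tuning",
    "total_input",
    "update_adaptation",
    "transfer",
    "sparsity",
    "adjust_gain_threshold",
    "NetworkState",
]


def hd_tuning(theta_pref: np.ndarray, omega: np.ndarray, c: float, nu: float) -> np.ndarray:
    """Head-direction gating factor ``c + (1-c) exp(nu (cos(gamma) - 1))``.

    ``cos(gamma)`` is the dot product between the unit's preferred direction
    and the current movement direction (both unit 3-vectors). Accepts a
    single preferred direction or an (N, 3) stack; returns the same leading
    shape. Values lie in ``[c + (1-c) e^{-2 nu}, 1]``.
    """
    th = np.asarray(theta_pref, dtype=float)
    om = np.asarray(omega, dtype=float)
    if abs(np.linalg.norm(om) - 1.0) > 1e-6:
        raise ValueError("omega must be a unit vector")
    norms = np.linalg.norm(th, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("preferred directions must be unit vectors")
    cosg = th @ om
    return c + (1.0 - c) * np.exp(nu * (cosg - 1.0))


def total_input(
    W_ff: np.ndarray,
    r: np.ndarray,
    W_coll: np.ndarray | None = None,
    psi_delayed: np.ndarray | None = None,
    f: np.ndarray | float = 1.0,
    rho_coll: float = 0.0,
) -> np.ndarray:
    """Gated total input ``h_i = f_i (sum_j W_ij r_j + rho sum_k Wc_ik psi_k)``."""
    if rho_coll < 0:
        raise ValueError("rho_coll must be nonnegative")
    h = W_ff @ r
    if rho_coll > 0 and W_coll is not None:
        h = h + rho_coll * (W_coll @ psi_delayed)
    return np.asarray(f) * h


def update_adaptation(alpha, beta, h, b1, b2):
    """One step of the two-variable adaptation dynamics.

    ``alpha' = alpha + b1 (h - beta - alpha)``, ``beta' = beta + b2 (h - beta)``.
    Under constant h the fixed point is ``alpha* = 0``, ``beta* = h``: slow
    subtraction of the running input level makes firing fatigue.
    """
    alpha2 = alpha + b1 * (h - beta - alpha)
    beta2 = beta + b2 * (h - beta)
    return alpha2, beta2


def transfer(alpha, mu, g):
    """Rectified saturating transfer ``(2/pi) arctan(g (alpha - mu))`` for
    ``alpha > mu``, else 0. Maximal rate 1."""
    if g <= 0:
        raise ValueError("gain must be positive")
    x = np.asarray(alpha, dtype=float) - mu
    return np.where(x > 0, (2.0 / np.pi) * np.arctan(g * x), 0.0)


def sparsity(psi: np.ndarray) -> float:
    """Population sparsity ``(sum psi)^2 / (N sum psi^2)``; 0 for silence."""
    ss = float(np.sum(psi**2))
    if ss == 0.0:
        return 0.0
    return float(np.sum(psi)) ** 2 / (len(psi) * ss)


def adjust_gain_threshold(
    alpha: np.ndarray,
    g: float,
    mu: float,
    a0: float = 0.1,
    s0: float = 0.3,
    b3: float = 0.01,
    b4: float = 0.1,
    tol: float = 0.1,
    max_iter: int = 100,
):
    """Iterate threshold and gain until mean activity and sparsity both sit
    within ``tol`` relative error of (a0, s0).

    Returns ``(g, mu, psi, converged, n_iter)``. On a silent population the
    sparsity term is neutral and only the threshold moves (downwards). If the
    cap is reached, the *rates* are those of the iterate with the smallest
    worst-case relative band violation, while the returned (g, mu) are the
    last iterate so that repeated warm-started calls keep making progress.
    """
    best_psi = None
    best_viol = np.inf
    for k in range(max_iter + 1):
        psi = transfer(alpha, mu, g)
        a = float(np.mean(psi))
        s = sparsity(psi)
        silent = s == 0.0
        s_eff = s0 if silent else s
        viol = max(abs(a - a0) / a0, abs(s_eff - s0) / s0)
        if viol < best_viol:
            best_viol = viol
            best_psi = psi
        if viol <= tol:
            return g, mu, psi, True, k
        if k == max_iter:
            break
        mu = mu + b3 * (a - a0)
        g = g + b4 * g * (s_eff - s0)
    return g, mu, best_psi, False, max_iter


@dataclass
class NetworkState:
    """Dynamic per-unit variables of the output layer."""

    h: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    psi: np.ndarray
    psi_bar: np.ndarray
    r_bar: np.ndarray
    g: float
    mu: float
    theta: np.ndarray  # (N, 3) preferred directions
    delay_buffer: np.ndarray  # (tau, N) past population rates

    @classmethod
    def zeros(cls, n_mec: int, n_inp: int, tau: int, theta: np.ndarray,
              g0: float = 1.0, mu0: float = 0.0) -> "NetworkState":
        z = lambda n: np.zeros(n)
        return cls(z(n_mec), z(n_mec), z(n_mec), z(n_mec), z(n_mec), z(n_inp),
                   g0, mu0, theta, np.zeros((tau, n_mec)))


def random_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform over the 4*pi solid angle."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
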