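"""Hebbian learning on the feed-forward weights.

The update is covariance-like: the outer product of instantaneous rates
minus the outer product of their exponential running means, followed by L2
normalization of every weight row (competitive constraint).
"""

from __future__ import annotations

import numpy as np

__all__ = ["update_running_means", "hebb_step", "init_weights", "normalize_rows"]


def update_running_means(psi_bar, r_bar, psi, r, eta: float):
    """Exponential moving averages with factor eta (default 0.05)."""
    if not (0 < eta <= 1):
        raise ValueError("eta must lie in (0, 1]")
    return psi_bar + eta * (psi - psi_bar), r_bar + eta * (r - r_bar)


def normalize_rows(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a zero weight row")
    return W / norms


def hebb_step(W, psi, r, psi_bar, r_bar, eps: float):
    """One Hebbian step with mean subtraction and row renormalization.

    ``W~_ij = W_ij + eps (psi_i r_j - psi_bar_i r_bar_j)``, then each row is
    rescaled to unit L2 norm. With rates equal to their means the update is
    exactly null (up to renormalization of an already unit-norm W).
    """
    Wt = W + eps * (np.outer(psi, r) - np.outer(psi_bar, r_bar))
    return normalize_rows(Wt)


def init_weights(n_mec: int, n_inp: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform(0,1) rows, L2-normalized."""
    return normalize_rows(rng.uniform(0.0, 1.0, size=(n_mec, n_inp)))
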