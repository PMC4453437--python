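"""Correlated random walk of the virtual bat in a 3D box.

The animal flies at constant speed; at every step the heading is rotated by
an angle drawn from N(0, sigma_h) about a uniformly random axis perpendicular
to the current heading (the isotropic one-parameter generalization of a 2D
turn-angle distribution). Walls reflect the normal component of the heading.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig

__all__ = ["step_heading", "simulate_path", "perp_basis"]


def perp_basis(h: np.ndarray):
    """Deterministic orthonormal pair spanning the plane perpendicular to h.

    Uses the coordinate axis least aligned with ``h`` as helper; this exact
    construction is mirrored in the compiled simulation kernel.
    """
    a = np.zeros(3)
    a[int(np.argmin(np.abs(h)))] = 1.0
    e1 = np.cross(h, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(h, e1)
    return e1, e2


def step_heading(heading: np.ndarray, sigma_h: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``heading`` by an angle ~ N(0, sigma_h) about a random
    perpendicular axis. Returns a unit vector.

    Draw order (one normal, then one uniform) is part of the contract: the
    fused simulation kernel consumes pre-drawn arrays in the same order.
    """
    h = np.asarray(heading, dtype=float)
    n = np.linalg.norm(h)
    if n < 1e-12:
        raise ValueError("zero-norm heading")
    h = h / n
    if sigma_h < 0:
        raise ValueError("sigma_h must be nonnegative")
    theta = rng.normal(0.0, sigma_h) if sigma_h > 0 else 0.0
    phi = rng.uniform(0.0, 2.0 * np.pi)
    if sigma_h == 0:
        return h
    e1, e2 = perp_basis(h)
    axis = np.cos(phi) * e1 + np.sin(phi) * e2
    # Rodrigues with axis perpendicular to h
    out = h * np.cos(theta) + np.cross(axis, h) * np.sin(theta)
    return out / np.linalg.norm(out)


def _reflect(pos: np.ndarray, head: np.ndarray, box) -> None:
    """Specular reflection into the box, in place."""
    for d in range(3):
        # a step never exceeds the box side, so at most one bounce per wall
        if pos[d] < 0.0:
            pos[d] = -pos[d]
            head[d] = -head[d]
        elif pos[d] > box[d]:
            pos[d] = 2.0 * box[d] - pos[d]
            head[d] = -head[d]


def initial_state(cfg: SimConfig, rng: np.random.Generator, box=(1.0, 1.0, 1.0)):
    """Box-center start with a uniformly random heading."""
    pos = 0.5 * np.asarray(box, dtype=float)
    h = rng.standard_normal(3)
    h /= np.linalg.norm(h)
    return pos, h


def simulate_path(
    n_steps: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    box=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Generate ``n_steps`` positions (including the initial one).

    Consecutive interior positions are separated by exactly ``v*dt/L``;
    positions never leave the box.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    box = np.asarray(box, dtype=float)
    step = cfg.step_len
    if step >= box.min():
        raise ValueError(f"step length {step} exceeds box side {box.min()}")
    pos, head = initial_state(cfg, rng, box)
    out = np.empty((n_steps, 3))
    out[0] = pos
    for t in range(1, n_steps):
        head = step_heading(head, cfg.sigma_h, rng)
        pos = pos + step * head
        _reflect(pos, head, box)
        out[t] = pos
    return out
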