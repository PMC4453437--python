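"""Orchestration of full learning runs.

``run`` wires together the trajectory, the place-cell input layer, the
output-unit dynamics, the collateral weights and the Hebbian plasticity, and
accumulates occupancy-normalized rate maps between checkpoints. The heavy
per-step loop executes in a compiled kernel; ``run_python`` is a slow
reference implementation composed from the per-operation module functions,
used to validate the kernel step for step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import collateral, inputs, mec_dynamics, plasticity, trajectory
from ._kernels import run_core
from .config import RunConfig, SimConfig
from .maps import RateMap3D

__all__ = ["RunOutput", "run", "run_python", "draw_turn_randoms"]


@dataclass
class RunOutput:
    """Everything a learning run produces."""

    cfg: RunConfig
    checkpoints: tuple
    #: per-checkpoint interval rate maps, (n_ck, n_mec, nx, ny, nz); NaN where unvisited
    rate_maps: np.ndarray
    occupancy: np.ndarray  # (n_ck, nx, ny, nz)
    W_ff: np.ndarray
    W_coll: np.ndarray | None
    theta: np.ndarray
    centers: np.ndarray
    g: np.ndarray
    mu: np.ndarray
    nonconv: np.ndarray
    mean_activity: np.ndarray  # per-checkpoint interval mean of a
    mean_sparsity: np.ndarray
    b1: np.ndarray
    trajectory: np.ndarray | None = None

    def ratemap(self, ck: int, unit: int) -> RateMap3D:
        return RateMap3D(self.rate_maps[ck, unit], box=self.cfg.box,
                         occupancy=self.occupancy[ck])


def draw_turn_randoms(n_steps: int, sigma_h: float, rng: np.random.Generator):
    """Pre-draw the per-step heading randomness in the step_heading order."""
    thetas = rng.normal(0.0, sigma_h, size=n_steps) if sigma_h > 0 else np.zeros(n_steps)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)
    return thetas, phis


def _setup(cfg: RunConfig, rng: np.random.Generator):
    sim = cfg.sim
    centers = inputs.make_centers(sim.per_axis_inp, box=cfg.box)
    theta = mec_dynamics.random_directions(sim.n_mec, rng)
    W = plasticity.init_weights(sim.n_mec, len(centers), rng)
    if cfg.no_collaterals or sim.rho_coll == 0:
        W_coll = np.zeros((sim.n_mec, sim.n_mec))
        rho = 0.0
    else:
        aux = collateral.choose_aux_positions(centers, sim.n_mec, rng)
        W_coll = collateral.build_collateral(aux, theta, sim, rng=rng)
        rho = sim.rho_coll
    if cfg.heterogeneous_b1:
        b1 = rng.uniform(0.85, 1.2, size=sim.n_mec) * sim.b1
    else:
        b1 = np.full(sim.n_mec, sim.b1)
    b2 = b1 / (sim.b1 / sim.b2)  # preserve the configured b1/b2 ratio per unit
    return centers, theta, W, W_coll, rho, b1, b2


def run(cfg: RunConfig, keep_trajectory: bool = False) -> RunOutput:
    """Execute a full learning run (compiled path). Deterministic per seed."""
    cfg.validate()
    sim = cfg.sim
    rng = np.random.default_rng(sim.seed)
    centers, theta, W, W_coll, rho, b1, b2 = _setup(cfg, rng)
    box = np.asarray(cfg.box, dtype=float)
    pos, head = trajectory.initial_state(sim, rng, box)
    thetas_turn, phis = draw_turn_randoms(cfg.n_steps, sim.sigma_h, rng)
    ck = np.asarray(cfg.checkpoints, dtype=np.int64)
    shape = np.asarray(cfg.map_shape, dtype=np.int64)
    stride = cfg.traj_stride if keep_trajectory else 0
    maps, occ, g_ck, mu_ck, nonconv, a_sum, s_sum, traj, nan_step = run_core(
        cfg.n_steps, pos.copy(), head.copy(), thetas_turn, phis,
        sim.step_len, box, centers, sim.sigma_p, W, W_coll, theta,
        sim.c, sim.nu, rho, sim.tau_delay, b1, b2, sim.b3, sim.b4,
        sim.eps, sim.eta, sim.a0, sim.s0, sim.band_tol, sim.max_gain_iter,
        1.0, 0.0, ck, shape, stride,
    )
    if nan_step >= 0:
        raise FloatingPointError(f"non-finite network state at step {nan_step}")
    full_shape = (len(ck), sim.n_mec, *cfg.map_shape)
    occ = occ.reshape(len(ck), *cfg.map_shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_maps = maps.reshape(full_shape) / occ[:, None]
    # interval lengths for the per-checkpoint activity averages
    lens = np.diff(np.concatenate([[0], ck]))
    return RunOutput(
        cfg=cfg, checkpoints=tuple(int(t) for t in ck), rate_maps=rate_maps,
        occupancy=occ, W_ff=W, W_coll=W_coll if rho > 0 else None, theta=theta,
        centers=centers, g=g_ck, mu=mu_ck, nonconv=nonconv,
        mean_activity=a_sum / lens, mean_sparsity=s_sum / lens, b1=b1,
        trajectory=traj if keep_trajectory else None,
    )


def run_python(cfg: RunConfig) -> dict:
    """Reference implementation built from the per-operation functions.

    Returns the final state after ``cfg.n_steps`` steps. Intended for short
    equivalence runs against the compiled kernel, not for production use.
    """
    cfg.validate()
    sim = cfg.sim
    rng = np.random.default_rng(sim.seed)
    centers, theta, W, W_coll, rho, b1, b2 = _setup(cfg, rng)
    box = np.asarray(cfg.box, dtype=float)
    pos, head = trajectory.initial_state(sim, rng, box)
    thetas_turn, phis = draw_turn_randoms(cfg.n_steps, sim.sigma_h, rng)
    layer = inputs.PlaceLayer(centers, sim.sigma_p)
    n = sim.n_mec
    alpha = np.zeros(n)
    beta = np.zeros(n)
    h = np.zeros(n)
    psi = np.zeros(n)
    psi_bar = np.zeros(n)
    r_bar = np.zeros(len(centers))
    delay = np.zeros((sim.tau_delay, n))
    g, mu = 1.0, 0.0
    positions = [pos.copy()]
    for t in range(cfg.n_steps):
        if t > 0:
            e1, e2 = trajectory.perp_basis(head)
            axis = np.cos(phis[t]) * e1 + np.sin(phis[t]) * e2
            head = head * np.cos(thetas_turn[t]) + np.cross(axis, head) * np.sin(thetas_turn[t])
            head = head / np.linalg.norm(head)
            pos = pos + sim.step_len * head
            for dax in range(3):
                if pos[dax] < 0:
                    pos[dax] = -pos[dax]
                    head[dax] = -head[dax]
                elif pos[dax] > box[dax]:
                    pos[dax] = 2 * box[dax] - pos[dax]
                    head[dax] = -head[dax]
            positions.append(pos.copy())
        r = inputs.place_rates(pos, layer)
        alpha, beta = mec_dynamics.update_adaptation(alpha, beta, h, b1, b2)
        g, mu, psi, conv, _ = mec_dynamics.adjust_gain_threshold(
            alpha, g, mu, sim.a0, sim.s0, sim.b3, sim.b4, sim.band_tol, sim.max_gain_iter
        )
        slot = t % sim.tau_delay
        psi_del = delay[slot].copy()
        f = mec_dynamics.hd_tuning(theta, head / np.linalg.norm(head), sim.c, sim.nu)
        h = mec_dynamics.total_input(W, r, W_coll, psi_del, f, rho) if rho > 0 else f * (W @ r)
        delay[slot] = psi
        W = plasticity.hebb_step(W, psi, r, psi_bar, r_bar, sim.eps)
        psi_bar, r_bar = plasticity.update_running_means(psi_bar, r_bar, psi, r, sim.eta)
    return {
        "positions": np.asarray(positions), "W": W, "psi": psi, "alpha": alpha,
        "beta": beta, "g": g, "mu": mu, "psi_bar": psi_bar, "r_bar": r_bar,
    }
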