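"""Model configuration containers.

All spatial quantities are expressed in units of the box side ``L`` unless
noted otherwise. The physical interpretation used throughout the docs is
``dt = 10 ms``, ``v = 1 m/s``, ``L = 2.5 m``, so one time step covers
``v*dt/L = 0.004`` box sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import yaml


@dataclass
class SimConfig:
    """Scalar parameters of the network model.

    Parameters
    ----------
    n_mec : number of medial-entorhinal (output) units.
    per_axis_inp : place-cell lattice count per axis; ``N_inp = per_axis**3``
        for a cubic box.
    sigma_p : place-field width (units of L).
    sigma_h : per-step heading-change s.d. (radians).
    v : running speed (m/s).
    dt : time step (s).
    L : box side (m). Positions are kept in units of L internally; only the
        ratio ``v*dt/L`` enters the dynamics.
    b1, b2 : fast / slow adaptation rates (per step); ``b2 = b1/3``.
    b3, b4 : threshold / gain iteration rates.
    eps : Hebbian learning rate.
    eta : running-mean averaging factor.
    a0, s0 : target mean activity and sparsity.
    c, nu : head-direction tuning floor and concentration.
    rho_coll : relative strength of collateral input.
    tau_delay : collateral transmission delay (steps).
    kappa : collateral inhibition factor.
    sigma_f : collateral connectivity spread (units of L).
    """

    n_mec: int = 125
    per_axis_inp: int = 12
    sigma_p: float = 0.05
    sigma_h: float = 0.15
    v: float = 1.0
    dt: float = 0.01
    L: float = 2.5
    b1: float = 0.1
    b2: float = 0.1 / 3.0
    b3: float = 0.01
    b4: float = 0.1
    eps: float = 0.002
    eta: float = 0.05
    a0: float = 0.1
    s0: float = 0.3
    c: float = 0.2
    nu: float = 0.8
    rho_coll: float = 0.1
    tau_delay: int = 25
    kappa: float = 0.05
    sigma_f: float = 0.2
    band_tol: float = 0.1
    max_gain_iter: int = 100
    seed: int = 0

    @property
    def step_len(self) -> float:
        """Distance covered in one time step, in units of L."""
        return self.v * self.dt / self.L

    def validate(self) -> None:
        if self.step_len <= 0 or self.step_len >= 1.0:
            raise ValueError(f"step length {self.step_len} must lie in (0, 1) box units")
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")
        if not (0 < self.a0 < 1 and 0 < self.s0 <= 1):
            raise ValueError("a0 and s0 must lie in (0, 1)")
        if self.rho_coll < 0:
            raise ValueError("rho_coll must be nonnegative")
        if self.tau_delay < 1:
            raise ValueError("tau_delay must be >= 1")


@dataclass
class RunConfig:
    """A full simulation run: SimConfig plus schedule and experiment variants."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_steps: int = 1_000_000
    checkpoints: Sequence[int] = ()
    map_shape: tuple = (25, 25, 25)
    no_collaterals: bool = False
    heterogeneous_b1: bool = False
    #: per-axis box scale factors (>= 1); place-center counts scale to keep
    #: input density fixed.
    scale: tuple = (1.0, 1.0, 1.0)
    #: store every k-th trajectory sample (0 disables storage)
    traj_stride: int = 100

    def __post_init__(self):
        if not self.checkpoints:
            self.checkpoints = default_checkpoints(self.n_steps)
        self.checkpoints = tuple(int(t) for t in self.checkpoints)
        self.map_shape = tuple(int(m) for m in self.map_shape)
        self.scale = tuple(float(s) for s in self.scale)

    @property
    def box(self) -> tuple:
        return self.scale

    def validate(self) -> None:
        self.sim.validate()
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        cps = self.checkpoints
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("checkpoint schedule must be strictly increasing")
        if cps and cps[-1] > self.n_steps:
            raise ValueError("checkpoints beyond n_steps")
        if any(s < 1.0 for s in self.scale):
            raise ValueError("scale factors must be >= 1")


def default_checkpoints(n_steps: int) -> tuple:
    """Snapshot schedule {2, 5, 10, 20} x 10^6 scaled proportionally to the run."""
    fracs = (0.1, 0.25, 0.5, 1.0)
    cps = sorted({max(1, int(round(f * n_steps))) for f in fracs})
    return tuple(cps)


def to_yaml(cfg: RunConfig) -> str:
    d = asdict(cfg)
    d["checkpoints"] = list(cfg.checkpoints)
    d["map_shape"] = list(cfg.map_shape)
    d["scale"] = list(cfg.scale)
    return yaml.safe_dump(d, sort_keys=False)


def from_yaml(text: str, logger=None) -> RunConfig:
    """Parse a YAML config; missing fields fall back to defaults (logged)."""
    d = yaml.safe_load(text) or {}
    if not isinstance(d, dict):
        raise ValueError("config root must be a mapping")
    sim_d = d.pop("sim", {}) or {}
    known_sim = {f.name for f in SimConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    known_run = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    bad = (set(sim_d) - known_sim) | (set(d) - known_run - {"sim"})
    if bad:
        raise ValueError(f"unknown config fields: {sorted(bad)}")
    missing = (known_sim - set(sim_d)) | (known_run - set(d) - {"sim"})
    if missing and logger is not None:
        logger(f"config: defaults injected for {sorted(missing)}")
    sim = SimConfig(**sim_d)
    if "b2" not in sim_d:
        sim = replace(sim, b2=sim.b1 / 3.0)
    d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
    return RunConfig(sim=sim, **d)


def physical_units(cfg: SimConfig):
    """Presentation helper converting model units to metres / seconds / hours."""
    return {
        "step_m": cfg.v * cfg.dt,
        "box_m": cfg.L,
        "steps_per_hour": 3600.0 / cfg.dt,
        "hours_per_Msteps": 1e6 * cfg.dt / 3600.0,
    }
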