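"""Persistence: HDF5 run containers, standalone rate maps, CSV score tables.

Every file embeds the config (YAML echo) and seed that produced it, so a
run can be reproduced bit-identically from its own output.
"""

from __future__ import annotations

import dataclasses
import sys

import h5py
import numpy as np
import pandas as pd

from . import config as cfgmod
from .maps import RateMap3D
from .simulator import RunOutput

__all__ = [
    "save_run",
    "load_run",
    "save_ratemap",
    "load_ratemap",
    "scores_to_frame",
    "log",
]

FORMAT_VERSION = 1


def log(msg: str) -> None:
    print(f"grid3d: {msg}", file=sys.stderr)


def _write_config(f: h5py.File, cfg: cfgmod.RunConfig) -> None:
    g = f.require_group("config")
    g.attrs["yaml"] = cfgmod.to_yaml(cfg)
    g.attrs["seed"] = cfg.sim.seed
    g.attrs["format_version"] = FORMAT_VERSION


def save_run(path, out: RunOutput) -> None:
    with h5py.File(path, "w") as f:
        _write_config(f, out.cfg)
        f.create_dataset("ratemaps/maps", data=out.rate_maps, compression="gzip")
        f.create_dataset("ratemaps/occupancy", data=out.occupancy, compression="gzip")
        f.create_dataset("ratemaps/checkpoints", data=np.asarray(out.checkpoints))
        f.create_dataset("weights/ff", data=out.W_ff)
        if out.W_coll is not None:
            f.create_dataset("weights/coll", data=out.W_coll)
        f.create_dataset("place/centers", data=out.centers)
        st = f.require_group("state")
        st.create_dataset("theta", data=out.theta)
        st.create_dataset("g", data=out.g)
        st.create_dataset("mu", data=out.mu)
        st.create_dataset("nonconv", data=out.nonconv)
        st.create_dataset("mean_activity", data=out.mean_activity)
        st.create_dataset("mean_sparsity", data=out.mean_sparsity)
        st.create_dataset("b1", data=out.b1)
        if out.trajectory is not None:
            f.create_dataset("trajectory", data=out.trajectory, compression="gzip")


def load_run(path) -> RunOutput:
    with h5py.File(path, "r") as f:
        for group in ("config", "ratemaps", "weights", "state", "place"):
            if group not in f:
                raise ValueError(f"corrupted run container: missing group '{group}'")
        ver = f["config"].attrs.get("format_version", -1)
        if ver != FORMAT_VERSION:
            raise ValueError(
                f"run container format v{ver} not supported (expected v{FORMAT_VERSION})"
            )
        cfg = cfgmod.from_yaml(f["config"].attrs["yaml"])
        return RunOutput(
            cfg=cfg,
            checkpoints=tuple(int(t) for t in f["ratemaps/checkpoints"][...]),
            rate_maps=f["ratemaps/maps"][...],
            occupancy=f["ratemaps/occupancy"][...],
            W_ff=f["weights/ff"][...],
            W_coll=f["weights/coll"][...] if "weights/coll" in f else None,
            theta=f["state/theta"][...],
            centers=f["place/centers"][...],
            g=f["state/g"][...],
            mu=f["state/mu"][...],
            nonconv=f["state/nonconv"][...],
            mean_activity=f["state/mean_activity"][...],
            mean_sparsity=f["state/mean_sparsity"][...],
            b1=f["state/b1"][...],
            trajectory=f["trajectory"][...] if "trajectory" in f else None,
        )


def save_ratemap(path, ratemap: RateMap3D, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ratemap/rates", data=ratemap.rates)
        f["ratemap"].attrs["box"] = ratemap.box
        f["ratemap"].attrs["format_version"] = FORMAT_VERSION
        for k, v in (meta or {}).items():
            f["ratemap"].attrs[k] = v


def load_ratemap(path) -> RateMap3D:
    with h5py.File(path, "r") as f:
        if "ratemap" not in f:
            raise ValueError("corrupted rate-map file: missing group 'ratemap'")
        return RateMap3D(f["ratemap/rates"][...], box=tuple(f["ratemap"].attrs["box"]))


def scores_to_frame(scores) -> pd.DataFrame:
    """Per-unit GridScores -> flat table (vectors expanded to components)."""
    rows = []
    for u, s in enumerate(scores):
        row = {"unit": u}
        for fld in dataclasses.fields(s):
            v = getattr(s, fld.name)
            if isinstance(v, np.ndarray):
                for ax, comp in zip("xyz", v):
                    row[f"{fld.name}_{ax}"] = comp
            elif v is None:
                pass
            else:
                row[fld.name] = v
        rows.append(row)
    return pd.DataFrame(rows)
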