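"""Ideal and null rate-map fixtures for the analysis machinery.

The crystalline fixtures voxelize the analytic plane-wave constructions; the
null fixtures (smoothed noise, voxel-shuffled) provide chance-level
references for the order scores.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .analytic_cost import LatticeSpec, psi
from .maps import RateMap3D

__all__ = ["make_fixture"]

KINDS = ("fcc", "hcp", "planar-hex", "noise", "shuffled")


def make_fixture(
    kind: str,
    a: float = 0.3,
    resolution: int = 48,
    rng: np.random.Generator | None = None,
    n: int = 4,
    box=(1.0, 1.0, 1.0),
) -> RateMap3D:
    """Voxelized ideal map on a ``resolution^3`` grid over ``box``.

    kinds: ``fcc`` / ``hcp`` — analytic psi_n with spacing ``a``;
    ``planar-hex`` — a planar hexagonal pattern extended uniformly in z;
    ``noise`` — rectified smoothed Gaussian noise; ``shuffled`` — the fcc
    fixture with voxels randomly permuted (destroys all spatial structure).
    """
    kind = kind.lower()
    if kind not in KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    if resolution < 32:
        raise ValueError("resolution must be >= 32")
    box = tuple(float(b) for b in box)
    if kind in ("fcc", "hcp", "planar-hex") and a >= min(box):
        raise ValueError("spacing a must be smaller than the box")
    rng = np.random.default_rng(0) if rng is None else rng
    ax = [(np.arange(resolution) + 0.5) * (b / resolution) for b in box]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    if kind in ("fcc", "hcp"):
        vals = psi(X, LatticeSpec(kind, a=a, n=n))
    elif kind == "planar-hex":
        # hexagonal wave-vector triple in the xy plane, constant along z
        from .analytic_cost import hcp_wavevectors

        kxy, _ = hcp_wavevectors(a)
        ph = X @ kxy.T
        base = 1.0 + (2.0 / 3.0) * np.cos(ph).sum(axis=-1)
        vals = np.clip(base, 0.0, None) ** n
    elif kind == "noise":
        vals = gaussian_filter(rng.standard_normal((resolution,) * 3), 2.0, mode="wrap")
        vals = np.clip(vals - vals.mean(), 0.0, None)
    else:  # shuffled
        base = make_fixture("fcc", a=a, resolution=resolution, n=n, box=box).rates
        flat = base.ravel().copy()
        rng.shuffle(flat)
        vals = flat.reshape(base.shape)
    return RateMap3D(vals, box=box)
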