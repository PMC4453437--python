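"""Place-cell-like input layer: Gaussian fields on a regular lattice.

Each input unit j fires as ``r_j(x) = exp(-||x - x_j||^2 / (2 sigma_p^2))``,
with centers on a cell-centered cubic lattice (no center on a wall), so that
summed input activity is approximately homogeneous across the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlaceLayer", "make_centers", "place_rates"]


@dataclass
class PlaceLayer:
    centers: np.ndarray  # (N, 3), units of L
    sigma_p: float

    @property
    def n_units(self) -> int:
        return len(self.centers)


def make_centers(per_axis: int, box=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Cell-centered regular lattice of place-field centers.

    ``per_axis`` is the count along a unit box side; for scaled (non-cubic)
    boxes the per-axis count grows with the side so the center density stays
    fixed. Nearest-neighbor distance is ``box_d / count_d`` per axis.
    """
    if per_axis < 2:
        raise ValueError("per_axis must be >= 2")
    box = np.asarray(box, dtype=float)
    counts = [max(2, int(round(per_axis * b))) for b in box]
    axes = [(np.arange(c) + 0.5) * (b / c) for c, b in zip(counts, box)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def place_rates(x: np.ndarray, layer: PlaceLayer) -> np.ndarray:
    """Gaussian place rates at position ``x``; values in (0, 1]."""
    if layer.sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    d2 = np.sum((layer.centers - np.asarray(x, dtype=float)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * layer.sigma_p**2))
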