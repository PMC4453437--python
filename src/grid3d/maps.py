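"""Voxelized 3D rate maps and autocorrelograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RateMap3D", "Autocorr3D"]


@dataclass
class RateMap3D:
    """Occupancy-normalized mean firing rate on a voxel grid.

    ``rates`` may contain NaN for unvisited voxels; ``box`` is the physical
    extent (units of L) of the grid along each axis.
    """

    rates: np.ndarray  # (nx, ny, nz), NaN = unvisited
    box: tuple = (1.0, 1.0, 1.0)
    occupancy: np.ndarray | None = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be a 3D array")
        self.box = tuple(float(b) for b in self.box)

    @property
    def shape(self):
        return self.rates.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.asarray(self.box) / np.asarray(self.shape)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.rates)

    def filled(self, fill: float | None = None) -> np.ndarray:
        """Rates with NaN replaced (default: mean of valid voxels)."""
        v = self.valid
        if v.all():
            return self.rates
        out = self.rates.copy()
        out[~v] = np.nanmean(self.rates) if fill is None else fill
        return out


@dataclass
class Autocorr3D:
    """Pearson spatial autocorrelation per 3D voxel displacement.

    ``corr`` is centered: index ``center`` corresponds to zero lag, and
    ``corr[center + q] = C(q)``. Displacements whose valid overlap falls
    below the threshold are NaN. ``voxel_size`` carries the physical size of
    one displacement step.
    """

    corr: np.ndarray
    n_overlap: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self):
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)

    @property
    def center(self) -> tuple:
        return tuple(s // 2 for s in self.corr.shape)

    def displacement_grid(self):
        """Physical displacement vectors of every lag voxel, shape (*shape, 3)."""
        c = self.center
        ax = [
            (np.arange(s) - c[d]) * self.voxel_size[d]
            for d, s in enumerate(self.corr.shape)
        ]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1)

    def value_at(self, disp: np.ndarray) -> float:
        """Trilinear interpolation of C at a physical displacement vector."""
        from scipy.ndimage import map_coordinates

        disp = np.asarray(disp, dtype=float)
        idx = disp / self.voxel_size + np.asarray(self.center)
        filled = np.nan_to_num(self.corr, nan=0.0)
        return float(
            map_coordinates(filled, idx.reshape(3, 1), order=1, mode="constant", cval=0.0)[0]
        )
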