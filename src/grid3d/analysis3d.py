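"""Measurement machinery for 3D firing-rate maps.

Everything downstream of the simulator lives here: masked 3D Pearson
autocorrelograms, grid spacing, the best-plane hexagonality search, FCC/HCP
long-range order scores, local (spike-triplet) gridness, population
alignment angles, and the empirical cost terms.

Conventions: rate maps are ``RateMap3D`` (NaN marks unvisited voxels);
displacements and distances are physical (units of L). Scores are invariant
to rotations of the map and to positive rescaling of the rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates, maximum_filter
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .analytic_cost import KernelParams
from .maps import Autocorr3D, RateMap3D

__all__ = [
    "autocorr3d",
    "radial_profile",
    "spacing_from_autocorr",
    "find_peaks3d",
    "count_symmetric_pairs",
    "BestPlane",
    "best_plane",
    "fcc_hcp_scores",
    "count_hex_planes",
    "GridScores",
    "analyze_map",
    "poisson_spikes",
    "local_gridness",
    "population_alignment",
    "empirical_cost",
]

#: angle between hexagonal-plane normals in a close packing, arccos(1/3)
PLANE_ANGLE = float(np.degrees(np.arccos(1.0 / 3.0)))  # ~70.53 deg; the "~72 deg"


def _xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """F(q) = sum_x a(x) b(x+q), indexed so that F[center + q] = F(q)."""
    out = signal.fftconvolve(a, b[::-1, ::-1, ::-1], mode="full")
    return out[::-1, ::-1, ::-1]


def autocorr3d(ratemap: RateMap3D, max_lag: int | None = None, min_overlap: float = 0.05) -> Autocorr3D:
    """Masked Pearson autocorrelation of a rate map for every displacement.

    For each lag the correlation is computed over the overlapping valid
    voxels only; lags whose overlap drops below ``min_overlap`` of the valid
    voxel count are masked NaN. A constant map has no defined correlation
    and yields an all-NaN result with a warning.
    """
    m = ratemap.valid.astype(float)
    f = np.where(ratemap.valid, ratemap.rates, 0.0)
    n_valid = m.sum()
    if n_valid == 0:
        raise ValueError("rate map has no valid voxels")
    n = _xcorr(m, m)
    sa = _xcorr(f, m)
    sb = _xcorr(m, f)
    saa = _xcorr(f * f, m)
    sbb = _xcorr(m, f * f)
    sab = _xcorr(f, f)
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab - sa * sb / n
        va = saa - sa**2 / n
        vb = sbb - sb**2 / n
        corr = cov / np.sqrt(va * vb)
    # variance floor: a (near-)constant overlap has no defined correlation
    var_floor = 1e-10 * n * (np.max(np.abs(f)) ** 2 + 1e-300)
    bad = (
        (n < max(min_overlap * n_valid, 2))
        | ~np.isfinite(corr)
        | (va < var_floor)
        | (vb < var_floor)
    )
    corr[bad] = np.nan
    corr = np.clip(corr, -1.0, 1.0)
    if np.isnan(corr).all():
        warnings.warn("autocorrelation undefined everywhere (constant map?)")
    ac = Autocorr3D(corr, n, ratemap.voxel_size)
    if max_lag is not None:
        c = ac.center
        sl = tuple(slice(c[d] - max_lag, c[d] + max_lag + 1) for d in range(3))
        ac = Autocorr3D(corr[sl], n[sl], ratemap.voxel_size)
    return ac


def radial_profile(ac: Autocorr3D, n_bins: int = 60, r_max: float | None = None):
    """Mean correlation as a function of displacement magnitude."""
    disp = ac.displacement_grid()
    r = np.linalg.norm(disp, axis=-1).ravel()
    v = ac.corr.ravel()
    ok = np.isfinite(v)
    r, v = r[ok], v[ok]
    if r_max is None:
        # restrict to lags with substantial overlap: beyond ~3/4 of the
        # smallest box side the masked Pearson estimates get noisy
        half_extent = float(np.min(np.asarray(ac.corr.shape) * ac.voxel_size)) / 2.0
        r_max = min(0.75 * half_extent, r.max())
    bins = np.linspace(0, r_max, n_bins + 1)
    idx = np.digitize(r, bins) - 1
    keep = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[keep], weights=v[keep], minlength=n_bins)
    cnts = np.bincount(idx[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prof = sums / cnts
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, prof


def spacing_from_autocorr(ac: Autocorr3D, n_bins: int = 60, min_prominence: float = 0.005) -> float:
    """Grid spacing: first peak of the radial autocorrelation profile beyond
    the central peak. NaN when no secondary peak exists.

    Radial (spherical) averaging dilutes the discrete peak ring heavily, so
    the secondary peak can be small in absolute correlation; a modest
    prominence requirement rejects flat/noise-only profiles instead.
    """
    r, prof = radial_profile(ac, n_bins=n_bins)
    ok = np.isfinite(prof)
    r, prof = r[ok], prof[ok]
    if len(prof) < 8:
        return np.nan
    sm = gaussian_filter1d(prof, 1.0)
    minima, _ = signal.find_peaks(-sm)
    if len(minima) == 0:
        return np.nan
    start = minima[0]
    peaks, _ = signal.find_peaks(sm[start:], prominence=min_prominence)
    if len(peaks) == 0:
        return np.nan
    i = start + peaks[0]
    # quadratic refinement around the peak bin
    if 0 < i < len(r) - 1:
        y0, y1, y2 = sm[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            i = i + 0.5 * (y0 - y2) / denom
    return float(np.interp(i, np.arange(len(r)), r))


def find_peaks3d(ac: Autocorr3D, threshold: float = 0.2, smooth: float = 1.0):
    """Local maxima of the (smoothed) autocorrelogram above ``threshold``.

    Returns ``(disp, values)``: physical displacement vectors and the peak
    correlation values, central peak included.
    """
    filled = np.nan_to_num(ac.corr, nan=-1.0)
    sm = gaussian_filter(filled, smooth) if smooth > 0 else filled
    is_max = (sm == maximum_filter(sm, size=3)) & (sm > threshold) & np.isfinite(ac.corr)
    idx = np.argwhere(is_max)
    disp = (idx - np.asarray(ac.center)) * ac.voxel_size
    return disp, sm[is_max]


def first_shell(disp: np.ndarray, values: np.ndarray, d: float, band=(0.7, 1.3)):
    r = np.linalg.norm(disp, axis=1)
    keep = (r > band[0] * d) & (r < band[1] * d)
    return disp[keep], values[keep]


def count_symmetric_pairs(disp: np.ndarray, tol: float) -> int:
    """Number of (p, -p) peak pairs (each pair counted once)."""
    if len(disp) == 0:
        return 0
    tree = cKDTree(disp)
    matched = tree.query_ball_point(-disp, r=tol)
    n_matched = sum(1 for m in matched if len(m) > 0)
    return n_matched // 2


# ---------------------------------------------------------------------------
# best-plane hexagonality


def _sph_normals(el_deg: np.ndarray, az_deg: np.ndarray):
    el = np.radians(el_deg)
    az = np.radians(az_deg)
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def _inplane_basis(normals: np.ndarray):
    """Reference in-plane frames (e1, e2) for a batch of unit normals."""
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    helper = np.where(np.abs(normals @ z)[:, None] < 0.9, z, x)
    e1 = np.cross(normals, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)
    return e1, e2


N_PHI = 120


def _polar_patches(ac, normals, d, n_phi=N_PHI, n_r=7, rband=(0.5, 1.4)):
    """Central-slice annulus around the first peak ring, resampled on a polar
    grid; returns (n_normals, n_r, n_phi)."""
    e1, e2 = _inplane_basis(normals)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    radii = np.linspace(rband[0] * d, rband[1] * d, n_r)
    dirs = (
        np.cos(phi)[None, :, None] * e1[:, None, :]
        + np.sin(phi)[None, :, None] * e2[:, None, :]
    )  # (N, n_phi, 3)
    pts = radii[None, :, None, None] * dirs[:, None, :, :]
    idx = pts / ac.voxel_size + np.asarray(ac.center)
    filled = np.nan_to_num(ac.corr, nan=0.0)
    vals = map_coordinates(
        filled, idx.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
    ).reshape(pts.shape[:3])
    return vals


def _hexsym_scores(patches: np.ndarray) -> np.ndarray:
    """Hexagonality of each annulus patch via its pi/3 rotational symmetry.

    Score = min(rho(60), rho(120)) - max(rho(30), rho(90), rho(150), 0),
    where rho is the Pearson correlation of the patch with itself rotated
    in-plane. 1 for a perfect hexagonal ring, ~0 for unstructured slices;
    clipped to [-1, 1].
    """
    n_phi = patches.shape[2]
    P = patches - patches.mean(axis=(1, 2), keepdims=True)
    denom = (P**2).sum(axis=(1, 2))
    denom = np.where(denom > 0, denom, 1.0)

    def rho(deg):
        s = int(round(deg / 360.0 * n_phi))
        return (P * np.roll(P, s, axis=2)).sum(axis=(1, 2)) / denom

    m60 = np.minimum(rho(60), rho(120))
    m30 = np.maximum.reduce([rho(30), rho(90), rho(150), np.zeros(len(patches))])
    return np.clip(m60 - m30, -1.0, 1.0)


def _trisym_scores(patches: np.ndarray) -> np.ndarray:
    """Three-fold variant tolerant to alternating peak heights.

    Score = rho(120) - max(rho(30), rho(90), rho(150), 0). The secondary
    hexagonal planes of an HCP arrangement carry hexagonally *arranged* peaks
    of alternating full/half height; a strict pi/3 symmetry requirement would
    punish them, a 2*pi/3 one does not, while square or unstructured slices
    still score near or below zero.
    """
    n_phi = patches.shape[2]
    P = patches - patches.mean(axis=(1, 2), keepdims=True)
    denom = (P**2).sum(axis=(1, 2))
    denom = np.where(denom > 0, denom, 1.0)

    def rho(deg):
        s = int(round(deg / 360.0 * n_phi))
        return (P * np.roll(P, s, axis=2)).sum(axis=(1, 2)) / denom

    m120 = rho(120)
    m30 = np.maximum.reduce([rho(30), rho(90), rho(150), np.zeros(len(patches))])
    return np.clip(m120 - m30, -1.0, 1.0)


def _score_normals(ac, normals, d, mode: str = "hex", **kw):
    patches = _polar_patches(ac, normals, d, **kw)
    return _hexsym_scores(patches) if mode == "hex" else _trisym_scores(patches)


def _hex_axis(ac, normal, d, kappa: float = 12.0, n_phi=N_PHI):
    """One hexagon axis in the given plane: best rotation of a six-peak
    template against the first-peak ring profile."""
    e1, e2 = _inplane_basis(normal[None, :])
    e1, e2 = e1[0], e2[0]
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    pts = d * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    idx = pts / ac.voxel_size + np.asarray(ac.center)
    filled = np.nan_to_num(ac.corr, nan=0.0)
    prof = map_coordinates(filled, idx.T, order=1, mode="constant", cval=0.0)
    tmpl = sum(np.exp(kappa * (np.cos(phi - j * np.pi / 3.0) - 1.0)) for j in range(6))
    p = prof - prof.mean()
    t = tmpl - tmpl.mean()
    cc = np.fft.irfft(np.fft.rfft(p) * np.conj(np.fft.rfft(t)), n=n_phi)
    delta = float(np.argmax(cc)) * 2 * np.pi / n_phi
    return np.cos(delta) * e1 + np.sin(delta) * e2


@dataclass
class BestPlane:
    normal: np.ndarray | None
    score: float
    axis: np.ndarray | None  # one hexagon axis (in-plane unit vector)
    d: float

    @property
    def found(self) -> bool:
        return self.normal is not None


def best_plane(
    ac: Autocorr3D,
    d: float | None = None,
    coarse_step: float = 5.0,
    refine_step: float = 1.0,
) -> BestPlane:
    """Search central autocorrelogram slices for the most hexagonal one.

    Slices are parameterized by the (azimuth, elevation) of their normal on a
    coarse grid with one local refinement pass; each slice is scored by the
    pi/3 rotational symmetry of its first-peak annulus (see _hexsym_scores).
    """
    if d is None:
        d = spacing_from_autocorr(ac)
    if not np.isfinite(d) or d <= 0:
        return BestPlane(None, 0.0, None, np.nan)
    el, az = np.meshgrid(
        np.arange(0.0, 90.0 + 1e-9, coarse_step),
        np.arange(0.0, 360.0, coarse_step),
        indexing="ij",
    )
    normals = _sph_normals(el.ravel(), az.ravel())
    scores = _score_normals(ac, normals, d)
    i = int(np.argmax(scores))
    el0, az0 = el.ravel()[i], az.ravel()[i]
    # refinement around the winner
    dels = np.arange(-coarse_step, coarse_step + 1e-9, refine_step)
    el2, az2 = np.meshgrid(np.clip(el0 + dels, -90, 90), az0 + dels, indexing="ij")
    normals2 = _sph_normals(el2.ravel(), az2.ravel())
    scores2 = _score_normals(ac, normals2, d)
    j = int(np.argmax(scores2))
    axis = _hex_axis(ac, normals2[j], d)
    return BestPlane(normals2[j], float(scores2[j]), axis, float(d))


def _cone_normals(n: np.ndarray, polar_deg: float, az_deg: np.ndarray):
    """Unit normals at angle ``polar`` from n, parameterized by azimuth about n."""
    e1, e2 = _inplane_basis(n[None, :])
    e1, e2 = e1[0], e2[0]
    th = np.radians(polar_deg)
    az = np.radians(az_deg)
    return (
        np.cos(th) * n[None, :]
        + np.sin(th) * (np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * e2)
    )


@dataclass
class GridScores:
    """Per-unit long-range order summary."""

    d: float
    best_normal: np.ndarray | None
    hex_score: float
    hex_axis: np.ndarray | None
    zeta_24: float
    zeta_57: float
    chi_fcc: float
    chi_hcp: float
    lambda_z: float


def fcc_hcp_scores(
    ac: Autocorr3D,
    bp: BestPlane,
    polar_range: float = 8.0,
    polar_step: float = 2.0,
    az_step: float = 2.0,
    kappa: float = 12.0,
    peak_threshold: float = 0.2,
) -> GridScores:
    """Long-range order scores from the tilted hexagonal-plane families.

    In a close packing, the secondary hexagonal planes sit at
    ``arccos(1/3) ~ 70.5 deg`` from the basal (best) plane. A triplet with
    120-degree azimuthal separation about the best normal is mutually at
    ~70.5 deg (the FCC family, zeta_2-4); the complementary triplet offset by
    60 deg of azimuth is at ~56 deg from the first (present only in HCP,
    zeta_5-7). chi_FCC = (zeta_24 - zeta_57) / zeta_24. chi_HCP is the map
    autocorrelation at a two-layer displacement along the best normal, with
    the interlayer distance lambda_z estimated from the normal components of
    the first-shell autocorrelogram peaks (fallback: sqrt(2/3) d).
    """
    if not bp.found:
        return GridScores(bp.d, None, bp.score, None, np.nan, np.nan, np.nan, np.nan, np.nan)
    d = bp.d
    n = bp.normal
    best = (-np.inf, None, None, None)  # zeta24, polar, phi0, slice scores
    az = np.arange(0.0, 360.0, az_step)
    n_per_turn = len(az)
    third = n_per_turn // 3
    sixth = n_per_turn // 6
    for polar in np.arange(PLANE_ANGLE - polar_range, PLANE_ANGLE + polar_range + 1e-9, polar_step):
        normals = _cone_normals(n, polar, az)
        scores = np.clip(_score_normals(ac, normals, d, mode="tri"), 0.0, None)
        trip = scores[:third] + scores[third : 2 * third] + scores[2 * third : 3 * third]
        i = int(np.argmax(trip))
        if trip[i] > best[0]:
            best = (float(trip[i]), polar, i, scores)
    zeta24, polar_star, i_star, scores = best
    # complementary triplet: azimuth offset by 60 deg about the best normal
    j = (i_star + sixth) % n_per_turn
    zeta57 = float(sum(scores[(j + k * third) % n_per_turn] for k in range(3)))
    chi_fcc = (zeta24 - zeta57) / zeta24 if zeta24 > 0 else np.nan

    # interlayer distance from first-shell peak geometry
    disp, vals = find_peaks3d(ac, threshold=peak_threshold)
    shell, _ = first_shell(disp, vals, d)
    zcomp = np.abs(shell @ n)
    out_of_plane = zcomp > 0.35 * d
    if out_of_plane.any():
        lam = float(np.median(zcomp[out_of_plane]))
    else:
        lam = float(np.sqrt(2.0 / 3.0) * d)
    chi_hcp = 0.5 * (ac.value_at(2 * lam * n) + ac.value_at(-2 * lam * n))
    return GridScores(d, n, bp.score, bp.axis, zeta24, zeta57, chi_fcc, float(chi_hcp), lam)


def count_hex_planes(
    ac: Autocorr3D,
    bp: BestPlane,
    score_threshold: float = 0.4,
    **kwargs,
) -> int:
    """Number of distinct central planes with hexagonally arranged peaks:
    the best plane plus the members of the two tilted triplets whose slice
    score clears ``score_threshold`` (4 for ideal FCC, 7 for ideal HCP)."""
    if not bp.found:
        return 0
    az = np.arange(0.0, 360.0, 2.0)
    count = 1 if bp.score > score_threshold else 0
    best = (-np.inf, None)
    for polar in np.arange(PLANE_ANGLE - 8.0, PLANE_ANGLE + 8.0 + 1e-9, 2.0):
        normals = _cone_normals(bp.normal, polar, az)
        scores = _score_normals(ac, normals, bp.d, mode="tri")
        third = len(az) // 3
        trip = scores[:third] + scores[third : 2 * third] + scores[2 * third :]
        i = int(np.argmax(trip))
        if trip[i] > best[0]:
            best = (float(trip[i]), (scores, i, third, len(az)))
    scores, i, third, n_per_turn = best[1]
    sixth = n_per_turn // 6
    t1 = [scores[(i + k * third) % n_per_turn] for k in range(3)]
    t2 = [scores[(i + sixth + k * third) % n_per_turn] for k in range(3)]
    count += sum(s > score_threshold for s in t1)
    count += sum(s > score_threshold for s in t2)
    return count


def analyze_map(ratemap: RateMap3D, max_lag: int | None = None, **kwargs) -> GridScores:
    """Full per-unit pipeline: autocorrelogram, spacing, best plane, scores."""
    ac = autocorr3d(ratemap, max_lag=max_lag)
    bp = best_plane(ac)
    return fcc_hcp_scores(ac, bp, **kwargs)


# ---------------------------------------------------------------------------
# local (triplet) gridness


def poisson_spikes(ratemap: RateMap3D, n_spikes: int, rng: np.random.Generator) -> np.ndarray:
    """Sample spike positions with probability proportional to the voxel
    rate, uniformly jittered within each voxel."""
    rates = np.where(ratemap.valid, ratemap.rates, 0.0)
    rates = np.clip(rates, 0.0, None).ravel()
    tot = rates.sum()
    if tot <= 0:
        raise ValueError("cannot sample spikes from an all-zero rate map")
    idx = rng.choice(rates.size, size=n_spikes, p=rates / tot)
    ijk = np.stack(np.unravel_index(idx, ratemap.shape), axis=1).astype(float)
    ijk += rng.uniform(0.0, 1.0, size=ijk.shape)
    return ijk * ratemap.voxel_size


@dataclass
class LocalGridness:
    d: float
    char_angle: float  # degrees
    significance: float
    window: tuple
    n_triplets: int


def _triplet_angles(spikes, lo, hi, rng, max_triplets=200_000):
    tree = cKDTree(spikes)
    pairs = tree.query_pairs(hi, output_type="ndarray")
    if len(pairs) == 0:
        return np.array([])
    dd = np.linalg.norm(spikes[pairs[:, 0]] - spikes[pairs[:, 1]], axis=1)
    pairs = pairs[dd >= lo]
    adj = [[] for _ in range(len(spikes))]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    tris = []
    for i in range(len(spikes)):
        nb = [j for j in adj[i] if j > i]
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                j, k = nb[x], nb[y]
                djk = np.linalg.norm(spikes[j] - spikes[k])
                if lo <= djk <= hi:
                    tris.append((i, j, k))
        if len(tris) > max_triplets:
            break
    if not tris:
        return np.array([])
    tris = np.asarray(tris)
    if len(tris) > max_triplets:
        tris = tris[rng.choice(len(tris), max_triplets, replace=False)]
    A, B, C = spikes[tris[:, 0]], spikes[tris[:, 1]], spikes[tris[:, 2]]

    def ang(p, q, r):  # angle at p
        u, v = q - p, r - p
        cu = np.einsum("md,md->m", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        return np.degrees(np.arccos(np.clip(cu, -1, 1)))

    return np.concatenate([ang(A, B, C), ang(B, A, C), ang(C, A, B)])


def local_gridness(
    spikes: np.ndarray,
    box=(1.0, 1.0, 1.0),
    control_spikes: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    min_spikes: int = 2000,
    n_bins: int = 120,
) -> LocalGridness:
    """Triangular-tile statistics from a spike point set.

    The pairwise-distance histogram is typically multi-peaked; the second
    peak is the grid distance d. Spike pairs within the window around d
    (surrounding troughs, bounded by [0.5 d, 1.4 d]) are declared neighbors;
    internal angles of all neighbor triplets are pooled and compared, as a
    binwise ratio, against the same construction on control spikes (uniform
    by default, or reshuffled across units). The characteristic angle is the
    data-weighted median over above-unity ratio bins; the significance is
    the maximum ratio.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes, got {len(spikes)}")
    box = np.asarray(box, dtype=float)
    r_max = 0.7 * np.linalg.norm(box)
    dd = pdist(spikes)
    hist, edges = np.histogram(dd[dd < r_max], bins=n_bins)
    # normalize by the uniform-occupancy distance distribution (a g(r)-style
    # correction) so peaks are not swallowed by the r^2 density growth
    uni = rng.uniform(0.0, 1.0, size=spikes.shape) * box
    du = pdist(uni)
    base, _ = np.histogram(du[du < r_max], bins=n_bins)
    base = gaussian_filter1d(base.astype(float), 3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gr = np.where(base > 0, hist / base, 0.0)
    sm = gaussian_filter1d(gr, 2.0)
    peaks, _ = signal.find_peaks(sm, prominence=0.05 * sm.max())
    if len(peaks) < 2:
        return LocalGridness(np.nan, np.nan, np.nan, (np.nan, np.nan), 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p2 = peaks[1]
    d = float(centers[p2])
    troughs, _ = signal.find_peaks(-sm)
    left = [t for t in troughs if t < p2]
    right = [t for t in troughs if t > p2]
    lo = max(float(centers[left[-1]]) if left else 0.5 * d, 0.5 * d)
    hi = min(float(centers[right[0]]) if right else 1.4 * d, 1.4 * d)

    ang_data = _triplet_angles(spikes, lo, hi, rng)
    if control_spikes is None:
        control_spikes = rng.uniform(0.0, 1.0, size=spikes.shape) * box
    ang_ctrl = _triplet_angles(np.asarray(control_spikes, dtype=float), lo, hi, rng)
    if len(ang_data) == 0 or len(ang_ctrl) == 0:
        return LocalGridness(d, np.nan, np.nan, (lo, hi), len(ang_data) // 3)
    bins = np.arange(0.0, 181.0, 3.0)
    hd, _ = np.histogram(ang_data, bins=bins, density=True)
    hc, _ = np.histogram(ang_ctrl, bins=bins, density=True)
    mids = 0.5 * (bins[:-1] + bins[1:])
    # require some control mass so the ratio is stable
    ok = hc > 0.2 * hc[hc > 0].mean() if (hc > 0).any() else hc > 0
    ratio = np.full(len(mids), np.nan)
    ratio[ok] = hd[ok] / hc[ok]
    above = ok & (ratio > 1.0)
    if not above.any():
        return LocalGridness(d, np.nan, 1.0, (lo, hi), len(ang_data) // 3)
    w = hd[above]
    order = np.argsort(mids[above])
    cw = np.cumsum(w[order])
    med_idx = np.searchsorted(cw, 0.5 * cw[-1])
    char = float(mids[above][order][min(med_idx, len(order) - 1)])
    sig = float(np.nanmax(ratio))
    return LocalGridness(d, char, sig, (lo, hi), len(ang_data) // 3)


# ---------------------------------------------------------------------------
# population measures


def population_alignment(
    normals,
    axes,
    beta_threshold: float = 15.0,
):
    """Pairwise plane-alignment angles across a population.

    beta: angles between best-plane normals, folded to [0, 90] deg.
    omega: for pairs with beta below the threshold, the in-plane angle
    between hexagon axes, folded to [0, 30] deg by hexagonal symmetry.
    """
    normals = [None if n is None else np.asarray(n, float) for n in normals]
    idx = [i for i, n in enumerate(normals) if n is not None]
    betas, omegas = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            ni, nj = normals[i], normals[j]
            beta = np.degrees(np.arccos(np.clip(abs(ni @ nj), -1, 1)))
            betas.append(beta)
            if beta < beta_threshold and axes[i] is not None and axes[j] is not None:
                proj = axes[j] - (axes[j] @ ni) * ni
                nrm = np.linalg.norm(proj)
                if nrm < 1e-9:
                    continue
                proj /= nrm
                cosv = float(np.clip(axes[i] @ proj, -1, 1))
                sinv = float(np.cross(axes[i], proj) @ ni)
                th = np.degrees(np.arctan2(sinv, cosv)) % 60.0
                omegas.append(min(th, 60.0 - th))
    return np.asarray(betas), np.asarray(omegas)


# ---------------------------------------------------------------------------
# empirical cost terms


def empirical_cost(ratemap: RateMap3D, params: KernelParams) -> tuple:
    """Kinetic and adaptation cost terms of a measured map.

    H_K is the volume-normalized mean squared gradient; H_A the
    volume-normalized double sum psi(x) K(|x'-x|) psi(x'), evaluated by
    difference-of-Gaussians filtering (kernel truncated at 4 sd, no wrap).
    The gamma weight is *not* applied; callers combine H_K + gamma * H_A.
    """
    f = ratemap.filled()
    vs = ratemap.voxel_size
    if params.vtau_L > 0.5 * min(ratemap.box):
        warnings.warn("kernel wider than half the box; boundary truncation is severe")
    grads = np.gradient(f, *vs)
    hk = float(np.mean(sum(g**2 for g in grads)))
    sigL = params.vtau_L / vs
    sigS = params.vtau_S / vs
    kf = gaussian_filter(f, sigL, mode="constant", truncate=4.0) - params.rho * gaussian_filter(
        f, sigS, mode="constant", truncate=4.0
    )
    ha = float(np.mean(f * kf))
    return hk, ha
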