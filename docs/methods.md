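# Methods

## The model

`grid3d` simulates the developmental self-organization of grid cells in a
three-dimensional environment. A virtual bat flies through a cubic box of
side `L` at constant speed `v`, sampled at steps of `dt`; the default
physical reading is `v = 1 m/s`, `dt = 10 ms`, `L = 2.5 m`, so one step
covers `v*dt/L = 0.004` box sides and one million steps correspond to
roughly 2.8 hours of flight. The flight path is a correlated random walk:
at each step the heading rotates by an angle drawn from N(0, σ_h = 0.15 rad)
about a uniformly random axis perpendicular to the current heading, and the
walls reflect the normal heading component specularly.

A layer of `N_inp = 12³` place-cell-like inputs (Gaussian fields of width
`σ_p = 0.05 L` on a cell-centered cubic lattice) drives `N_mEC = 125`
would-be grid units through plastic feed-forward weights. Each unit's
dynamics per step are:

1. **Input.** `h_i = f_θi(ω) (Σ_j W_ij r_j + ρ Σ_k Wc_ik Ψ_k(t − τ))`, a
   head-direction-gated sum of feed-forward and delayed collateral drive
   (`ρ = 0.1`, `τ = 25` steps). The gating factor is
   `f_θ(ω) = c + (1 − c) exp(ν(cos γ − 1))` with `c = 0.2`, `ν = 0.8`, and
   `cos γ` the dot product between the unit's preferred direction (one
   random unit vector per unit, uniform over the sphere) and the current
   movement direction.
2. **Adaptation.** Two-variable fatigue dynamics,
   `α' = α + b1(h − β − α)`, `β' = β + b2(h − β)` with `b1 = 0.1`,
   `b2 = b1/3`. Under constant drive α relaxes to 0, so a unit cannot fire
   at the same place for long — this is the mechanism that spaces the
   firing fields.
3. **Transfer.** `Ψ = (2/π) arctan(g(α − μ))` for `α > μ`, else 0.
4. **Gain/threshold control.** g and μ are iterated
   (`μ ← μ + b3(a − a0)`, `g ← g + b4 g(s − s0)`, `b3 = 0.01`, `b4 = 0.1`)
   until the population mean activity `a` and sparsity
   `s = (ΣΨ)²/(N ΣΨ²)` sit within 10% of `a0 = 0.1` and `s0 = 0.3`.
5. **Learning.** Hebbian covariance rule
   `W̃_ij = W_ij + ε(Ψ_i r_j − Ψ̄_i r̄_j)` with `ε = 0.002`, where the bars
   are exponential running means with factor `η = 0.05`; every row is then
   rescaled to unit L2 norm. Weights start uniform(0, 1), row-normalized.

Collateral weights are fixed at construction (no recurrent plasticity):
each unit is assigned an auxiliary field among the place centers, and
`Wc_ik = [f_θi(ω_ik) f_θk(ω_ik) exp(−d²_ki / 2σ_f²) − κ]_+` with
`σ_f = 0.2 L`, `κ = 0.05`, `ω_ik` the direction from field k to field i,
and `d_ki` the distance between field i and field k displaced by
`l = vτ` along `ω_ik`. Rows are L2-normalized and the diagonal is zero.

### Numerical decisions in the dynamics

- The iteration cap for the gain/threshold loop is 100 per step. When the
  cap is hit, the emitted rates come from the iterate with the smallest
  relative band violation, but (g, μ) continue from the *last* iterate:
  early in a run, when the population is still silent or ill-scaled, the
  control loop needs a few thousand cumulative iterations, and carrying the
  last iterate across warm-started steps lets that progress accumulate.
  Cap-outs are counted per checkpoint interval and drop to ~zero after the
  initial transient.
- On a fully silent population the sparsity term is held neutral
  (`s := s0`) so only the threshold moves (downward, via the activity
  term); otherwise the gain update would push g in an arbitrary direction.
- The input at step t uses the weights *before* that step's Hebbian
  update; adaptation at step t consumes the input of step t − 1; the delay
  line is zero-filled for t < τ.
- The per-step loop (trajectory, place rates, dynamics, learning, map
  accumulation) is compiled with numba. All randomness is pre-drawn from a
  single `numpy` Generator in a fixed order (one normal and one uniform
  per step for the heading), which makes runs bit-reproducible and lets
  the compiled kernel be checked draw for draw against the pure-numpy
  per-operation functions (`simulator.run_python`). The two paths agree to
  1e-12 over short horizons; beyond that, ~1e-16 summation-order
  differences get amplified by the discrete iteration count of the gain
  loop (the comparison is then statistical, not bitwise).

## Rate maps and analysis

Rate maps are occupancy-normalized sums of Ψ on a voxel grid (default
25×25×25 at the reduced scale; unvisited voxels are missing values and are
excluded from all correlations). Between checkpoints the accumulator is
reset, so each checkpoint map reflects its own interval.

The 3D autocorrelogram is the Pearson correlation of the map with itself at
every voxel displacement, computed over the overlapping valid voxels only
(FFT-based); displacements with less than 5% overlap, or with a
near-constant overlap (variance floor), are masked. Grid spacing `d` is the
first peak of the radially averaged autocorrelation beyond the central
peak, with a quadratic sub-bin refinement and a minimum peak correlation of
0.05 to reject structureless maps.

**Best plane and hexagonality.** Central slices are parameterized by the
azimuth/elevation of their normal on a 5° grid with a 1° refinement pass;
slice values are interpolated trilinearly on a polar annulus spanning
0.5–1.4 d around the first-peak ring. The hexagonality of a slice is its
π/3 rotational symmetry: `min(ρ(60°), ρ(120°)) − max(ρ(30°), ρ(90°),
ρ(150°), 0)`, where ρ is the Pearson correlation of the annulus with
itself rotated in-plane. A perfect hexagonal ring scores 1; measured null
maps (smoothed noise, voxel-shuffled) score below ~0.55 even after
maximizing over ~1300 candidate normals. A plain six-peak-template
correlation was rejected: smooth null profiles correlate above 0.8 with a
smooth template once the rotation and the normal are both maximized over.
The hexagon axis (used for population alignment) is the best rotation of a
six-peak von-Mises template against the ring profile.

**FCC/HCP long-range order.** In a close packing the secondary hexagonal
planes lie at arccos(1/3) ≈ 70.5° from the basal plane (the paper-style
"~72°"); a triplet separated by 120° of azimuth about the best normal is
mutually at ~70.5°, and the complementary triplet (offset 60°) is at ~56°
from the first. ζ_{2−4} is the best triplet sum of slice scores over a
±8° polar band around 70.5° (2° azimuth steps); ζ_{5−7} is the
complementary triplet at the winning geometry. For these tilted slices a
2π/3 (not π/3) rotational-symmetry score is used, because the secondary
planes of an HCP arrangement carry hexagonally arranged peaks of
*alternating* full/half height — a strict 6-fold criterion would punish
them — and negative slice scores are clipped to 0 before summation so that
χ_FCC = (ζ_{2−4} − ζ_{5−7})/ζ_{2−4} stays on its intended [0, 1] scale.
On ideal fixtures: FCC gives χ_FCC = 1.0, HCP gives χ_FCC ≈ 0.12.

The interlayer distance λ_z is the median normal component of the
first-shell autocorrelogram peaks (fallback: √(2/3) d from close-packing
geometry). It is *not* taken from the first autocorrelation peak along the
normal itself: for an ABC (FCC) stacking the first peak on that axis sits
at three interlayer distances, which would make the two-layer correlation
χ_HCP = C(2λ_z n̂) unity for FCC and destroy the score's discriminative
power. With the geometric λ_z, ideal HCP gives χ_HCP ≈ 0.95 and ideal FCC
≈ −0.13.

**Local (triplet) gridness.** Spikes are drawn from a rate map by a
Poisson-style sampler (voxel probability ∝ rate, uniform jitter within the
voxel). The pairwise-distance histogram is divided by that of
equally many uniform points (a g(r)-style correction that removes the r²
growth); the second peak is the grid distance d, and the window around it
(surrounding troughs, clamped to [0.5 d, 1.4 d]) defines neighboring
fields. Internal angles of all spike triplets with all three sides in the
window are pooled and compared, bin by bin (3° bins), against the same
construction on control spikes (uniform by default, or spikes reshuffled
across units). The characteristic angle is the data-weighted median over
above-unity ratio bins; the significance is the maximum ratio.

**Empirical cost.** For a measured map, the kinetic term H_K is the mean
squared discrete gradient; the adaptation term H_A is the mean of
ψ·(K*ψ) with K a difference of normalized Gaussians (widths vτ_L and
vτ_S = vτ_L/3, inhibition ρ = 0.03), truncated at 4 sd with no wraparound.
The kernel width for empirical maps is a user choice; a natural default is
the distance covered in one slow-adaptation time constant,
`v dt / b2 = 0.012 L … 0.12 L` depending on the reading — the analytic
treatment uses vτ_L = 1 in units where the adaptation length is 1.

## The variational model

Asymptotic field arrangements are modeled as plane-wave constructions:
FCC as `ψ_n = p_n (1 + ¼ Σ_{i=1..4} cos(k_i·r))^n` with the four wave
vectors along tetrahedral axes (|k_i|² = (3/2)(2π/a)²), and HCP as a
vertical envelope (wave number k_z, |k_z|² = (3/8)(2π/a)² at the perfect
ratio k_z/k_xy = 3/√32 ≈ 0.53) times planar hexagonal layers
(|k_xy|² = (4/3)(2π/a)²), plus the same pattern shifted by the
hexagon-centroid offset (a/√3, 0) in-plane and in vertical antiphase
(ABAB stacking). p_n enforces a unit mean, computed numerically.

Both cost terms are evaluated *exactly* by expanding ψ_n in Fourier modes:
ψ_n is a finite trigonometric polynomial in the three generating wave
vectors, so an FFT over one periodic unit cell in lattice coordinates
(grid 4n+4 per axis) recovers the coefficients to machine precision. Then
`H_K = Σ_q |c_q|² |q|²` and `H_A = Σ_{q≠0} |c_q|² K̃(|q|)` with
`K̃(k) = exp(−½(k vτ_L)²) − ρ exp(−½(k vτ_S)²)`. The q = 0 mode contributes
the spacing-independent constant (1 − ρ) to H_A and is excluded by
default, matching the closed-form n = 2 expressions. The coefficients
depend only on (kind, n) — never on the spacing or on k_z — so optimizing
`H = H_K + γ H_A` over a (FCC) or jointly over (a, k_z/k_xy) (HCP, with
the B-layer envelope kept in antiphase for any k_z) costs microseconds per
evaluation: a coarse log-spaced grid plus bounded local refinement
(Nelder–Mead for the 2D case). At k_z = 0 modes that differ only in their
k_z multiplicity formally coalesce; the optimizer treats the boundary as
the limit k_z → 0⁺ (incoherent mode powers), which is the columnar
solution the n = 1 optimization selects for every γ.

An independent check of this machinery: the n = 2 FCC kinetic term is a
rational multiple of k². The Fourier expansion and a Monte-Carlo
central-difference quadrature over the unit cell agree on 73/162 · k²
(the test suite asserts the dual-route agreement). Note that the three
sum modes k_i + k_j coincide pairwise with −(k_k + k_l) because the four
tetrahedral wave vectors sum to zero, so their amplitudes add coherently;
an incoherent count would give 71/162 instead, and correspondingly
undercount one adaptation-term coefficient by a factor 2.

**Relaxation-curve fitting.** The two cost-term timecourses are fit
jointly (`least_squares`, residuals scaled by each series' range,
time constants log-parameterized, three starts at different time-scale
guesses) to `H_K(t) = A e^{−t/τS} + B e^{−t/τL} + K` and
`H_A(t) = C e^{−t/τS} − D e^{−t/τM} + E` with a shared τS. The weighting
γ* is then the largest γ keeping `H_K + γ H_A` non-increasing on the
fitted curves (computed from the fitted derivatives on a dense grid; +∞
when H_A never rises, e.g. for constant series). Parameter recovery on
synthetic curves with 1% noise is within 10%.

## Synthetic fixtures and what passing tests show

`fixtures.make_fixture` voxelizes the analytic constructions (default
spacing 0.3 L, 48³ voxels, power n = 4) and two nulls (rectified smoothed
Gaussian noise; a voxel-shuffled FCC map). These fixtures are ideal:
noise-free, unmasked, perfectly stationary. Passing the fixture-based
score tests shows the *measures* are correct and calibrated; it does not
show that simulated (or biological) maps are crystalline — the simulation
tests address the dynamics separately, and at full scale the model's own
claim is that FCC/HCP order remains mixed. Fixture spacing 0.3 L (rather
than the simulation's ~0.5 L) keeps several lattice periods in the box;
with fewer periods, the box boundary breaks the equivalence of the six
tilted HCP planes measurably.

## Problem sizes

Simulation-based tests and the acceptance script use the reduced scale:
27 output units, 8³ place inputs, 25³ map voxels, 1 M steps in the test
suite and 4 M steps (the spacing-stabilization horizon) in the acceptance
script, all other parameters at their standard values. The full-scale
configuration (125 units, 12³ inputs, tens of millions of steps) is the
package default for `SimConfig` and runs unchanged, just longer.

## Known limitations

- The 3D application of the scalar turn-angle distribution (axis–angle
  about a random perpendicular axis) is one of several isotropic readings.
- Map binning, smoothing and occupancy treatment for the analysis are
  package choices (25³ voxels, 1-voxel Gaussian smoothing before peak
  detection, 0.2 correlation threshold for peaks).
- χ_FCC is undefined (reported missing) when ζ_{2−4} ≤ 0, and is noisy
  for weakly ordered maps; on pure-noise maps its distribution is wide and
  biased high because ζ_{5−7} is clipped at 0.
- Collateral weights are fixed; recurrent plasticity is out of scope. At
  the reduced scale the collateral drive measurably increases the converged
  spacing (~0.53 L with versus ~0.41 L without, 27 units); fields form
  either way, but spacing-sensitive comparisons should hold the collateral
  configuration fixed.
- The gain-control loop can transiently overshoot g by orders of magnitude
  during the initial silent phase; it recovers within a few steps and
  does not affect converged statistics, but exact early-time trajectories
  are sensitive to floating-point summation order.
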