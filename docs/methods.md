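# Methods

## The estimation problem

A diffusion MRI voxel in white matter contains on the order of 10⁵ axon
segments whose orientations follow some unknown antipodally symmetric
density p(ω) on the sphere (the fiber orientation distribution, FOD).
The measured signal fraction at weighting b and gradient direction g is
the spherical convolution

    e_b(g) = ∫_{S²} h_b(⟨g, ω⟩) p(ω) dω,

where h_b is the impulse response of a single segment plus its immediate
neighborhood. Any voxel-scale quantity estimated directly from e_b —
e.g. tensor FA — mixes microstructure (h_b) with orientation architecture
(p). The spherical mean technique exploits the fact that the direction
average of e_b equals the direction average of h_b alone: averaging over
g makes the FOD integrate out exactly, for every p. The per-shell sample
mean of the measured directions is therefore a sufficient statistic for
the microscopic response, and microstructure can be estimated without
modelling — or even acknowledging — fiber dispersion and crossing.

## Response model

The impulse response is an axially symmetric Gaussian (second-order)
micro-tensor,

    h_b(c) = exp(−b c² λ∥ − b (1 − c²) λ⊥),  c = ⟨g, ω⟩,

with effective diffusivities λ∥ ≥ λ⊥ in μm²/ms. Its powder average is

    ē_b(λ∥, λ⊥) = exp(−b λ⊥) ₁F₁(1/2; 3/2; −b(λ∥ − λ⊥)),

evaluated through the equivalent erf form; for b(λ∥ − λ⊥) < 10⁻⁶ the
code switches to the hypergeometric series 1 − x/3 + x²/10 − x³/42 to
avoid the 0/0 of erf(√x)/√x (`response.spherical_mean_model`). A
Gauss–Legendre quadrature of the defining 1-D integral
(`spherical_mean_quadrature`) serves as an independent oracle; the two
agree to ~1e-15 across the physical parameter range.

Physical constraints: 0 ≤ λ⊥ ≤ λ∥ ≤ λ_free with λ_free = 3.05 μm²/ms,
the bulk water diffusivity at 37 °C. `LAMBDA_FREE` is a module constant
and a per-fit argument (`lam_free`) so that e.g. ex-vivo data acquired at
room temperature can lower the bound.

Units: b-values are ms/μm² internally (1000 s/mm² = 1.0 ms/μm²), so all
model arguments are O(1); FSL bval files (s/mm²) are converted at the I/O
boundary.

## Constrained fit

`fit_smt` minimizes Σᵢ (ê_bᵢ − ē_bᵢ(λ∥, λ⊥))² over the triangle
0 ≤ λ⊥ ≤ λ∥ ≤ λ_free. At least two nonzero shells are required,
otherwise the problem is underdetermined. The solver is deterministic:

1. a 40×40 grid scan over the feasible triangle (vectorized closed-form
   evaluations) locates the global basin;
2. bounded local least squares (`scipy.optimize.least_squares`, trf,
   tolerances 1e-15) refines it in the reparameterization
   (u, v) → (λ⊥, λ∥) = (u, u + v(1 − u/λ_free)), which maps the box
   [0, λ_free]² onto the triangle and enforces the ordering by
   construction;
3. the local stage is multistarted from the three best grid cells, each
   nudged 1e-3·λ_free into the interior — a start sitting exactly on a
   box face can stall the trust-region step along the degenerate
   direction.

Noiseless round trips recover interior parameters to better than 1e-8;
active constraints are reported as `at_bound` flags (perpendicular
diffusivity at zero, equal diffusivities, free-water bound) rather than
NaN, so downstream maps stay numeric. Voxels whose shell means all
equal or exceed 1 (pure noise) fit to the flagged origin (0, 0).

Derived metrics: per-axon MD = (λ∥ + 2λ⊥)/3; per-axon FA from the
axially symmetric tensor formula, defined as 0 at (0, 0); anisotropy
index λ∥/λ⊥ with an explicit `inf` sentinel at λ⊥ = 0 (and 1 at the
0/0 corner) — background and CSF voxels must not crash map generation.

## Rician noise model

Magnitude MR signals with complex Gaussian noise follow the Rician law;
its mean √(πς²/2)·L₁⁄₂(−E²/2ς²) exceeds the true signal E, most severely
near the noise floor. The bias adjustment inverts the mean function at
the measurement: since the mean is strictly increasing in E, the
least-squares projection reduces to monotone root-finding, implemented as
a vectorized bisection on [0, S + 5ς] (~1e-12 accuracy in ≤ 100
halvings); measurements at or below the floor ς√(π/2) map to 0. All
Bessel-function expressions use the exponentially scaled i0e/i1e so the
high-SNR regime cannot overflow.

The noise level is estimated from the repeated b=0 images: per voxel, a
joint (E, ς) maximum-likelihood fit (Nelder–Mead from Rayleigh-corrected
moment starts), summarized by the median of the voxelwise ς̂ — robust to
occasional non-convergence and spatial variation. Voxels with identical
repeats (ς → 0 boundary) are skipped with a warning. With 10 repeats the
ML estimate carries the expected O(1/n) downward bias (~5–10%); the
median over voxels does not remove it. Adjusted signals are computed
before normalization, and the normalizing b=0 mean is itself
bias-adjusted.

In `fit_volume`, voxels whose adjusted mean b=0 signal does not exceed
3ς are flagged as background and excluded; normalized signal fractions
are clamped to [0, 1] before averaging (the adjustment can overshoot 1
in noise).

## Simulation framework

Random FODs are drawn from a Dirichlet-process mixture of bipolar Watson
densities in the stick-breaking representation: weights
πᵢ = Xᵢ Π_{j<i}(1 − Xⱼ) with Xᵢ ~ Beta(1, α), axes uniform on S², and
concentrations κᵢ ~ InverseGamma(ακ, βκ). Defaults α = 1.5, ακ = 4.71,
βκ = 57.1 place the prior mode at κ = 10 with P[κ ≤ 50] = 0.99 — spanning
realistic axon dispersion, from nearly isotropic fanning to coherent
bundles, with crossings arising naturally from multiple components.
Stick-breaking is truncated once the drawn components carry ≥ 1 − 1e-4 of
the mass; the tail is folded back proportionally (renormalization), so
every FOD is an exact probability density. The simulator never samples
axon orientations: synthesis evaluates the convolution integral against
the density.

Watson densities are evaluated in log space via Dawson's function
(₁F₁(1/2; 3/2; κ) = e^κ D(√κ)/√κ), stable to κ ~ 10⁵.

**Convolution quadrature.** The spherical convolution is computed on a
product grid: Gauss–Legendre in the polar cosine × uniform in azimuth,
with analytic weights. The polar order adapts to the sharpest mixture
component (band limit ≈ 8.5√κ_max), giving FOD mass errors below 1e-9
for any peak orientation. An equal-weight antipodal Fibonacci lattice
was evaluated first and rejected: its error for randomly oriented Watson
peaks at κ ~ 20–50 reaches 1e-4…7e-3 at 4096 nodes, and — worse — depends
on how the peak aligns with the lattice. `fibonacci_sphere` is retained
for generating dense direction sets. Synthesis verifies ∫p dω = 1 to
1e-3 on the actual grid and raises a simulation error otherwise.

**Gradient schemes.** Shell directions are spread by electrostatic
(Coulomb) repulsion of antipodal point pairs — projected gradient descent
with backtracking from a seeded random start. The 76-direction shell's
minimum pairwise angle is ~16°, versus ≤ 4° for random schemes. b=0
measurements are interleaved evenly across the acquisition. Prefix
subsets of a shell are approximately uniform (the optimized points keep
their random ordering) but are not hierarchically optimal; the
reduced-acquisition robustness results should be read with that in mind.

**Monte-Carlo harness.** `monte_carlo_experiment` shares each trial's
FOD and noiseless synthesis across all configurations (common random
numbers), then applies independent Rician corruptions per configuration:
an SNR sweep at the full protocol and a direction-count sweep (prefix
subsets) at the protocol SNR 17.5. Noise seeds derive from
(root seed, sweep tag, trial, config), so every cell is independently
reproducible. Default study conditions: truth (λ∥, λ⊥) = (2.5, 0.1)
μm²/ms, shells b = 1.0/2.5 ms/μm² with 76/75 directions and 10 b=0
images, SNR 17.5 — with 500 trials the protocol medians land within
~0.15% (shell means), ~1% (λ∥) and ~4% (λ⊥) of the truth.

## What the simulations do and do not show

The generator emulates orientation dispersion and crossing faithfully
(any square-integrable antipodal density is a weak limit of the mixture
family) and the Rician noise regime of SENSE1-combined magnitude data.
It does not emulate: spatially varying noise levels or noise correlation
introduced by preprocessing resampling; non-central chi statistics of
sum-of-squares multi-coil combination; partial-volume mixtures of
distinct microscopic compartments within a voxel (every simulated voxel
has a single (λ∥, λ⊥)); gradient-nonlinearity b-value variation;
time-dependent diffusion or exchange. Passing tests therefore certify
the estimator's behavior under the stated noise and orientation
conditions, not under arbitrary scanner physics.

## Numerical conventions

- float64 in memory, float32 on disk (NIfTI); maps keep the input grid
  and affine, out-of-mask voxels are NaN.
- b < 0.05 ms/μm² (50 s/mm²) counts as b=0; nonzero b-values are grouped
  into shells by greedy clustering with a 10% relative tolerance, and the
  shell's b is the member average.
- bvecs are taken in the image frame as given; the model's antipodal
  symmetry makes sign flips irrelevant. A 3×3 bvec table is read with the
  FSL row convention (rows = x, y, z components).
- All randomness flows through explicit seeds / `numpy.random.SeedSequence`;
  there is no global RNG state.

## Known limitations

- Single-compartment response: no free-water elimination, no kurtosis;
  CSF-contaminated voxels bias toward higher λ⊥.
- λ∥, λ⊥ are *effective* diffusivities for the given sequence timing;
  different gradient waveforms with the same b yield different values.
- The noise-level ML estimate from few repeats is biased low by several
  percent; at SNR ≳ 15 the effect on the diffusivity maps is small.
- FOD recovery (spherical deconvolution with the fitted response) is out
  of scope here, as are preprocessing (distortion/motion correction) and
  tissue segmentation.
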