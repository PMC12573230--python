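# Methods

## Model

A peak-picked IMS data set is a matrix `A ∈ R^{m×n}` (m pixels × n m/z
peaks, m ≫ n) modelled as `A = B + C + D` with `B = Y Zᵀ` of rank
r ≪ min(m, n). The column space of B carries spatial patterns (each
basis vector refolds to an image), its row space carries spectral
patterns. C collects variation confined to few entries — spatially
small, high-intensity tissue substructures or isolated peaks — and D
collects small-magnitude entry-wise variation (noise). PCA forces all
non-low-rank variation into D; PCP forces it all into C; SPCP splits it
between C and a dense residual bounded by a noise ball.

## Solvers

**PCA** is a truncated SVD (LAPACK `gesdd` for ordinary sizes, seeded
randomized SVD with oversampling 10 and 2 power iterations above a
5,000×5,000 work size). The Eckart–Young identity — reconstruction error
equals the tail singular-value energy — is used as its test oracle.

**PCP** (`min ‖B‖* + λ‖C‖₁ s.t. A = B + C`) uses the inexact augmented
Lagrangian method: alternating singular-value thresholding (B-step,
threshold 1/μ) and soft thresholding (C-step, threshold λ/μ), dual
ascent `Y += μ(A − B − C)`, and geometric penalty growth `μ ← ρμ` with
ρ = 1.5 and `μ₀ = 1.25/‖A‖₂` (capped at 10⁷·μ₀). The dual is
initialised to `A / max(‖A‖₂, ‖A‖∞/λ)`. Because μ₀ scales with 1/‖A‖₂,
the iteration is exactly equivariant under `A ← cA`, which the
homogeneity test exploits. Stopping: relative feasibility
`‖A − B − C‖_F/‖A‖_F ≤ tol` (default 10⁻⁷) or `max_iter` (default 1000;
hitting it sets `converged=False` without raising).

**SPCP** (`min ‖B‖* + θ‖C‖₁ s.t. ‖A − B − C‖_F ≤ δ`) uses the same
splitting with a third block: an auxiliary dense-residual variable
updated by projecting `A − B − C + Y/μ` onto the Frobenius ball of
radius δ. At δ = 0 the projection returns zero and the scheme coincides
with PCP step for step — the reduction test checks this within 10⁻⁴.
Stopping adds a relative term-change criterion (≤ max(tol, 10⁻⁶)) to
constraint satisfaction. On exit D is *defined* as `A − B − C`, so the
conservation identity holds exactly; at convergence
`‖D‖_F ≤ δ(1 + 10⁻⁶)`. When `δ ≥ ‖A‖_F` the zero decomposition is
feasible with objective 0 and is returned directly. The alternative
Lagrangian formulation (penalty bisected until the residual meets δ)
was considered but not implemented: the ball projection handles the
constraint directly and reduces to PCP cleanly at δ = 0.

Numerical conventions: a singular value exactly equal to the SVT
threshold is set to zero (strict inequality retains); the reported rank
counts singular values above `rank_threshold · S₁` (default 10⁻⁶); the
largest-magnitude entry of each left singular vector is made positive so
factor output is deterministic; an all-zero input returns zero terms,
rank 0, converged after 0 iterations. Exact-SVD runs are bit-reproducible
across reruns; randomized-SVD runs are reproducible given the seed.

## Parameter multipliers

Useful regularisation values scale with the matrix size, so sweeps use
dimension-free multipliers: `λ = λmult/√max(m,n)` and
`θ = θmult/√max(m,n)`. The SPCP ball radius comes from a σ-multiplier
via `δ = √(d + √(8d)) · σmult · ‖A‖_F`, d = min(m, n): this is the
standard stable-PCP radius containing i.i.d. noise of per-entry level σ
with high probability, with σ expressed as a fraction of ‖A‖_F. The
printed source for this relation was typographically damaged, so the
formula is adopted here as a documented convention; any other δ(σ)
mapping can be passed by computing δ directly. Default sweep grids:
PCA ranks 1..min(m,n); 2000 linearly spaced λ-multipliers on [0.05, 3]
(chosen so a sweep represents almost every achievable rank — rank grows
near-monotonically with λ because a larger λ drives C toward zero);
100 linearly spaced θ-multipliers on [0.4, 2.0] × 100 log-spaced
σ-multipliers on [10⁻⁴, 10⁻¹], 10⁴ SPCP pairs.

## Comparison metrics

*Subspace overlap* between two orthonormal bases is the mean of the
singular values of `U₁ᵀU₂` (the cosines of the principal angles):
1 for identical spans, 0 for orthogonal spans, 1/√2 for planar bases at
45°. Values are clipped to [0, 1] before averaging to absorb rounding.
Cross-method comparisons default to *matched* rank (both bases truncated
to the common leading rank) so terms of similar rank are compared; a
*native* mode compares full retrieved bases. *Negativity statistics*
(percentage, sum, mean of negative entries) quantify how far a low-rank
term strays from the non-negativity of real ion counts. Per-term
energies (squared Frobenius norms) and entry-wise intensity histograms
(default 201 bins over a shared symmetric range ±max|entry| across
terms, or restricted to one m/z column) support residual analysis and
denoising decisions.

## TIC normalization

"Trimmed TIC" divides each spectrum by the sum of its nonzero
intensities lying within the [lower, upper] percentile band (linear
interpolation percentiles, ends inclusive; defaults 5–95). The band
[0, 100] recovers classic TIC (row sums to 1). The exact trimming recipe
is not standardised across IMS software; this definition is the
package's documented dialect and is deliberately easy to substitute.
Rows whose band sum is zero are left unchanged and reported in the
output metadata.

## Synthetic data

`gen_lowrank_sparse` builds theory-side instances
`A = L0 + S0 + N0`: `L0 = |G1|·|G2|ᵀ` with standard-normal factors —
absolute value applied to the *factors* keeps the rank exactly r while
making L0 non-negative like ion counts (entry-wise |·| of a product
would destroy the rank); `S0` places ±amp (default 5) on a uniformly
random support of exactly `round(sparsity·m·n)` cells; `N0` is i.i.d.
Gaussian, left signed so the additive model stays exact for theory
tests.

`gen_synthetic_ims` emulates the structure the method assumes in
tissue: smooth horizontal "anatomical layer" bands (logistic edge
profiles) times half-normal spectral loadings give a non-negative
matrix of rank ≤ n_layers; small high-intensity blobs (≤ 9 pixels,
active in 1–3 peaks, amplitude 5 ≈ 5× the layer scale — sparse tissue
substructures are characteristically bright relative to the background
layers) form the sparse part; Gaussian noise (default σ = 0.01) is
added and the measurement clipped at zero, with the clipped energy
recorded and folded into N0 so `A = L0 + S0 + N0` remains exact.
Defaults: 64×64 pixels, 100 peaks, 4 layers, 10 blobs.

What the generator does *not* emulate: isotope patterns, peak shapes,
mass-axis drift, pixel-to-pixel TIC variation, spatially correlated
noise, or the 10⁵-pixel scale of real tissue sections. Passing tests
therefore demonstrate correctness of the decomposition machinery and
the qualitative separation mechanism, not performance on real MALDI
data; test problem sizes (up to 200×200 theory instances and the
64×64×100 cube) were chosen as the smallest sizes at which the planted
structure is in the reliable recovery regime of the convex programs.

## Sweeps and pipeline

Grid points are independent; sweep rows are keyed by grid index so
output order is canonical under any scheduling. With a CSV path given,
rows are appended after each fit and previously completed points are
skipped on restart; resumed CSV rows are parsed with round-trip float
precision so an interrupted-then-resumed sweep is bit-identical to an
uninterrupted one (runtime columns aside). A fit failure is recorded in
the row's `error` column and never aborts the sweep. `denoise` returns
B or B + C as an IMSMatrix (D always dropped); keeping C is
application-specific because C carries real small structures as well as
outliers. `image_quartet` refolds the A/B/C/D columns of one m/z bin
into four ion images, with absent terms rendered as zero images.

## Known limitations

* The inexact ALM/ADMM schemes solve the convex programs to the
  feasibility tolerance, not to certified duality gaps; extremely
  ill-conditioned inputs may stop at `converged=False`.
* Randomized-SVD determinism is per-seed, not bit-identical to the
  exact-SVD path.
* imzML reading loads spectra eagerly; very large files should be
  converted to the HDF5 container once and memory-mapped downstream.
* The δ(σ-multiplier) convention and the trimmed-TIC dialect are
  documented choices, not community standards.
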