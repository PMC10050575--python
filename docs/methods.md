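# Methods

## Model and estimation pipeline

The package treats a multichannel electrophysiological recording as a
second-order stationary vector time series.  Non-overlapping (or
overlapping) segments of odd length `2T + 1` are transformed with a
centered discrete Fourier transform,

    x(f) = Σ_{t=-T..T} x(t) exp(-i 2π (f Δν)(t Δς)),   Δν = 1/((2T+1) Δς),

and the sensor cross-spectrum is the segment average
`Σ̄ᵥᵥ(f) = (1/M) Σ_m v_m(f) v_m(f)ᴴ`.  For stationary, strongly mixing
series the Fourier coefficients are asymptotically independent circularly
symmetric complex Gaussian vectors, and `M Σ̄` is complex Wishart with `M`
degrees of freedom and scale equal to the true cross-spectrum.  Both
densities are implemented (`complex_gaussian_logdensity`,
`complex_wishart_loglik`); the Wishart log-density keeps exactly the terms
that depend on the scale matrix — the normalization constant, which
depends only on the sample matrix, M, and R, is dropped because it never
affects estimation of the scale.  No taper is applied before the DFT by
default (a Hann taper is available behind a flag); multitaper/Welch
variants are out of scope.

The forward model is linear and frequency-flat:
`Σᵥᵥ(f) = L Σᵢᵢ(f) Lᵀ + Σ_ξξ(f)` with a real lead field `L` (E × G,
E ≪ G).  All inverse solvers are quasilinear: they return a real matrix
`T` applied as `Σ̂ᵢᵢ = T Σ̄ᵥᵥ Tᵀ`, which keeps the estimate Hermitian PSD
and preserves the Gaussian/Wishart sampling structure (F-invariance).

## Gaussianity test

Per frequency and channel, the real and imaginary parts of the Fourier
coefficients across segments are each tested with Shapiro–Wilk;
Benjamini–Hochberg controls the false discovery rate across all
channels × frequencies × parts.  Numerically constant coefficients (e.g.
the imaginary part at 0 Hz) are flagged degenerate and excluded.  The
result reports both the corrected rejection fraction and the uncorrected
per-test fraction; only the latter is expected to sit at the nominal
level under the Gaussian null (the corrected fraction is near zero at the
global null by construction of FDR control).  Any calibrated univariate
normality test would serve; Shapiro–Wilk was chosen for its power at the
segment counts used here (M ≥ 20 enforced).

## Solvers

**sMNE / seLORETA (MAP with a Gaussian prior).**  The operator is the
constrained generalized inverse `T = Π Lᵀ B⁻¹`,
`Π = (Lᵀ B⁻¹ L + α A⁻¹)⁻¹`, evaluated through the dual (Woodbury) form
`T = A Lᵀ (L A Lᵀ + α B)⁻¹` when G > E.  sMNE uses A = I.  seLORETA
computes diagonal weights from the fixed point
`w_g = sqrt(l_gᵀ (L diag(w)⁻¹ Lᵀ + α B)⁺ l_g)` — damped iteration
(damping 0.5), pseudo-inverse by eigendecomposition with relative cutoff
1e-12 — and uses A = diag(w)⁻¹.  The damped iteration stalls at a
residual floor of roughly the condition number times machine epsilon, so
tolerances should be chosen accordingly when α is extremely small.

**sLCMV.**  Row g of T is the unit-gain minimum-variance filter
`w_gᵀ = (l_gᵀ C⁻¹ l_g)⁻¹ l_gᵀ C⁻¹` with `C = Re(Σ̄ᵥᵥ) + λI` and default
diagonal loading `λ = 1e-3 · trace(Σ̄ᵥᵥ)/E`.  The real part is used so the
operator stays real (and the estimated source cross-spectrum Hermitian);
for the real-valued ground-truth spectra of the synthetic benchmark this
loses nothing, and for complex data it discards only the imaginary
(lag-quadrature) part of the sensor covariance.

**ssSBL (gamma-MAP).**  Per frequency, an EM loop over per-source
variances γ (the variational spectrum) and a fixed (optionally updated)
diagonal noise spectrum β:

1. E-step: `Π = (Lᵀ diag(β)⁻¹ L + diag(γ)⁻¹)⁻¹`, `T = Π Lᵀ diag(β)⁻¹`
   (computed in the E × E dual form), posterior second moments
   `m2_g = [T Σ̄ᵥᵥ Tᵀ]_{gg} + Π_{gg}`.
2. M-step: γ_g maximizes `Q(γ) = −M log γ − M m2/γ − α₁√γ − α₂γ` over
   γ ≥ 0.  The stationarity condition multiplied by γ² is strictly
   decreasing with a unique root in [0, m2]; it is found by 100 steps of
   vectorized bisection (relative precision 2⁻¹⁰⁰, deterministic).

Because the M-step maximizes the exact expected log-joint plus the
hyper-penalty, the penalized evidence
`−M log|Σᵥ(γ)| − M tr(Σᵥ(γ)⁻¹ Σ̄ᵥᵥ) − α₁Σ√γ − α₂Σγ`,
`Σᵥ(γ) = L diag(γ) Lᵀ + diag(β)`, is non-decreasing across iterations;
the solver records it per iteration and tests assert monotonicity to
1e-8 relative.  At α₁ = α₂ = 0 the update is the classic SBL fixed point
γ ← m2 (verified against an independent EM implementation).

*Scaling.*  Before solving, the lead field is rescaled so
`trace(L Lᵀ)/E = 1` and each data matrix so `trace(Σ̄ᵥᵥ)/E = 1`; the
penalties α, α₁, α₂ are then dimensionless.  Defaults: α = 1e-2
(MAP1 temperature), α₁ = 1, α₂ = 1e-2.  Results (T, Π, γ, β, Σ̂ᵢᵢ) are
reported back on the original data scale.  γ is initialized uniform with
total source power matched to the scaled data trace; no random
initialization is used, and all argmax ties break to the lowest index.

*Noise spectrum.*  β defaults to the mean of the smallest quartile of
eigenvalues of the (scaled) real sensor cross-spectrum — a noise-floor
estimate — replicated across sensors; a scalar or vector `beta0` may be
supplied, and an EM residual update is available behind `noise_update`
(default off).

*Band pooling.*  The solver runs independently per frequency; passing a
band-averaged cross-spectrum gives band-pooled operators.  The EM
shrinkage of spurious γ on noise-only data has a slow tail: the default
`max_iter = 200` / `tol = 1e-6` is a pragmatic setting for benchmark
runs, while asymptotic statements (e.g. near-zero source energy on pure
noise) require running the loop to convergence (a few thousand
iterations on small problems).

## Distortion measures

With resolution operator `R = T L` and geodesic distances d (mm):

* GPSF: `r(g) = (1/|G₀|) Σ_{g₀∈G₀} |R(g, g₀)|²`;
* spatial dispersion: `θ²(g₀) = (1/G) Σ_g |R(g, g₀)| d²(g, g₀)` — the
  column **magnitude** (not squared) weighted by squared distance, as the
  measure is defined here; since this convention scales with operator
  gain, a per-column mass-normalized variant is available behind a flag;
* BLUR: the mean of θ² over the reference set; exactly 0 for R = I;
* EMD: both CSTs are divided by their sums (unit mass) and the optimal
  transport cost with geodesic ground distance is solved as a
  transportation LP (HiGHS), reported in mm; symmetric and a metric on
  normalized topographies (verified on random triples to LP tolerance);
* correlation distance: 1 − Pearson correlation of the raw band-averaged
  CSTs (a log-scale option exists);
* localization error: geodesic distance between CST argmax and the true
  vertex, ties to the lowest index.

The reference set is the most active 25 % (`ceil(0.25 G)` entries) of the
reference CST, ties to the lowest index.

## Synthetic benchmark: what it emulates, and what it does not

The generator emulates the statistical structure of cortical activity
seen by a low-density montage: a **dense, spatially smooth, incoherent
background** (diagonal source cross-spectrum, geodesic-Gaussian smoothed
positive field, flat across frequency) plus **sparse coherent patches** —
rank-1 terms `power · shape(f) · u uᵀ` with u a geodesic Gaussian bump
(default radius 15 mm) and shape a unit-peak Hann profile supported in
the patch's band.  Defaults: E = 19 sensors on a 100 mm scalp sphere,
G = 200 sources on an 80 mm cortical sphere (Fibonacci spiral vertices,
convex-hull triangulation, graph geodesics), M = 600 segments at 200 Hz
with 201-sample segments (Δν ≈ 1 Hz, band 1–45 Hz), three patches
(theta/alpha/beta) centered at fixed fractions (0.10, 0.225, 0.35) of the
vertex ordering so they lie under the sensor cap, background power 0.01
per source, and white sensor noise at 10 dB SNR (the noise variance is
derived from the mean sensor signal power unless given explicitly).  All
randomness flows through one seeded generator (default seed 20230315).

The head model is a current dipole in an infinite homogeneous medium with
average-referenced sensors and mesh-normal orientations.  It reproduces
the smoothness and severe ill-conditioning of real scalp lead fields
(condition number of L Lᵀ far above 10³ at E = 19, G = 200) but not
tissue-conductivity geometry, and the spherical mesh is not a cortical
anatomy.  Consequences worth knowing: sources near the cap apex are
heavily attenuated by the average reference, so peak localization of
individual patches can be off by one or two vertices (~20 mm vertex
spacing) even for a well-behaved solver; passing tests therefore
demonstrate relative solver behavior under a realistic ill-conditioning
regime, not absolute performance on real anatomy or realistic artifact
regimes (no eye blinks, line noise, or non-stationarity).

## Benchmark orchestration

`run_benchmark` builds the bundle, runs each requested solver on the
sampled sensor cross-spectrum, band-averages the estimated and true
source spectra (default delta [1,4), theta [4,8), alpha [8,12),
beta [12,30), gamma [30,45) Hz, closed-open, configurable), and scores
each band against the truth.  The MAP1 baselines receive the data-driven
regularization scale `α · trace(L Lᵀ)/E`.  GPSF/BLUR need one resolution
operator per band; for per-frequency solvers (sLCMV, ssSBL) the
arithmetic mean of T over the band's frequencies is used.  A failing
solver is recorded in the report with its error message; other methods
continue.  With a fixed seed the whole report is byte-identical across
runs.

## Numerical and design choices

* Hermitianity is enforced by symmetrization after every matrix sandwich
  product; validation tolerances are 1e-10 (relative) for Hermitianity
  and −1e-8·λ_max for the minimum eigenvalue.
* The transportation LP is restricted to the joint support of the two
  densities and drops one redundant marginal constraint.
* Geodesics are graph shortest paths along mesh edges (Dijkstra), not
  exact polyhedral geodesics — adequate at ~20 mm vertex spacing.
* Problem sizes in the test suite (40–200 sources, 60–600 segments,
  20 benchmark seeds) were chosen so the whole suite completes in
  minutes on a single core while keeping the default scenario at the
  full 19/200/600 study conditions.

## Known limitations

* The exact matrix-variate (Wishart-likelihood) MAP over the source
  cross-spectrum is not implemented; ssSBL is its variational/joint
  approximation.  Off-diagonal entry-wise penalties on connectivity are
  likewise out of scope.
* Sources are scalar (fixed, mesh-normal orientation); free-orientation
  3-vector sources are not supported.
* The beamformer discards the imaginary part of the sensor
  cross-spectrum when forming its covariance (see above).
* Real-data pipelines (artifact handling, realistic BEM/FEM head models,
  MEG forward physics) are out of scope; inputs are assumed clean and
  stationary.
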