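# cesi — cross-spectral electrophysiological source imaging

`cesi` estimates **source cross-spectral matrices** from multichannel
EEG/MEG-style sensor recordings.  Given segments of a stationary
multichannel signal, the package computes the sensor cross-spectrum
Σ̄ᵥᵥ(f) by segment averaging of discrete Fourier coefficients and inverts
the frequency-domain forward model

    Σᵥᵥ(f) = L Σᵢᵢ(f) Lᵀ + Σ_ξξ(f)

for the source cross-spectrum Σᵢᵢ(f), whose diagonal is the *cortical
spectral topography* (CST — the spatial map of source power per
frequency).  The problem is severely ill-conditioned (tens of sensors,
hundreds to thousands of sources), so the quality of the prior matters.

## What is inside

**Solvers.**  All estimators are *quasilinear*: a real matrix operator
`T` (sources × sensors) applied as `Σ̂ᵢᵢ = T Σ̄ᵥᵥ Tᵀ`, which preserves the
Gaussian/Wishart structure of spectral estimates.

* `smne_operator` — spectral minimum-norm estimate,
  `T = Π Lᵀ B⁻¹`, `Π = (Lᵀ B⁻¹ L + α A⁻¹)⁻¹`;
* `seloreta_operator` — spectral eLORETA (diagonal weights from the
  eLORETA fixed point; zero peak-localization error for a point source);
* `slcmv_operator` — spectral LCMV unit-gain minimum-variance beamformer;
* `sssbl_solve` — **spectral structured sparse Bayesian learning**: a
  gamma-MAP evidence-maximization loop over per-source variances γ(g, f)
  (the "variational spectrum") with an Elastic-Net hyper-penalty
  `α₁ Σ√γ + α₂ Σγ` that favors sparse-plus-smooth source spectra.  Each
  EM iteration forms the quasilinear operator
  `T = Π Lᵀ diag(β)⁻¹`, `Π = (Lᵀ diag(β)⁻¹ L + diag(γ)⁻¹)⁻¹`, takes the
  posterior second moments `m2_g = [T Σ̄ᵥᵥ Tᵀ]_{gg} + Π_{gg}`, and maximizes
  `Q(γ_g) = −M log γ_g − M·m2_g/γ_g − α₁√γ_g − α₂γ_g` per source.  The
  penalized evidence is non-decreasing across iterations, and at
  α₁ = α₂ = 0 the update reduces to the classic SBL fixed point γ ← m2.

**Distortion metrics.**  From the resolution operator `R = T L`:
the generalized point spread function `r(g) = mean_{g₀∈G₀} |R(g,g₀)|²`,
and BLUR `b = mean_{g₀∈G₀} (1/G) Σ_g |R(g,g₀)| d²(g,g₀)` with geodesic
distances d (mm).  Between two CSTs: the earth mover's distance on
unit-mass densities with geodesic ground cost (a transportation LP),
the correlation distance 1 − corr, and the peak localization error.
The reference set G₀ is the most active 25 % of the reference CST.

**Synthetic benchmark.**  `synthetic.build_benchmark` generates the whole
validation setup: a Fibonacci-sphere cortical mesh with graph geodesics, a
scalp montage, an infinite-homogeneous-medium dipole lead field
(average-referenced), a ground-truth source cross-spectrum (dense smooth
background + coherent band-limited patches), circularly symmetric complex
Gaussian Fourier instances, and the sampled sensor cross-spectrum.  The
default scenario uses 19 sensors, 200 sources, 600 segments, three
patches (theta/alpha/beta) and 10 dB SNR.

## Worked example

```python
from cesi import RunConfig, ScenarioSpec, run_benchmark

config = RunConfig(
    scenario=ScenarioSpec(seed=7),
    solvers=("sssbl", "seloreta", "slcmv", "smne"),
)
table = run_benchmark(config)
print(table.drop(columns="error").round(3).to_string(index=False))
```

prints (abridged to the alpha band):

```
  method  band  blur_mm2  emd_mm  corr_distance  localization_error_mm
   sssbl alpha    15.637  89.546          0.044                  0.000
seloreta alpha   233.242  24.044          0.460                  0.000
   slcmv alpha 73818.693  98.197          1.069                184.247
    smne alpha    44.646  45.602          0.526                 21.011
```

Reading the numbers: ssSBL concentrates the point-spread energy near the
true active patches (BLUR 16 mm² versus 233 mm² for seLORETA and ~7×10⁴
mm² for the beamformer), reconstructs the alpha-band topography almost
collinearly with the truth (correlation distance 0.04, i.e. corr ≈ 0.96),
and localizes the alpha patch exactly (0 mm peak error).  The smooth
baselines spread power broadly; the beamformer misplaces it by ~18 cm of
geodesic distance on this 80 mm sphere.

The same pipeline is scriptable from the shell:

```sh
cesi fixtures --out fixtures/            # materialize the benchmark
cesi solve --method sssbl --leadfield fixtures/leadfield.h5 \
     --cross-spectrum fixtures/sensor_cs.h5 --out sssbl.h5
cesi metrics --estimate est.h5 --truth truth.h5 --mesh fixtures/mesh.off
cesi benchmark --config run.toml
cesi gausstest --data ts.csv --sampling-rate 200 --segment-length 201
```

## Layout

```
src/cesi/spectral.py    segmentation, DFT, cross-spectra, densities, bands
src/cesi/forward.py     meshes, geodesics, toy lead fields, projection
src/cesi/solvers.py     sMNE / seLORETA / sLCMV / ssSBL
src/cesi/metrics.py     GPSF, BLUR, EMD, 1-CORR, localization error
src/cesi/synthetic.py   benchmark generators (meshes, spectra, instances)
src/cesi/benchmark.py   end-to-end multi-solver benchmark
src/cesi/io.py, cli.py  containers (OFF/CSV/HDF5) and the `cesi` CLI
docs/methods.md         model assumptions, parameter choices, limitations
```
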