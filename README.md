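# dsca — diffuse speckle contrast analysis

Deep-tissue blood flow can be sensed optically: coherent near-infrared light
multiply scattered by tissue forms a speckle pattern whose temporal
decorrelation rate tracks the motion of red blood cells. Diffuse speckle
contrast analysis (DSCA, also called SCOS/SVS) measures this with a camera
whose exposure `T` is longer than the speckle decorrelation time — faster
flow blurs the pattern and lowers the spatial speckle contrast
`κ = σ_I / ⟨I⟩` over an ensemble of pixels.

This package is a desk-scale, instrument-free implementation of the whole
chain for a photon-counting SPAD camera:

- **Forward model** — the normalized field autocorrelation `g1(ρ, τ)` of a
  point source on a semi-infinite dynamic turbid medium (extrapolated-
  boundary image-source solution of the correlation diffusion equation,
  Brownian scatterer dynamics `⟨Δr²(τ)⟩ = 6 α·Db τ`) and the
  exposure-integrated squared contrast

  `κ²(ρ, T) = (2β/T) ∫₀ᵀ (1 − τ/T) g1(ρ, τ)² dτ`

  where `β ≤ 1` is the coherence factor of the collection optics.
- **Sensor timing** — the register model of photon-counting acquisition:
  `exposure = TINT_TBIN_ITERATIONS × TBIN_CLK_PERIODS / f_clk`,
  `frame rate = 1 / (exposure + readout)`.
- **Synthetic frames** — gamma-Poisson photon-count stacks with a planted
  contrast (latent speckle intensity ~ Gamma with shape `M = 1/κ²`, counts
  ~ Poisson), per-pixel dark counts and a hot-pixel defect population;
  scenario generators for cuff occlusion (reactive hyperemia) and
  cognitive-task flow steps.
- **Contrast pipeline** — dark-offset subtraction, single-pass 3σ hot-pixel
  rejection, full-array ensemble contrast, shot-/dark-noise correction
  `κc² = (Var(Ic) − σ_D² − ⟨Ic⟩)/⟨Ic⟩²`, blood-flow index `BFi = 1/κc²`,
  baseline normalization (rBFi) and moving-average smoothing.
- **Signal analysis** — Welch power spectral density, SNR in dB,
  peak-envelope trend extraction and baseline-relative percent change.

Who it is for: anyone prototyping or validating DSCA/SCOS processing — the
synthetic generator provides ground truth that real instruments cannot, so
every pipeline stage is testable quantitatively.

## Worked example

```python
import numpy as np
from dsca import (OpticalProperties, FlowParams, SemiInfiniteGeometry,
                  speckle_contrast_sq, TimingConfig, exposure_time, frame_rate,
                  generate_speckle_frames, process_stack)

optics = OpticalProperties.typical_tissue()          # 785 nm, mua=0.01/mm, musp=1/mm, n=1.33
geom = SemiInfiniteGeometry.for_separation(20.0, optics)
flow = FlowParams(alpha_db=1e-6, beta=1.0)           # typical tissue flow index, mm^2/s

k2 = speckle_contrast_sq(optics, flow, geom, exposure=2e-3)
print(f"kappa^2(rho=20 mm, T=2 ms) = {k2:.5f}  ->  BFi = {1/k2:.1f}")

cfg = TimingConfig(tint_tbin_iterations=1024)
print(f"iterations=1024: exposure = {exposure_time(cfg)*1e3:.4f} ms, "
      f"frame rate = {frame_rate(cfg):.1f} fps")

stack = generate_speckle_frames(kappa_sq_target=0.25, mean_photons=10.0,
                                n_frames=200, seed=42)
series = process_stack(stack)
print(f"recovered kappa_c^2 = {series.kappa_c_sq.mean():.4f} "
      f"(target 0.25), kappa_m^2 = {series.kappa_m_sq.mean():.4f}")
```

prints

```
kappa^2(rho=20 mm, T=2 ms) = 0.01822  ->  BFi = 54.9
iterations=1024: exposure = 1.6384 ms, frame rate = 361.7 fps
recovered kappa_c^2 = 0.2502 (target 0.25), kappa_m^2 = 0.3501
```

Reading the numbers: at a 20 mm source–detector separation and 2 ms
exposure, tissue-like optics give a low contrast (κ² ≈ 0.018) because the
speckle decorrelates far faster than the exposure; its reciprocal is the
blood-flow index. The timing model converts the accumulation register to the
1.6384 ms exposure and 361.7 fps frame rate of that setting. On synthetic
10-photon frames the noise-corrected estimator recovers the planted κ² =
0.25 while the uncorrected κm² is inflated to ≈ 0.35 by shot noise
(1/⟨I⟩ = 0.1).

A CLI mirrors the chain: `dsca simulate`, `dsca timing`, `dsca process`,
`dsca analyze`, `dsca reproduce-table2`, `dsca reproduce-fig4` — see
`dsca --help`.

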