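# Methods

## Physical model

The package models deep-tissue blood-flow sensing by diffuse speckle
contrast. Coherent light at wavelength λ enters a homogeneous half-space of
tissue (absorption μa, reduced scattering μs′, refractive index n) and is
detected on the surface at separation ρ. The electric-field autocorrelation
obeys the correlation diffusion equation; for Brownian scatterer motion with
effective diffusion coefficient αDb (mean-square displacement
⟨Δr²(τ)⟩ = 6 αDb τ) the unnormalized solution in the extrapolated-boundary
image-source geometry is

    G1(ρ, τ) ∝ exp(−K(τ) r1)/r1 − exp(−K(τ) rb)/rb
    K(τ)     = sqrt(3 μa μs′ + 6 μs′² k0² αDb τ),   k0 = 2π n / λ

with r1 = sqrt(ρ² + z0²), rb = sqrt(ρ² + (z0 + 2 zb)²), z0 = 1/μs′ and
zb = (2/3)(1 + Reff)/((1 − Reff) μs′). The appendix of the source study that
states its Green's function is not available to us verbatim; the standard
semi-infinite form above is adopted, which is what the stated symbols imply.

A camera exposure of length T integrates the speckle field, giving a squared
spatial contrast (Siegert relation applied, so the integrand is g1², with
coherence factor β):

    κ²(ρ, T) = (2β/T) ∫₀ᵀ (1 − τ/T) g1(ρ, τ)² dτ.

Consequences used throughout: 0 < κ² ≤ β with equality as T → 0 or for a
static medium; κ² decreases monotonically in each of ρ, T and αDb; and
1/κ² is nearly affine in αDb over the physiological range at fixed ρ and T,
which is what justifies BFi = 1/κc² as a flow index.

### Effective reflection coefficient

Reff accounts for internal reflection at the tissue–air index mismatch. The
default evaluator is a degree-8 Chebyshev polynomial in n (domain [1, 1.6]),
fitted once against the unpolarized Fresnel-integral definition
Reff = (RΦ + Rj)/(2 − RΦ + Rj); the fit's maximum absolute error over the
domain is 4.1e-4, and the numerical integral itself is available as
`method="integral"` (and is used as the oracle in the tests, and the
fallback for n > 1.6). The widely quoted cubic-in-1/n polynomial from the
literature follows a different Reff convention and differs from this
definition by ~0.04, so it was not used.

### Quadrature

κ² is computed by adaptive Gauss–Kronrod quadrature on [0, T] with relative
tolerance 1e-10. For stiff kernels (g1 collapses at τ ≪ T, e.g. large ρ or
long T) the interval is first truncated by bisection at the lag where
g1² < 1e-14; the discarded tail is bounded by 1e-14·T. Non-convergence
raises rather than returning a degraded value. The integrator was verified
against the closed form for an exponential kernel g1 = exp(−τ/τc),
κ² = β(e^{−2x} − 1 + 2x)/(2x²) with x = T/τc, to better than 1e-9 relative
over x ∈ [0.01, 100].

## Sensor timing model

Photon-counting acquisition is parameterized by the clock frequency
(default 20 MHz), TBIN_CLK_PERIODS (minimum exposure unit, default 32
clock periods) and TINT_TBIN_ITERATIONS ∈ [1, 65535] (on-chip
accumulations): exposure = iterations × periods / f_clk. Frame readout is a
stored constant (1.1264 ms, global shutter) because no row-level readout
formula is available; frame rate = 1/(exposure + readout), displayed
half-up to one decimal as data sheets print it.

## Synthetic frame generator

The generator is a statistical digital twin of the acquisition, not an
optical simulation. Per pixel and frame it draws a latent integrated
intensity from Gamma(shape M = 1/κ²_target, mean = `mean_photons`) — the
classic fully-developed-speckle result for an exposure containing M
effective independent fluctuations — and a Poisson photon count around it.
The law of total variance gives Var(I) = ⟨I⟩ + ⟨I⟩²/M, so the
shot-noise-corrected ensemble estimator has expectation exactly κ²_target.
Dark counts are Poisson with a per-pixel rate map; a fraction of pixels
(default 1%) are "hot" at a multiplied rate (default 50×). Hot-pixel
*locations* are a fixed property of the detector (drawn from the
`DarkModel.detector_seed`, default 0), so a dark calibration stack and an
illuminated stack generated from the same model share the same defect map,
as they would on real hardware; photon noise still follows the per-call
seed.

Defaults mirror the instrument's study conditions: 128 × 128 macropixels,
`mean_photons` = 10 counts/pixel/frame (the reported in vivo photon level),
dark base rate 2 counts/frame (reported dark level ≈ 2), exposure 1.6384 ms
and 361.7 fps (the 1024-iteration register setting), ρ = 20 mm, tissue
optics μa = 0.01 mm⁻¹, μs′ = 1 mm⁻¹, n = 1.33, λ = 785 nm, and a baseline
αDb = 1e-6 mm²/s (the customary tissue magnitude). β defaults to 1 for
forward-model curves, as no simulation β is stated.

Scenario profiles drive αDb(t): cuff occlusion (3.5 s baseline, 7 s at
0.1× baseline flow, release with a 3× hyperemic overshoot relaxing with a
2 s time constant over 4 s — the overshoot factor and time constant are our
choices for a realistic reactive-hyperemia shape, which the pipeline must
recover only *ordinally*) and a cognitive task (8 s rest, 30 s at +8% flow,
recovery; +8% sits in the middle of reported activation responses).

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: inter-pixel speckle correlation (each
macropixel is independent, justified by the pipeline's full-array ensemble
statistic, which never uses spatial structure), frame-to-frame field
correlation (each frame is a fresh speckle realization; frame spacing is
assumed ≫ decorrelation time), laser coherence/polarization effects, fiber
speckle statistics, intensity–flow coupling (mean photon flux is held
independent of αDb), motion artifacts, pulsatile waveforms, and SPAD
dead-time/pileup nonlinearity. Read noise and quantization are genuinely
absent in photon-counting SPADs and are therefore absent here by
construction, not omission.

## Contrast pipeline

Per frame, over valid pixels only: Ic = I − mean dark map;
κm² = Var(Ic)/⟨Ic⟩² with the unbiased sample variance (at 128² pixels the
population/sample distinction is negligible; sample variance chosen);
κc² = κm² − 1/⟨Ic⟩ − σ̄D²/⟨Ic⟩², where σ̄D² is the per-pixel dark variance
map averaged over valid pixels (per-pixel-then-average chosen over pooled;
identical in expectation for homogeneous dark). Shot noise uses the frame's
mean corrected intensity in count units (unit conversion gain; SPAD counts
are already digital photons). Read-noise and quantization terms are
identically zero. The decomposition κm² − κc² = 1/⟨Ic⟩ + κd² holds exactly
per frame and is asserted in tests.

Hot pixels are flagged by a *single* 3σ pass (|I − Ī| > 3σ over all pixels)
on the mean dark image — hotness is defined by dark counts; applying the
same rule to an intensity frame is available as an option. One pass, not
iterated sigma-clipping, keeps the flagged count at the stated rule.
Flagged pixels are excluded from every downstream statistic.

Degenerate cases: ⟨Ic⟩ ≤ 0 yields NaN contrast (logged); κc² ≤ 0 (noise
over-subtraction at low signal) is kept in the series for diagnostics but
maps to a missing BFi, never infinity. BFi = 1/κc²; rBFi divides by the
mean BFi over a configurable baseline window, making the baseline mean
exactly 1 before smoothing. Smoothing is a centered 20-sample moving
average, NaN-aware, window shrinking at the edges (edge policy unstated in
the source; shrink-at-edges preserves series length without padding
assumptions). Note the centered window bleeds sharp transitions across
segment boundaries by half a window — visible as a slightly depressed
baseline mean when smoothing is applied after normalization.

## Signal analysis

Welch PSD: Hann window, 256-sample segments, 50% overlap by default,
one-sided density scaling, per-segment mean removal — so the integral of
the density approximates the series variance (asserted within 10% on white
noise). SNR = 20·log10(S/N); for BFi traces the operational definition
S = mean, N = standard deviation over a stationary segment is provided,
with the raw two-amplitude form exposed directly (the source text's S and N
are ambiguous; both are shipped, neither is claimed to match any printed
in vivo SNR).

Envelope trend: local maxima (minima) separated by at least `window`
samples (default 250) are cubic-spline interpolated into an upper (lower)
envelope with endpoints pinned to the series values (no extrapolation);
trend = (upper + lower)/2. Where fewer than three knots exist the envelope
degenerates to linear interpolation (a constant series returns itself).
The pair is sorted pointwise afterwards so upper ≥ lower always holds; the
midline is unaffected. Percent change references the mean of the trend over
the first 8 s by default.

## Problem sizes

Estimator-recovery checks run at the full 128 × 128 array with 200 frames;
end-to-end scenario runs use 64 × 64 pixels at an effective 30 fps sampling
and the task/occlusion timelines above — sizes at which every statistical
assertion has comfortable power while the whole suite stays interactive.
All randomness flows from explicit seeds; identical seeds reproduce stacks
byte-for-byte.

## Known limitations

- The forward model is homogeneous semi-infinite only: no layered or slab
  geometries, no shear-diffusion ⟨Δr²⟩ variants, no time-gated
  (pathlength-resolved) contrast, no Monte Carlo photon transport.
- BFi is a relative index; no absolute calibration to volumetric perfusion.
- The generator's independence assumptions (above) mean estimator variance
  on real cameras with correlated speckle sampling will exceed the
  synthetic prediction; bias properties are unaffected by design.
- In vivo quantities (measured SNRs, photon histograms, task-response
  percentages of any particular instrument) are outside what synthetic data
  can certify; the tests cover the corresponding *identities and orderings*
  instead.
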