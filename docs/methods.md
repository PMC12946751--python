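# Methods

This note records the models implemented by `fiberscope`, their
assumptions, the default parameters and where they come from, and what the
synthetic-data tests do and do not demonstrate.

## Endoscope design calculator (`optics`)

The calculator is purely closed-form. The usable field of view is the
bundle quality-area diameter demagnified by the distal element,
`FOV_max = phi_fiber / M`, and the lateral resolution is the core-lattice
pitch demagnified, `inter_core / M` — in a bundle-relay microscope the core
lattice, not diffraction, samples the image. Values are rounded to the
precision at which such quantities are quoted (10 µm for FOV, 0.1 µm for
resolution); the unrounded effective inter-core distance Δx is kept for
downstream arithmetic.

A spot is specified by the FWHM of its **two-photon** profile. Because 2P
signal is the square of illumination intensity, the illumination Gaussian
is √2 wider; the number of illuminated cores is the squared illumination
FWHM over Δx² (a 10 µm spot at Δx = 3.9 µm covers 13 cores), and the
per-core power assumes 50% of a Gaussian beam's power falls inside its
FWHM. Note the worked number 0.5·200/13 = 7.69 mW is quoted elsewhere as
7.8 mW — consistent with rounding the illumination FWHM to 14 µm before
squaring — so the calculator's exactness claim for that case carries a
±0.3 mW slack.

Two calibration constants are deliberately *not* derived from geometry:

* the scanning/static power ratio (default 0.65). The inscribed-circle area
  ratio π/4 ≈ 0.785 overestimates it because the iris crop also removes the
  slow mirror-turnaround dwell at the square edges; 0.65 is the measured
  ratio of a triangular-waveform scan and is configurable.
* the self-phase-modulation threshold (default 10 mW/core) is an empirical
  property of 920 nm / 130 fs / 80 MHz pulses in these fibers; it is stored
  with the laser preset so a different laser must state its own threshold.

The SNR-matched power rule `P_i = P_0 * sqrt(f_i / f_0)` follows from
holding the per-frame 2P signal `P² / f` constant.

## Tissue-heating simulation (`thermal`)

**Model.** Homogeneous, isotropic, infinite medium; the temperature rise is
the linear superposition of instantaneous-point-source kernels

    dT(r, t) = E / (rho c) * (4 pi D t)^(-3/2) * exp(-r^2 / (4 D t))

over every energy parcel the scan deposits. Deposits are anisotropic
Gaussians (the illumination spot transversally, the depth-slab extent
axially); a Gaussian source of variance σ² evolves exactly as σ² + 2Dt per
axis, so the superposition stays closed-form. The probed quantity is the
time-resolved ΔT at the FOV center, 120 µm deep — the hottest point —
relative to the steady-state brain temperature.

**Scan.** Triangular (constant-speed) raster over the bounding square of
the circular FOV; samples outside the inscribed circle are discarded
(matching an iris-cropped galvo scan, retained fraction π/4) and the
per-frame time budget is spread uniformly over the retained samples, so
the configured scanning power is exactly the average power delivered.

**Light deposition.** Default mode is deterministic Beer–Lambert: Gaussian
transverse profile, depth attenuation `exp(-mu_a z)`, no absorption above
the tissue surface. The deposition domain is truncated at 1 mm: far beyond
the scattering length the ballistic column is not a meaningful description
of where light travels, and the truncation changes the 3.2 s peak by < 5%.
The optional `bpm` mode propagates the field through random phase screens
(unitary, variance dz/l_s per step so the coherent component decays as
`exp(-z / l_s)`) and returns ensemble-averaged per-slab absorption and
transverse widths; it is seeded and used for scattering studies, not for
the headline result.

**Constants.** The tissue constants are not a measurement of this package;
they are standard brain gray-matter values from the optogenetics-heating
modeling literature: conductivity κ = 0.527 W m⁻¹ K⁻¹, volumetric heat
capacity ρc = 3.796 MJ m⁻³ K⁻¹ (ρ = 1040 kg/m³, c = 3650 J/kg/K), hence
D = 1.39·10⁻⁷ m²/s, and µ_a(920 nm) = 13 m⁻¹ (0.13 cm⁻¹), the
water-dominated absorption of ~80%-water tissue at 920 nm. A default
scattering length of 170 µm is carried for the bpm mode. All are fields of
`TissueThermalModel` and can be overridden.

**Numerics.** Defaults: 100 lines and 10⁴ samples per frame, 24 depth
slabs refined around the probe depth, 10 output times per frame.
Convergence was checked by halving/doubling the sampling (2500 vs 2·10⁴
samples per frame move the peak by < 0.5%); the test suite runs at 2500
samples per frame for speed. The `equilibrated` flag is set when the
per-frame peak grows by less than 1% (relative) between the last two
frames. Two independent oracles check the implementation: the analytic
kernel against an explicit 3D finite-difference solver (2%), and a full
scanned mini-protocol against the same solver (5%).

**Result.** With these constants, scanning a 10 µm spot over a 500 µm FOV
at 5 Hz for 16 frames gives peak ΔT = 1.10 °C at 195 mW, 0.73 °C at
130 mW and 0.37 °C at 65 mW, equilibrating within the 16 frames — only the
highest power crosses a 1 °C safety threshold. Because the published
tissue constants carry real uncertainty, this conclusion should be read as
a threshold comparison, not a 3-digit temperature.

**Out of scope.** Perfusion (Pennes) heat sinks, boundary effects at the
cranial window, pulsed (non-CW-average) deposition, photothermal damage
kinetics. Perfusion would lower the late-time plateau, so the model is
conservative.

## Holographic pattern synthesis (`holography`)

The propagation model is a single unitary discrete Fourier transform
between the SLM and sample planes (ideal lens conjugation) on a square
computational grid; the addressable field (default 480 µm) fixes the
sample-plane pixel. Energy conservation of this transform is exact, which
makes delivered-power bookkeeping meaningful.

* **Gerchberg–Saxton**: alternating projections between the
  uniform-amplitude SLM constraint and the target far-field amplitude;
  random-phase initialization with an explicit seed, default 50 iterations,
  early stop when the relative error change falls below 10⁻⁴. The RMS
  amplitude error is non-increasing (projection property). Extended GS
  holograms carry speckle, quantified as σ/mean of intensity over the
  target support.
* **Multiplexed Gaussian spots**: the phase of a coherent sum of tilted
  Gaussian beamlets, displayed on an incident Gaussian matched to the spot
  size — smooth, speckle-free spots, which is why somata are targeted this
  way. Discarding the amplitude of the beamlet sum compresses unequal
  weights, so the weights are refined closed-loop (damped multiplicative
  updates, exponent 0.25, at most 20 iterations) until per-spot delivered
  powers match the request within 5%; the loop stops at tolerance because
  the phase-only response near equality is steep enough to amplify
  discretization noise (visible as a bifurcation for two exactly symmetric
  spots).
* **Diffraction efficiency**: no first-principles model of the LC-SLM is
  attempted; a separable sinc² falloff of normalized deflection (Nyquist
  deflection at the field edge) stands in for the position-dependent
  efficiency and is swappable. Compensation weights are 1/η with the
  center at 1; positions where η < 0.1 are refused.
* **Shape power normalization**: `power_i = excitation_density * area_i`,
  keeping power per unit area constant across shapes of different size.
* **Zernike phases**: Noll-indexed, Noll-normalized polynomials on the SLM
  pupil, zero outside; checked by disk-sampled orthogonality and by the
  sign of the best-focus shift a pure defocus term produces under
  angular-spectrum propagation.

## Photostimulation-response statistics (`stim`)

The paradigm: trains of 10 pulses of 20 ms at 4 Hz, pulses placed in the
50 ms camera-off gaps of a 200 ms-on / 50 ms-off gating (hence the 4 Hz
frame clock), repeated 4 times per acquisition. Analysis runs on the
repetition-averaged ΔF/F trace of each cell:

* baseline = mean over the 2 s before train onset;
* response = mean over the 2 s after the **5th pulse** (the train middle,
  onset + 4 inter-pulse intervals = +1.0 s);
* responding ⇔ response − baseline > 3 × sd(baseline window), with the sd
  taken on the averaged trace (the criterion is stated on ⟨ΔF/F⟩; this
  convention is isolated in one function and testable).

Labels cross targeted status with response (T/R, T/nR, nT/R, nT/nR) and
always partition the cells. The criterion is scale-equivariant: scaling a
trace by c > 0 never changes its label.

Off-target activation is summarized as the probability of responding
versus distance to the nearest spot, binned at 10 µm (bins with fewer than
5 cells merged forward — no binning rule is canonical, this one is
configurable), and fitted with `A * exp(-x / k)` by unweighted nonlinear
least squares with standard errors from the fit covariance. On synthetic
Bernoulli outcomes at n = 2000 the estimator is unbiased (replicate mean
within 0.5% of truth, replicate sd ≈ 1 µm at k = 18.4 µm). Degenerate
inputs (all-zero or all-one probabilities, < 3 usable bins) are refused
rather than fitted.

The motion summary reduces externally supplied per-patch displacements to
`d = sqrt(dx² + dy²)` averaged per frame over non-corner patches (corner
patches image static regions outside the bundle). SNR-thresholded counting
uses strict inequality (SNR > 2). Source extraction itself (CNMF), motion
correction estimation and pose estimation are out of scope: this module
consumes their outputs.

## Optical characterization (`characterization`)

Axial profiles integrate pixel intensity in a circular ROI around the spot
after subtracting the per-plane median of the pixels outside the ROI
(background choice ours; the measurement is insensitive to it as long as
the layer is dark away from the spot). The axial FWHM is read at half of
(peak − baseline) with linear interpolation between planes; monotone
profiles are refused. Attenuation lengths come from a log-linear least
squares of `S = S0 exp(-2 z / l_e)` — the factor 2 because the 2P signal
is the square of the attenuated illumination — exact on noiseless
exponentials, within 10% under 5% multiplicative noise across the 80–246 µm
range. The power-law exponent is the natural-log/log slope of signal vs
power; 2.0 within 0.1 on synthetic pure-2P series over 32.5–325 mW.

## Behavior (`behavior`)

Speed is inter-frame displacement over the frame interval, moving-averaged
over 200 ms to suppress single-frame tracking artifacts. Exploration rate
is the fraction of a fixed 48-zone partition of the cage floor visited at
least once; the grid is laid out 8 × 6 (zones of 4.625 × 3.5 cm on a
37 × 21 cm floor), cells are half-open with boundary points assigned to
the lower-index zone, and a single-frame visit counts (no dwell minimum —
the simplest defensible convention). Positions outside the cage (tracking
reflections) are flagged and clipped.

## Synthetic data (`synth`)

Each generator exports its hidden parameters so every analysis has a
recovery test:

* **Bundle images**: hexagonal core lattice in a circular aperture,
  per-core transmission lognormal with configurable CV (≈0 emulates
  leached bundles with constant cores; larger CVs emulate bundles
  manufactured with stochastic core inhomogeneity). Imaged signal scales
  with transmission² (2P), so transmission CV c appears as intensity CV
  ≈ 2c — verified over a 100-seed ensemble.
* **Calcium experiments**: slow-indicator kinetics (0.5 s rise, 1.5 s
  decay — chosen as jGCaMP7s-like values; no kinetics are canonical) with
  additive Gaussian frame noise; targeted cells respond to every train,
  non-targets are Bernoulli(p₀·exp(−d/k_true)) drawn once per cell; frames
  run on the camera-gated 4 Hz clock; an optional power-dependent baseline
  ramp emulates opsin cross-activation by the imaging laser above a
  threshold power. A separate light-weight generator draws pure
  distance/outcome pairs for decay-fit studies.
* **Z-stacks**: static spots on a thin fluorescent layer with Gaussian
  axial response of known FWHM, best-focus plane shifting quadratically
  with radial position up to the field curvature at the FOV edge, Poisson
  photon noise over a flat background.
* **Trajectories**: random walk with speeds drawn from a caller-supplied
  distribution held constant over 200 ms blocks (so the analysis smoothing
  window does not distort the recovered distribution), diffusing heading,
  and wall reflection.

**What passing these tests shows — and does not.** Recovery tests prove
the estimators are correctly implemented and statistically calibrated
under the generators' assumptions (Gaussian noise, exact timing, rigid
geometry). Real recordings add neuropil contamination, non-rigid motion,
indicator nonlinearity and segmentation errors that these generators
deliberately omit; in-vivo component counts, measured axial resolutions
and behavioral comparisons are therefore not reproduced here, only the
computational machinery that produces them.

## Problem sizes

Defaults were chosen so the full test suite runs in under a minute and the
acceptance script in well under a minute on one CPU: thermal tests use
2500 scan samples per frame (convergence-checked against 10⁴, which the
acceptance script uses), holography tests run on 256² grids (the library
default is 512²), and recovery studies use 2000 cells / 200 replicates.
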