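# Methods

`epiqsm` simulates and analyses the test-retest reliability of
T2\*-weighted brain MRI and its quantitative derivatives — the effective
transverse relaxation rate R2\*, the tissue frequency shift *f*, and the
magnetic susceptibility χ — comparing a conventional multi-echo 3D
gradient-echo (GRE) acquisition against multi-shot multi-echo 3D EPI with
EPI factors 3 and 5. This note documents the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic study
does and does not establish about real data.

## Digital phantom

The phantom is analytic: an ellipsoidal "brain" of white-matter-like
tissue (χ = −30 ppb, R2\* = 21 s⁻¹, M0 = 0.85), five spherical deep
grey-matter nuclei (χ drawn per seed from 50–180 ppb, R2\* from
30–80 s⁻¹), three white-matter ROI spheres, a CSF shell (χ = 0 ppb,
R2\* = 1 s⁻¹, M0 = 1), and zero signal outside the head. Tissue values
are literature-typical for healthy adult deep-brain structures at 3 T;
the source study reports no tissue values of its own. Ellipsoid-plus-
spheres geometry keeps every ROI's ground truth exact and placement
testable; grids too small to hold all ROIs (sphere radius under two
voxels, or protruding from the brain) raise an error naming the first
unplaceable ROI.

The default grid is 64 × 64 × 48 voxels at 3 mm — a desk-scale stand-in
for the study's 1 mm, 240 × 180 × 144 mm protocol; the full-size matrices
are available through the protocol presets. One deliberate geometric
choice: the head fits within **half** the field of view along both
phase-encode axes. The acquisitions are 2 × 2 CAIPI-undersampled, and
with a uniform (single-coil) receive model the zero-filled reconstruction
of a regular lattice is alias-free exactly when the object fits the
reduced FOV. This removes parallel-imaging machinery from the reliability
analysis entirely — replica ghosts never overlap the brain, so R2\* fits
see single-compartment decays and coregistration is unambiguous (up to
the replica lattice, which the coregistration handles explicitly).

The susceptibility-induced field uses the standard k-space dipole kernel
D(**k**) = 1/3 − k_z²/|**k**|², D(0) := 0 (zero spatial mean), with B0
along z and γ = 42.58 MHz/T. Note that the discrete kernel's voxel-level
near field differs appreciably from the analytic point dipole (its
continuum limit); agreement with open-space dipole summation holds for
band-limited sources, which is how the oracle tests probe it.

## Physiological model

Shot-resolved physiological state is a `ShotTimeline` with three
components per TR:

| parameter | default | meaning |
|---|---|---|
| `drift_sd_hz` | 0.2 Hz/shot | random-walk global B0 drift |
| `resp_amp_hz`, `resp_period_s` | 1 Hz, 4 s | sinusoidal respiratory B0 modulation |
| `grad_sd_hz_per_mm` | 0.002 Hz/mm/shot | random-walk spatially linear B0 gradient (per axis) |
| `trans_sd_mm` | 0.02 mm/shot | random-walk rigid translation (per axis) |

The study protocol reports no physiological magnitudes; the defaults are
chosen once at a realistic 3 T scale: ~1 Hz respiratory modulation, a few
Hz of frequency drift over a ~50 s scan, a few Hz of edge-of-FOV linear
field drift, and sub-millimetre positional drift. They produce visibly
worse uncorrected reliability, which is the regime the comparison is
about. Rotations and through-plane dephasing are out of scope.

## Acquisition simulation

The forward model is an inverse-crime simulator: for shot *s* and echo
*e* the image is

    m0 · exp(−R2* TE_e) · exp(i 2π (f_χ(r) + a_s + g_s·r) TE_e),

translated by the shot's rigid offset (Fourier shift), sampled on the
shot's CAIPI lines via the unitary 3D DFT, with circular complex Gaussian
noise of SD σ per k-space sample. σ is set from a target first-echo brain
SNR (default 50 for GRE — consistent with the reported in-vivo last-echo
SNR comfortably above 10) and scaled across protocols by √(bandwidth
ratio); the EPI protocols are repeated by their EPI factor so that
averaging the repetitions restores the GRE noise level (the matched-SNR
design, which the tests verify to within a few per mille).

Because the per-shot physiological phase is global + spatially linear it
factorizes over the axes, so each line is evaluated by dense matrix
products (a partial DFT cast as BLAS gemm) rather than per-shot FFTs.
This is numerically identical to the FFT formulation and roughly an
order of magnitude faster on one core — it is what makes 20-seed-pair
property tests affordable. Echo trains alternate readout polarity; an
optional constant + linear odd/even phase error can be injected together
with a ky = kz = 0 calibration line pair, mirroring the N/2-ghost
calibration scheme.

Timing arithmetic (readout train length, navigator TR count, maximum
feasible EPI factor under gradient limits) is implemented in idealized
ramp-free / flat-top-only form. The ramp-free train length reproduces the
GRE value (1/125 Hz/px = 8 ms) exactly; the EPI columns of the protocol
table include gradient overheads the model deliberately omits (3/372 =
8.06 ms vs the tabulated 10 ms). Scan-time prediction from matrix × TR is
exposed but known not to reproduce tabulated scan times (vendor sampling
reductions are not modelled).

## Reconstruction

Two modes:

* **uncorrected** — density-compensated zero-filled inverse DFT with one
  global demodulation by the scan-mean B0 offset per echo;
* **corrected** — per-shot demodulation. The global offset, the
  translation and the readout-axis component of the linear gradient are
  diagonal per line and inverted **exactly**. The phase-encode ramp
  components are removed by the per-shot conjugate ramp (the k-domain
  equivalent of the image ramp), followed by a small number of
  model-based refinement steps: predict the ramp-induced k-space
  perturbation from the current estimate, subtract it, re-grid. When the
  object support is supplied (the pipeline passes the known phantom
  support — the stand-in for a brain-extraction mask), the prediction
  uses the replica-free part of the estimate and the correction becomes
  accurate to the noise level. A data-consistency guard reverts any
  refinement step that increases the residual. The full non-uniform-FFT
  coordinate-shift reconstruction used in the original motion-corrected
  framework is deliberately not reimplemented.

The corrected mode accepts either the true simulation timeline (oracle
correction, the default in the experiments — an upper bound on navigator
performance) or a navigator-style estimate: `estimate_timeline` fits
a + **g**·**r** per shot to aligned, unwrapped low-resolution phase maps
at the nominal navigator TE of 3.9 ms. Navigator *images* are not
synthesized; only the estimation contract and the timing arithmetic are
modelled.

## Quantification

* **R2\*** — per-voxel nonlinear least squares of S0·exp(−R2\*·TE) on the
  magnitudes (magnitude-only fitting, as in the study), initialized from
  the magnitude-weighted log-linear fit and refined by vectorized
  Gauss–Newton with a divergence guard; non-converged voxels fall back to
  the log-linear estimate and are flagged; negative estimates are clipped
  to zero with a logged count; a warning is emitted when the last-echo
  SNR falls below 10 (magnitude-only fitting underestimates R2\* there).
* ***f*** — temporal unwrapping of each echo against the linear
  prediction from earlier echoes (spatial unwrapping first when
  within-echo wraps are detected, via the quality-guided unwrapper from
  scikit-image), then a weighted least-squares slope of phase versus
  2π·TE with weights magnitude²·TE and a free intercept. The weight
  choice is a standard interpretation of weighted echo averaging; the
  study does not print its weights.
* **background removal** — VSHARP: spherical-mean-value filtering with
  the largest feasible radius per voxel (default radii 6→1 voxel
  equivalents), deconvolved by the largest-radius kernel with truncated
  inverse filtering (threshold 0.05). The sphere kernels are analytic in
  k-space (a voxelized ball visibly violates the discrete mean-value
  property on steep fields); deconvolving with the smallest radius would
  truncate the entire low-frequency tissue band, hence the largest-radius
  choice. The LBV stage of the original pipeline is omitted.
* **χ** — closed-form dipole inversion: thresholded k-space division
  (default threshold 0.2) with the standard point-spread amplitude
  correction (divide by mean(D/D_clipped)), or Tikhonov. Results are in
  ppb, re-referenced to the brain-mask mean. The structure-prior
  iterative inversion of the original pipeline is deliberately replaced;
  χ is accordingly excluded from the thermal-noise floor, whose value
  would be specific to the regularizer.

## Reliability analysis

Magnitude reliability is the voxelwise normalized absolute difference
NAD = |m₁ − m₂| / ((m₁ + m₂)/2), computed per echo and on
echo-and-repetition-averaged magnitudes; near-zero-mean voxels (below
10⁻¹² of the grid maximum) are excluded and counted. Quantitative maps
are compared by |ΔR2\*|, |Δf|, |Δχ|, where multi-repetition scans are
averaged **as maps over repetitions**, never as complex data. Headline
scalars are medians (the CDF-0.5 point); averaging curves report the
median |Δ| versus the number N of repetition averages. Inter-scan motion
is corrected with a single translation per scan pair estimated by Fourier
phase correlation on the repetition- and echo-averaged magnitudes,
snapped to the nearest replica-lattice vector of the sampling pattern
(phase correlation on regularly undersampled images is ambiguous modulo
that lattice, including its CAIPI-staggered diagonal), and applied to all
companion maps by cubic-spline resampling. Distortion correction is not
applied in the test-retest path (distortion is protocol-specific and
identical within a protocol's scan pair).

Thermal-noise floors come from a complex-noise Monte Carlo on a noiseless
reconstructed reference: per trial, two scan sides of N independent noisy
realizations each are quantified per realization and averaged as maps,
mirroring the estimator chain of the experiment. The folded-normal
closed form (median |X₁ − X₂| = √2·Φ⁻¹(0.75)·σ ≈ 0.954 σ for i.i.d.
Gaussian inputs) anchors the NAD and |Δ| floors in the tests.

## Distortion and blurring evaluation

EPI off-resonance displacement follows the full-train dwell model:
shift [px] = Δf · ETL, so 150 Hz across a 10 ms train is 1.5 px.
Correction resamples along the phase-encode axis with cubic splines on a
periodic grid and refuses warps beyond a quarter of the grid. The
evaluation displaces a discrete delta by a band-limited Fourier shift,
corrects it with the matching uniform field, and reports (a) the residual
shift from the linear Fourier-phase trend, fitted inside the resolved
passband (up to half the −3 dB cutoff; beyond it the resampler's phase
response is strongly nonlinear), and (b) the effective voxel size as
Nyquist over the −3 dB *amplitude* cutoff relative to DC — the
amplitude-vs-power convention is a documented choice — normalized so an
on-grid delta gives exactly 1.

T2\*-decay blurring weights the phase-encode lines by exp(−t/T2\*) with
acquisition time mapped linearly 0 → ETL in sequential order; the PSF is
the magnitude of the inverse DFT and the FWHM is measured with linear
interpolation between samples. Two conventions are reported: the discrete
convention (no decay → exactly 1.0 voxel), which is normative here, and
the oversampled continuous-sinc convention (no decay → 1.2067 voxels).
Interleaved multi-shot orderings produce ghost-like modulation rather
than smooth blur and are out of scope.

## Study conditions and problem sizes

The packaged experiment (and the property tests) uses the 64 × 64 × 48
phantom, the three desk-scaled protocols (768 sampled lines per
repetition after 2 × 2 CAIPI; 768/256/154 shots per repetition for
GRE/EPI×3/EPI×5; repetition counts 1/3/5, so total scan durations are
matched at ~46–51 s as in the full-size design), target GRE SNR 50,
default physiological noise, 20 independent scan-pair seeds, and
single-precision complex arithmetic in the bulk simulations (double
precision everywhere precision-sensitive properties are asserted).
Thermal floors use 5 Monte Carlo trials of the full repetition-averaged
estimator chain.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* the study attributes its
findings to — shorter k-space passes accumulate less intra-scan B0
drift/respiration inconsistency; repetition averaging cancels part of
what remains; matched total acquisition time equalizes thermal noise —
and the package's analyses recover the expected structure: reliability
improving with EPI factor, corrected beating uncorrected
reconstruction, single-repetition EPI×5 already rivalling GRE, and
corrected EPI×5 sitting at its thermal floor. None of this calibrates to
the study's in-vivo numbers: real brains have continuous tissue
distributions, coil arrays, rotational motion, flow, and physiological
noise of unknown per-subject magnitude, and the published group medians
(e.g. |ΔR2\*| ≈ 1.4–1.7 s⁻¹) depend on that unreleased data. The
synthetic study tests the algorithms and the direction of the effects,
not the in-vivo effect sizes.

## Known limitations

* Single uniform receive coil with an alias-free geometry contract; no
  g-factor, no coil-array reconstruction.
* Translation-only motion, in simulation, correction and coregistration.
* The phase-encode linear-B0 correction is model-based rather than an
  exact inversion; with the default gradient magnitudes its residual is
  below the thermal floor, but large gradients (several radians of
  edge-to-edge phase per shot spread) would exceed the refinement's
  convergence range — the guard then falls back to the one-step
  correction.
* Inverse-crime simulation: reconstruction shares the forward model's
  discretization, so trajectory infidelity, eddy currents, ramp sampling,
  T1 saturation and partial-Fourier effects are all outside the model.
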