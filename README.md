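# epiqsm

Test-retest reliability of R2\* and quantitative susceptibility mapping
(QSM) with multi-shot multi-echo 3D EPI versus conventional 3D GRE — as a
fully synthetic, reproducible pipeline.

Quantitative T2\*-weighted MRI derives the effective transverse
relaxation rate R2\* (from the multi-echo magnitude decay
S(TE) = S₀·e^(−R2\*·TE)), the tissue frequency shift *f* (from the
multi-echo phase) and the magnetic susceptibility χ (by inverting the
dipole field model B(**k**) ∝ (1/3 − k_z²/|**k**|²)·χ(**k**)). A
conventional GRE scan acquires one k-space line per TR and takes minutes,
during which B0 drift, respiration and motion corrupt the phase.
Multi-shot 3D EPI acquires several lines per TR (the *EPI factor*),
shortening each k-space pass; repeating the faster scan and raising the
readout bandwidth keeps the thermal SNR matched while shrinking the
physiological-noise footprint. This package simulates that comparison end
to end — digital brain phantom, shot-resolved k-space with thermal and
physiological noise, corrected/uncorrected reconstruction, R2\*/f/χ
quantification — and quantifies test-retest reliability with the
normalized absolute difference (NAD = |m₁−m₂|/pair mean), inter-scan
|ΔR2\*|, |Δf|, |Δχ|, their CDFs and medians, repetition-averaging curves
and Monte Carlo thermal-noise floors, plus the EPI distortion-correction
and T2\*-blurring evaluations.

It is aimed at MR physicists who want a transparent sandbox for
shot-timescale B0/motion artifact mechanisms and reliability statistics,
with every stage testable against ground truth.

## Worked example

```python
import numpy as np
import epiqsm as eq

phantom = eq.build_phantom()                      # 64 x 64 x 48, 3 mm
fieldmap = eq.chi_to_field(phantom)
protocols = {n: p.with_geometry(phantom.shape, phantom.voxel_mm)
             for n, p in eq.protocol_presets().items()}
sigma = eq.gre_sigma_for_snr(phantom, protocols["GRE"], 50.0, fieldmap)

for name in ("GRE", "EPIx3", "EPIx5"):
    p = protocols[name]
    res = eq.run_scan_pair(
        phantom, p, (11, 22),
        sigma_k=eq.protocol_sigma(p, sigma),
        physio=dict(eq.DEFAULT_PHYSIO),
        metrics=("nad", "dr2s"), dtype=np.complex64, fieldmap=fieldmap)
    for mode in ("corrected", "uncorrected"):
        r = res[mode]
        print(f"{name:6s} {mode:12s} median NAD {r['nad_median']:.4f}"
              f"  median |dR2*| {r['dr2s_median']:.2f} 1/s")
```

Output (one seed pair; values fluctuate a little across seeds):

```
GRE    corrected    median NAD 0.0109  median |dR2*| 0.89 1/s
GRE    uncorrected  median NAD 0.1439  median |dR2*| 6.24 1/s
EPIx3  corrected    median NAD 0.0088  median |dR2*| 0.65 1/s
EPIx3  uncorrected  median NAD 0.0500  median |dR2*| 3.26 1/s
EPIx5  corrected    median NAD 0.0088  median |dR2*| 0.64 1/s
EPIx5  uncorrected  median NAD 0.0364  median |dR2*| 2.08 1/s
```

Two scans of the same phantom differ only through noise: thermal noise is
matched by design across protocols, so the uncorrected columns isolate
the physiological term — reliability improves monotonically with the EPI
factor (median NAD 0.144 → 0.050 → 0.036, i.e. each full k-space pass is
faster and internally more consistent), and the shot-resolved B0/motion
correction removes most of the remaining physiological error at every
EPI factor.

The same pipeline is scriptable from the shell:

```bash
epiqsm run-experiment --seed 0 --out out/        # full report.json
epiqsm distortion-eval --out out/distortion/     # effective-voxel curves
```

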