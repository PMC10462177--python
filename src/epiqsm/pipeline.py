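"""Experiment orchestration, configuration and file I/O.

One "experiment" mirrors the study design: a phantom is scanned twice per
protocol (test-retest), each scan carrying its own physiological timeline
and thermal noise realization; both scans are reconstructed in corrected
and uncorrected modes, quantified per repetition, coregistered, and
compared with the reliability metrics.  All randomness flows from explicit
seeds recorded in the report manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import acquisition as acq
from . import quantify, reliability, recon
from .phantom import Phantom, ShotTimeline, build_phantom, chi_to_field, \
    sample_physio_timeline

DEFAULT_PHYSIO = {"drift_sd_hz": 0.2, "resp_amp_hz": 1.0,
                  "resp_period_s": 4.0, "grad_sd_hz_per_mm": 0.002,
                  "trans_sd_mm": 0.02}


@dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment bit-for-bit."""

    phantom_shape: tuple = (64, 64, 48)
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    phantom_seed: int = 0
    b0_tesla: float = 3.0
    protocols: tuple = ("GRE", "EPIx3", "EPIx5")
    modes: tuple = ("corrected", "uncorrected")
    metrics: tuple = ("nad", "dr2s", "df", "dchi")
    seed_pairs: tuple = ((101, 202),)
    target_snr: float | None = 50.0
    noise_sigma: float | None = None
    physio: dict = field(default_factory=lambda: dict(DEFAULT_PHYSIO))
    ordering: str = "interleaved"
    precision: str = "double"            # "double" | "single"
    noise_floor_trials: int = 0
    out_dir: str = "epiqsm_out"

    def __post_init__(self):
        if not self.protocols or not self.modes:
            raise ValueError("at least one protocol and one mode are required")
        for s1, s2 in self.seed_pairs:
            if s1 == s2:
                raise ValueError("scan seeds within a pair must be distinct")
        if self.target_snr is None and self.noise_sigma is None:
            raise ValueError("either target_snr or noise_sigma must be set")

    @property
    def dtype(self):
        return np.complex64 if self.precision == "single" else np.complex128

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        for k in ("phantom_shape", "voxel_mm", "protocols", "modes", "metrics"):
            if k in d:
                d[k] = tuple(d[k])
        if "seed_pairs" in d:
            d["seed_pairs"] = tuple(tuple(p) for p in d["seed_pairs"])
        return cls(**d)


# ----------------------------------------------------------------------
# Noise calibration
# ----------------------------------------------------------------------

def gre_sigma_for_snr(phantom: Phantom, protocol_gre: acq.Protocol,
                      target_snr: float, field=None) -> float:
    """k-space complex-noise SD giving the target first-echo brain SNR.

    With the unitary DFT and zero-filled R = ry*rz undersampling the
    image-domain complex noise SD is sqrt(R) times the k-space SD, so
    sigma_k = S1 / (SNR * sqrt(R)) with S1 the mean first-echo brain
    magnitude.
    """
    if field is None:
        field = chi_to_field(phantom)
    te1 = protocol_gre.te_s[0]
    s1 = float(np.mean((phantom.m0 * np.exp(-phantom.r2s * te1))[phantom.mask]))
    r = protocol_gre.accel[0] * protocol_gre.accel[1]
    return s1 / (target_snr * np.sqrt(r))


def protocol_sigma(protocol: acq.Protocol, sigma_gre: float,
                   gre_bw: float = 125.0) -> float:
    return acq.thermal_noise_sigma(protocol.bw_hz_per_px, sigma_gre, gre_bw)


# ----------------------------------------------------------------------
# One protocol / one seed pair
# ----------------------------------------------------------------------

def _scan(phantom, protocol, seed, sigma_k, physio, ordering, dtype,
          base_images, fieldmap):
    """Simulate one scan: all repetitions plus its physiological timeline."""
    n_total = protocol.n_shots() * protocol.repetitions
    if physio is None:
        timeline = ShotTimeline.null(n_total)
    else:
        timeline = sample_physio_timeline(n_total, tr_s=protocol.tr_s,
                                          seed=seed, **physio)
    reps = acq.simulate_multirep_scan(phantom, protocol, timeline, sigma_k,
                                      seed=seed + 7919, ordering=ordering,
                                      dtype=dtype, base_images=base_images,
                                      field=fieldmap)
    return reps, timeline


def _reconstruct_scan(reps, timeline, mode, protocol, support=None):
    n = protocol.n_shots()
    images = []
    for r, k in enumerate(reps):
        tl = timeline.slice(r * n, (r + 1) * n) if mode == "corrected" else timeline
        images.append(recon.reconstruct(k, mode, tl, support=support))
    return images


def run_scan_pair(phantom: Phantom, protocol: acq.Protocol, seeds,
                  *, sigma_k: float, physio=DEFAULT_PHYSIO,
                  modes=("corrected", "uncorrected"),
                  metrics=("nad", "dr2s"), ordering="interleaved",
                  dtype=np.complex128, base_images=None, fieldmap=None,
                  coregister=True, return_cdf=False) -> dict:
    """Simulate and analyse one test-retest scan pair for one protocol.

    Returns {mode: {"nad_median", "dr2s_median", "df_median",
    "dchi_median", "<metric>_curve", ...}} with medians over the masks
    natural to each metric and averaging curves over N = 1..repetitions.
    """
    if fieldmap is None:
        fieldmap = chi_to_field(phantom)
    if base_images is None:
        base_images = acq.ideal_echo_images(phantom, protocol.te_s, fieldmap,
                                            dtype)
    scans = [_scan(phantom, protocol, s, sigma_k, physio, ordering, dtype,
                   base_images, fieldmap) for s in seeds]
    mask = phantom.mask
    support = phantom.m0 > 0
    need_chi = "dchi" in metrics
    need_f = "df" in metrics or need_chi
    out = {}
    for mode in modes:
        images = [_reconstruct_scan(reps, tl, mode, protocol, support)
                  for reps, tl in scans]
        # scan-level magnitude: echo kept, repetitions averaged
        mag_scan = [np.mean([np.abs(im.data) for im in ims], axis=0)
                    for ims in images]
        mag_avg = [m.mean(axis=-1) for m in mag_scan]   # echo-averaged
        if coregister:
            nx, ny, nz = phantom.shape
            pattern = acq.caipi_pattern(ny, nz, *protocol.accel,
                                        1 if protocol.caipi else 0)
            vecs = reliability.replica_lattice(pattern.lines, ny, nz)
            shift, _ = reliability.coregister_translation(
                mag_avg[1], mag_avg[0], alias_vectors=vecs)
        else:
            shift = np.zeros(3)

        res = {}
        m2 = reliability.apply_shift(mag_avg[1], shift)
        nad, _ = reliability.nad_map(mag_avg[0], m2, mask)
        res["nad_median"] = reliability.masked_median(nad)
        if return_cdf:
            res["nad_cdf"] = reliability.empirical_cdf(nad)[:2]

        if "dr2s" in metrics or need_f:
            per_rep = [[], []]
            for i, ims in enumerate(images):
                for im in ims:
                    mag = np.abs(im.data)
                    r2s, _, _ = quantify.fit_r2star(mag, im.te_s, mask)
                    rec = {"r2s": r2s}
                    if need_f:
                        f_tot = quantify.frequency_map(
                            np.angle(im.data), im.te_s, mag, mask)
                        f_tis, eroded = quantify.vsharp_background_removal(
                            f_tot, mask, im.voxel_mm)
                        rec["f"] = f_tis
                        rec["eroded"] = eroded
                        if need_chi:
                            rec["chi"] = quantify.dipole_inversion(
                                f_tis, eroded, phantom.b0_tesla, im.voxel_mm)
                    per_rep[i].append(rec)
            if "dr2s" in metrics:
                maps1 = [r["r2s"] for r in per_rep[0]]
                valid = mask.copy()
                for recs in per_rep:
                    for r in recs:
                        valid &= np.isfinite(r["r2s"])
                maps1 = [np.nan_to_num(m) for m in maps1]
                maps2 = [reliability.apply_shift(np.nan_to_num(r["r2s"]), shift)
                         for r in per_rep[1]]
                curve = reliability.averaging_curve(maps1, maps2, valid)
                res["dr2s_curve"] = curve
                res["dr2s_median"] = float(curve[-1])
                res["dr2s_median_single"] = float(curve[0])
            if need_f:
                emask = per_rep[0][0]["eroded"] & per_rep[1][0]["eroded"]
                if "df" in metrics:
                    f1 = [np.nan_to_num(r["f"]) for r in per_rep[0]]
                    f2 = [reliability.apply_shift(np.nan_to_num(r["f"]), shift)
                          for r in per_rep[1]]
                    curve = reliability.averaging_curve(f1, f2, emask)
                    res["df_curve"] = curve
                    res["df_median"] = float(curve[-1])
                if need_chi:
                    c1 = [np.nan_to_num(r["chi"]) for r in per_rep[0]]
                    c2 = [reliability.apply_shift(np.nan_to_num(r["chi"]), shift)
                          for r in per_rep[1]]
                    curve = reliability.averaging_curve(c1, c2, emask)
                    res["dchi_curve"] = curve
                    res["dchi_median"] = float(curve[-1])
        res["shift_voxels"] = np.asarray(shift, dtype=float)
        out[mode] = res
    return out


# ----------------------------------------------------------------------
# Full experiment
# ----------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> dict:
    """Run all protocols, modes and seed pairs; write the report files.

    Per-protocol failures are isolated and reported in the output rather
    than aborting the remaining protocols.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom = build_phantom(config.phantom_shape, config.voxel_mm,
                            config.phantom_seed, config.b0_tesla)
    fieldmap = chi_to_field(phantom)
    presets = acq.protocol_presets()
    protocols = {name: presets[name].with_geometry(config.phantom_shape,
                                                   config.voxel_mm)
                 for name in config.protocols}
    sigma_gre = (config.noise_sigma if config.noise_sigma is not None
                 else gre_sigma_for_snr(phantom, protocols.get(
                     "GRE", next(iter(protocols.values()))),
                     config.target_snr, fieldmap))

    physio = config.physio if any(config.physio.values()) else None
    report = {"config": json.loads(config.to_json()),
              "sigma_gre_kspace": float(sigma_gre),
              "protocols": {}, "errors": {}}
    for name, protocol in protocols.items():
        sigma_k = protocol_sigma(protocol, sigma_gre)
        base = acq.ideal_echo_images(phantom, protocol.te_s, fieldmap,
                                     config.dtype)
        cells = {mode: {m: [] for m in config.metrics} for mode in config.modes}
        curves = {mode: {} for mode in config.modes}
        try:
            for seeds in config.seed_pairs:
                pair = run_scan_pair(
                    phantom, protocol, seeds, sigma_k=sigma_k, physio=physio,
                    modes=config.modes, metrics=config.metrics,
                    ordering=config.ordering, dtype=config.dtype,
                    base_images=base, fieldmap=fieldmap)
                for mode in config.modes:
                    for m in config.metrics:
                        key = f"{m}_median" if m != "nad" else "nad_median"
                        if key in pair[mode]:
                            cells[mode][m].append(pair[mode][key])
                    for m in ("dr2s", "df", "dchi"):
                        ck = f"{m}_curve"
                        if ck in pair[mode]:
                            curves[mode].setdefault(m, []).append(
                                pair[mode][ck].tolist())
            entry = {"medians": {
                mode: {m: (float(np.mean(v)) if v else None)
                       for m, v in cells[mode].items()}
                for mode in config.modes},
                "per_pair_medians": {
                    mode: {m: [float(x) for x in v]
                           for m, v in cells[mode].items() if v}
                    for mode in config.modes},
                "averaging_curves": {
                    mode: {m: np.mean(c, axis=0).tolist()
                           for m, c in curves[mode].items()}
                    for mode in config.modes},
                "scan_time_s": protocol.scan_time_s()}
            if config.noise_floor_trials >= 2:
                ref_img = recon.reconstruct(
                    acq.simulate_scan(phantom, protocol,
                                      ShotTimeline.null(protocol.n_shots()),
                                      0.0, 0, ordering=config.ordering,
                                      dtype=config.dtype, base_images=base),
                    "uncorrected")
                sig_img = float(np.sqrt(np.prod(protocol.accel)) * sigma_k)
                floors = reliability.monte_carlo_noise_floor(
                    ref_img, sig_img, config.noise_floor_trials,
                    metrics=tuple(m for m in config.metrics
                                  if m in ("nad", "dr2s", "df")),
                    seed=config.phantom_seed + 13, mask=phantom.mask,
                    n_averages=protocol.repetitions)
                entry["noise_floor_medians"] = {
                    m: float(np.median(v)) for m, v in floors.items()}
            report["protocols"][name] = entry
        except Exception as exc:   # isolate per protocol
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "manifest.json").write_text(config.to_json())
    return report


# ----------------------------------------------------------------------
# NIfTI plumbing
# ----------------------------------------------------------------------

def save_nifti(volume: np.ndarray, voxel_mm, path) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine),
             str(path))


def nifti_roundtrip(path):
    """Load a NIfTI volume: (data, affine, voxel_mm).

    Raises a clear format error for malformed files.
    """
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"not a readable NIfTI file: {path}: {exc}") from exc
    voxel = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, img.affine, voxel
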