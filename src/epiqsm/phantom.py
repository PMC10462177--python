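"""Digital brain phantoms and physical forward quantities.

Ground-truth proton density (M0), effective transverse relaxation rate (R2*),
and magnetic susceptibility (chi) maps are laid out as an ellipsoidal brain
(white-matter background) containing spherical deep grey-matter nuclei and
white-matter ROI spheres, wrapped in a CSF shell and surrounded by
zero-signal background.  Geometry is analytic (ellipsoid + spheres) so every
ROI has an exact ground truth.

The susceptibility-induced off-resonance field is computed with the standard
k-space dipole kernel D(k) = 1/3 - kz^2/|k|^2 (D(0) := 0, so the field has
zero spatial mean), with B0 along the z axis.  Susceptibility is stored in
ppb and converted to Hz with gamma = 42.58 MHz/T.

Shot-resolved physiological state (global B0 offset, spatially linear B0
gradient, rigid translation) is modelled as a random-walk drift plus a
sinusoidal respiratory term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GAMMA_HZ_PER_T = 42.58e6
"""Gyromagnetic ratio of the proton, Hz/T (gamma/2pi)."""

# Tissue ground-truth values (literature-typical at 3 T; the study population
# itself is healthy adults, for which deep grey nuclei span roughly the
# chi/R2* ranges below).
_WM_CHI_PPB = -30.0
_WM_R2S = 21.0
_CSF_CHI_PPB = 0.0
_CSF_R2S = 1.0

LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_CSF = 2
GM_LABELS = (10, 11, 12, 13, 14)
GM_NAMES = ("substantia_nigra", "red_nucleus", "putamen",
            "globus_pallidus", "caudate_nucleus")
WM_ROI_LABELS = (20, 21, 22)
WM_ROI_NAMES = ("splenium", "internal_capsule", "optic_radiation")


@dataclass
class Phantom:
    """Ground-truth 3D maps on a regular grid.

    Attributes
    ----------
    m0 : proton-density map, arbitrary units >= 0 (0 outside the head).
    r2s : R2* map in 1/s, >= 0 everywhere.
    chi : susceptibility map in ppb (0 outside the head support).
    labels : integer tissue-class map.
    mask : brain mask (bool).
    voxel_mm : per-axis voxel size in mm.
    b0_tesla : main field strength in T.
    seed : generator seed recorded for provenance.
    """

    m0: np.ndarray
    r2s: np.ndarray
    chi: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    voxel_mm: np.ndarray
    b0_tesla: float = 3.0
    seed: int | None = None
    roi_truth: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.m0.shape)


@dataclass
class ShotTimeline:
    """Per-TR physiological state of a scan.

    global_hz : per-shot global B0 offset (Hz).
    grad_hz_per_mm : per-shot (3,) spatially linear B0 coefficient (Hz/mm).
    trans_mm : per-shot (3,) rigid translation (mm).
    """

    global_hz: np.ndarray
    grad_hz_per_mm: np.ndarray
    trans_mm: np.ndarray

    def __post_init__(self):
        self.global_hz = np.atleast_1d(np.asarray(self.global_hz, dtype=float))
        self.grad_hz_per_mm = np.asarray(self.grad_hz_per_mm, dtype=float).reshape(-1, 3)
        self.trans_mm = np.asarray(self.trans_mm, dtype=float).reshape(-1, 3)
        n = self.n_shots
        if self.grad_hz_per_mm.shape[0] != n or self.trans_mm.shape[0] != n:
            raise ValueError("timeline arrays must share length n_shots")
        for arr in (self.global_hz, self.grad_hz_per_mm, self.trans_mm):
            if not np.all(np.isfinite(arr)):
                raise ValueError("timeline values must be finite")

    @property
    def n_shots(self) -> int:
        return self.global_hz.shape[0]

    def is_null(self) -> bool:
        return (not self.global_hz.any() and not self.grad_hz_per_mm.any()
                and not self.trans_mm.any())

    def has_gradient(self) -> bool:
        return bool(self.grad_hz_per_mm.any())

    @classmethod
    def null(cls, n_shots: int) -> "ShotTimeline":
        return cls(np.zeros(n_shots), np.zeros((n_shots, 3)), np.zeros((n_shots, 3)))

    def slice(self, start: int, stop: int) -> "ShotTimeline":
        return ShotTimeline(self.global_hz[start:stop],
                            self.grad_hz_per_mm[start:stop],
                            self.trans_mm[start:stop])


@dataclass
class FieldMap:
    """Off-resonance map in Hz with its voxel size in mm."""

    hz: np.ndarray
    voxel_mm: np.ndarray


# ----------------------------------------------------------------------
# Phantom construction
# ----------------------------------------------------------------------

# ROI layout in fractions of the grid extent (centre-relative), radii as a
# fraction of the smallest half-extent.  Positions are jittered slightly by
# the seed, values are drawn per-seed from the stated physiological ranges.
_GM_LAYOUT = (
    # name, (cx, cy, cz) fractional offsets from centre, radius fraction
    ("substantia_nigra", (-0.08, -0.05, -0.08), 0.10),
    ("red_nucleus", (0.08, -0.05, -0.08), 0.10),
    ("putamen", (-0.21, 0.06, 0.02), 0.12),
    ("globus_pallidus", (0.21, 0.06, 0.02), 0.12),
    ("caudate_nucleus", (0.0, 0.10, 0.07), 0.12),
)
_WM_LAYOUT = (
    ("splenium", (0.0, -0.10, 0.05), 0.11),
    ("internal_capsule", (-0.16, 0.09, -0.05), 0.10),
    ("optic_radiation", (0.16, 0.09, -0.05), 0.10),
)
# chi (ppb) and R2* (1/s) ranges per deep grey nucleus
_GM_CHI_RANGE = (50.0, 180.0)
_GM_R2S_RANGE = (30.0, 80.0)
_WM_ROI_CHI_RANGE = (-45.0, -15.0)
_WM_ROI_R2S_RANGE = (18.0, 26.0)

# Semi-axes as fractions of the full grid extent.  The head (CSF outer
# boundary) fits within half the FOV along both phase-encode axes (y, z),
# i.e. the FOV phase-encode-oversamples the head by the 2x2 acceleration
# factor, so the uniform-coil zero-filled reconstruction of the regular
# CAIPI lattice is alias-free and the reliability analysis stays
# independent of parallel-imaging machinery.
_BRAIN_SEMI_FRAC = np.array([0.40, 0.218, 0.218])
_HEAD_SEMI_FRAC = _BRAIN_SEMI_FRAC * 1.12         # CSF shell outer boundary


def _centered_coords(shape, voxel_mm):
    """Physical coordinates (mm) of voxel centres, origin at grid centre."""
    return [(np.arange(n) - n / 2.0) * d for n, d in zip(shape, voxel_mm)]


def build_phantom(shape=(64, 64, 48), voxel_mm=(3.0, 3.0, 3.0), seed: int = 0,
                  b0_tesla: float = 3.0) -> Phantom:
    """Build a deterministic ellipsoid-plus-spheres brain phantom.

    Parameters
    ----------
    shape : grid size, each dimension >= 32.
    voxel_mm : physical voxel size (> 0 per axis).
    seed : drives ROI value draws and sub-voxel position jitter; the same
        seed always yields a bitwise-identical phantom.

    Raises
    ------
    ValueError
        If the grid is too small to place all ROIs (names the first
        unplaceable ROI).
    """
    shape = tuple(int(n) for n in shape)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if len(shape) != 3 or any(n < 32 for n in shape):
        raise ValueError("phantom grid must be 3D with each dimension >= 32")
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel sizes must be positive")

    rng = np.random.default_rng(seed)
    extent = np.asarray(shape) * voxel_mm          # mm
    xs, ys, zs = _centered_coords(shape, voxel_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    brain_semi = _BRAIN_SEMI_FRAC * extent
    head_semi = _HEAD_SEMI_FRAC * extent
    brain = ((X / brain_semi[0]) ** 2 + (Y / brain_semi[1]) ** 2
             + (Z / brain_semi[2]) ** 2) <= 1.0
    head = ((X / head_semi[0]) ** 2 + (Y / head_semi[1]) ** 2
            + (Z / head_semi[2]) ** 2) <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    labels[head] = LABEL_CSF
    labels[brain] = LABEL_WM

    m0 = np.zeros(shape)
    r2s = np.zeros(shape)
    chi = np.zeros(shape)
    m0[head] = 1.0                      # CSF
    r2s[head] = _CSF_R2S
    chi[head] = _CSF_CHI_PPB
    m0[brain] = 0.85                    # WM background
    r2s[brain] = _WM_R2S
    chi[brain] = _WM_CHI_PPB

    roi_truth = {}
    min_half = float(np.min(extent) / 2.0)

    def place(name, label, frac_centre, frac_radius, chi_rng, r2s_rng, m0_val):
        centre = np.asarray(frac_centre) * extent
        centre = centre + rng.uniform(-0.3, 0.3, 3) * voxel_mm  # sub-voxel jitter
        radius = frac_radius * min_half
        if radius < 2.0 * float(np.max(voxel_mm)):
            raise ValueError(
                f"grid too small to place ROI '{name}': radius {radius:.1f} mm "
                f"< 2 voxels")
        # sphere must lie inside the brain ellipsoid
        r_norm = np.linalg.norm(centre / brain_semi) + radius / np.min(brain_semi)
        if r_norm > 1.0:
            raise ValueError(f"grid too small to place ROI '{name}' inside brain")
        sphere = ((X - centre[0]) ** 2 + (Y - centre[1]) ** 2
                  + (Z - centre[2]) ** 2) <= radius ** 2
        chi_v = rng.uniform(*chi_rng)
        r2s_v = rng.uniform(*r2s_rng)
        labels[sphere] = label
        chi[sphere] = chi_v
        r2s[sphere] = r2s_v
        m0[sphere] = m0_val
        roi_truth[name] = {"label": int(label), "chi_ppb": float(chi_v),
                           "r2s_per_s": float(r2s_v),
                           "centre_mm": centre.tolist(),
                           "radius_mm": float(radius)}

    for (name, c, r), label in zip(_GM_LAYOUT, GM_LABELS):
        place(name, label, c, r, _GM_CHI_RANGE, _GM_R2S_RANGE, 0.80)
    for (name, c, r), label in zip(_WM_LAYOUT, WM_ROI_LABELS):
        place(name, label, c, r, _WM_ROI_CHI_RANGE, _WM_ROI_R2S_RANGE, 0.85)

    mask = head.copy()
    return Phantom(m0=m0, r2s=r2s, chi=chi, labels=labels, mask=mask,
                   voxel_mm=voxel_mm, b0_tesla=float(b0_tesla), seed=int(seed),
                   roi_truth=roi_truth)


# ----------------------------------------------------------------------
# Dipole forward model
# ----------------------------------------------------------------------

def dipole_kernel(shape, voxel_mm) -> np.ndarray:
    """k-space dipole kernel D(k) = 1/3 - kz^2/|k|^2 with D(0) = 0.

    z is the B0 axis.  Defined on the unshifted (numpy fft) grid.
    """
    kx = np.fft.fftfreq(shape[0], d=voxel_mm[0])
    ky = np.fft.fftfreq(shape[1], d=voxel_mm[1])
    kz = np.fft.fftfreq(shape[2], d=voxel_mm[2])
    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij")
    k2 = KX ** 2 + KY ** 2 + KZ ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 / 3.0 - KZ ** 2 / k2
    D[0, 0, 0] = 0.0
    return D


def chi_to_field(phantom: Phantom) -> FieldMap:
    """Susceptibility-induced off-resonance field (Hz).

    field = B0 * gamma * 1e-9 * IFT[D(k) * FT(chi_ppb)].  The D(0) := 0
    convention removes the spatial mean, so the returned map is zero-mean
    over the full grid.
    """
    if not np.all(np.isfinite(phantom.chi)):
        raise ValueError("chi must be finite everywhere")
    D = dipole_kernel(phantom.shape, phantom.voxel_mm)
    f = np.fft.ifftn(D * np.fft.fftn(phantom.chi)).real
    hz = phantom.b0_tesla * GAMMA_HZ_PER_T * 1e-9 * f
    return FieldMap(hz=hz, voxel_mm=np.asarray(phantom.voxel_mm, dtype=float))


# ----------------------------------------------------------------------
# Physiological timeline
# ----------------------------------------------------------------------

def sample_physio_timeline(n_shots: int,
                           drift_sd_hz: float = 0.2,
                           resp_amp_hz: float = 1.0,
                           resp_period_s: float = 4.0,
                           tr_s: float = 0.064,
                           grad_sd_hz_per_mm: float = 0.002,
                           trans_sd_mm: float = 0.02,
                           seed: int = 0) -> ShotTimeline:
    """Sample a physiological B0/motion timeline.

    The global offset is a Gaussian random walk (``drift_sd_hz`` per shot)
    plus a respiratory sinusoid ``resp_amp_hz * sin(2*pi*t/resp_period_s)``
    with t = shot_index * tr_s.  The linear-gradient coefficients (Hz/mm per
    axis) and translations (mm per axis) are independent random walks.
    Reproducible for a fixed seed.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    for name, v in (("drift_sd_hz", drift_sd_hz), ("resp_amp_hz", resp_amp_hz),
                    ("grad_sd_hz_per_mm", grad_sd_hz_per_mm),
                    ("trans_sd_mm", trans_sd_mm)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if resp_period_s <= 0 or tr_s <= 0:
        raise ValueError("resp_period_s and tr_s must be > 0")

    rng = np.random.default_rng(seed)
    t = np.arange(n_shots) * tr_s
    drift = np.cumsum(rng.normal(0.0, drift_sd_hz, n_shots)) if drift_sd_hz else np.zeros(n_shots)
    resp = resp_amp_hz * np.sin(2.0 * np.pi * t / resp_period_s)
    grad = (np.cumsum(rng.normal(0.0, grad_sd_hz_per_mm, (n_shots, 3)), axis=0)
            if grad_sd_hz_per_mm else np.zeros((n_shots, 3)))
    trans = (np.cumsum(rng.normal(0.0, trans_sd_mm, (n_shots, 3)), axis=0)
             if trans_sd_mm else np.zeros((n_shots, 3)))
    return ShotTimeline(drift + resp, grad, trans)


# ----------------------------------------------------------------------
# Persistence (NIfTI maps + JSON sidecar)
# ----------------------------------------------------------------------

def save_phantom(phantom: Phantom, out_dir) -> None:
    """Write the phantom maps as NIfTI-1 volumes plus a JSON sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.voxel_mm) + [1.0])
    for name in ("m0", "r2s", "chi"):
        nib.save(nib.Nifti1Image(getattr(phantom, name).astype(np.float64), affine),
                 out / f"{name}.nii")
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int32), affine),
             out / "labels.nii")
    nib.save(nib.Nifti1Image(phantom.mask.astype(np.uint8), affine),
             out / "mask.nii")
    sidecar = {"voxel_mm": phantom.voxel_mm.tolist(),
               "b0_tesla": phantom.b0_tesla,
               "seed": phantom.seed,
               "labels": {"background": LABEL_BACKGROUND, "wm": LABEL_WM,
                          "csf": LABEL_CSF,
                          **{n: l for n, l in zip(GM_NAMES, GM_LABELS)},
                          **{n: l for n, l in zip(WM_ROI_NAMES, WM_ROI_LABELS)}},
               "roi_truth": phantom.roi_truth}
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(in_dir) -> Phantom:
    import nibabel as nib

    d = Path(in_dir)
    sidecar = json.loads((d / "phantom.json").read_text())
    vols = {name: np.asarray(nib.load(d / f"{name}.nii").dataobj)
            for name in ("m0", "r2s", "chi", "labels", "mask")}
    return Phantom(m0=vols["m0"].astype(float), r2s=vols["r2s"].astype(float),
                   chi=vols["chi"].astype(float),
                   labels=vols["labels"].astype(np.int32),
                   mask=vols["mask"].astype(bool),
                   voxel_mm=np.asarray(sidecar["voxel_mm"], dtype=float),
                   b0_tesla=float(sidecar["b0_tesla"]),
                   seed=sidecar.get("seed"),
                   roi_truth=sidecar.get("roi_truth", {}))
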