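"""Quantification of R2*, tissue frequency and susceptibility.

The chain mirrors a standard QSM processing pipeline: mono-exponential
magnitude fitting for R2*; temporal (and, when needed, spatial) phase
unwrapping followed by magnitude-weighted multi-echo combination for the
tissue frequency shift f; VSHARP spherical-mean-value filtering for
background-field removal; and a closed-form dipole inversion (thresholded
k-space division or Tikhonov) for chi, referenced to the brain-mask mean.
The path-based unwrapper, LBV stage and iterative structure-prior dipole
inversions used by full QSM toolboxes are deliberately replaced by these
simpler standard components; the substitutions are documented in the
methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import GAMMA_HZ_PER_T, dipole_kernel


@dataclass
class QuantMaps:
    """Fitted quantitative maps with diagnostics.

    chi_hat is in ppb and zero-mean over ``mask`` (brain-mean reference);
    r2s_hat is clipped at 0 with the clip count logged in diagnostics.
    """

    r2s_hat: np.ndarray
    s0_hat: np.ndarray
    f_hat: np.ndarray
    chi_hat: np.ndarray
    mask: np.ndarray
    fit_diagnostics: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# R2* mono-exponential fit
# ----------------------------------------------------------------------

def _loglinear_fit(mag: np.ndarray, te: np.ndarray):
    """Magnitude-weighted log-linear fit; returns (r2s, s0)."""
    eps = np.finfo(float).tiny
    logm = np.log(np.maximum(mag, eps))
    w = mag ** 2
    sw = w.sum(axis=-1)
    sw = np.where(sw > 0, sw, 1.0)
    mt = (w * te).sum(axis=-1) / sw
    ml = (w * logm).sum(axis=-1) / sw
    cov = (w * (te - mt[..., None]) * (logm - ml[..., None])).sum(axis=-1)
    var = (w * (te - mt[..., None]) ** 2).sum(axis=-1)
    var = np.where(var > 0, var, 1.0)
    slope = cov / var
    r2s = -slope
    s0 = np.exp(ml - slope * mt)
    return r2s, s0


def fit_r2star(magnitude: np.ndarray, te_s, mask: np.ndarray,
               max_iter: int = 25, tol: float = 1e-8,
               snr_warn_threshold: float = 10.0):
    """Per-voxel nonlinear least squares of S0 * exp(-R2* TE).

    ``magnitude`` is (..., n_echoes) with non-negative values.  The fit is
    initialized from the magnitude-weighted log-linear estimate and
    refined by vectorized Gauss-Newton; voxels that do not converge fall
    back to the log-linear estimate and are flagged.  All-zero voxels
    inside the mask get NaN and are excluded from downstream statistics.

    Returns (r2s_hat, s0_hat, diagnostics); diagnostics hold the residual
    norm, convergence flags, the number of clipped negative R2* values
    and the valid-voxel mask.
    """
    mag = np.asarray(magnitude, dtype=float)
    te = np.asarray(te_s, dtype=float)
    if mag.shape[-1] != te.shape[0]:
        raise ValueError("last axis of magnitude must match the TE list")
    if te.shape[0] < 2:
        raise ValueError("at least two echoes are required")
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    shape = mag.shape[:-1]
    mask = np.asarray(mask, dtype=bool)

    m = mag[mask]                               # (nvox, ne)
    dead = ~(m.max(axis=-1) > 0)
    r0, s0_init = _loglinear_fit(m, te)
    r = np.clip(r0, 0.0, None)
    s0 = np.maximum(s0_init, np.finfo(float).tiny)

    converged = np.zeros(m.shape[0], dtype=bool)
    active = ~dead
    r_cap = 10.0 / max(te[1] - te[0], 1e-6)     # decay far beyond resolvable
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            if not active.any():
                break
            e = np.exp(-np.outer(r[active], te))     # (na, ne)
            f = s0[active, None] * e
            res = m[active] - f
            j11 = (e * e).sum(axis=-1)
            j12 = (-s0[active, None] * te * e * e).sum(axis=-1)
            j22 = ((s0[active, None] * te * e) ** 2).sum(axis=-1)
            b1 = (e * res).sum(axis=-1)
            b2 = (-s0[active, None] * te * e * res).sum(axis=-1)
            det = j11 * j22 - j12 * j12
            det = np.where(np.abs(det) > 1e-300, det, np.inf)
            ds0 = (j22 * b1 - j12 * b2) / det
            dr = (j11 * b2 - j12 * b1) / det
            s0a, ra = s0[active] + ds0, r[active] + dr
            step = np.abs(ds0) / np.maximum(s0[active], 1e-30) + np.abs(dr)
            idx = np.flatnonzero(active)
            # diverging voxels keep their previous value and are retired
            bad = ~np.isfinite(s0a) | ~np.isfinite(ra) | (np.abs(ra) > r_cap)
            s0[idx[~bad]] = s0a[~bad]
            r[idx[~bad]] = ra[~bad]
            done = (step < tol) & ~bad
            converged[idx[done]] = True
            active[idx[done | bad]] = False

    # non-converged voxels fall back to the log-linear estimate
    fallback = ~converged & ~dead
    r[fallback] = r0[fallback]
    s0[fallback] = s0_init[fallback]
    clipped = int(np.sum(r < 0))
    r = np.clip(r, 0.0, None)

    resid = np.linalg.norm(m - s0[:, None] * np.exp(-np.outer(r, te)), axis=-1)
    r[dead] = np.nan
    s0[dead] = np.nan

    r2s_hat = np.full(shape, np.nan)
    s0_hat = np.full(shape, np.nan)
    resid_map = np.full(shape, np.nan)
    conv_map = np.zeros(shape, dtype=bool)
    r2s_hat[mask] = r
    s0_hat[mask] = s0
    resid_map[mask] = resid
    tmp = np.zeros(m.shape[0], dtype=bool)
    tmp[:] = converged
    conv_map[mask] = tmp

    last_echo_snr = np.nanmedian(m[~dead][:, -1]) / max(
        np.median(resid[~dead]) / np.sqrt(max(te.shape[0] - 2, 1)), 1e-30) \
        if (~dead).any() else np.inf
    if last_echo_snr < snr_warn_threshold:
        warnings.warn("last-echo SNR below 10: magnitude-only fitting may "
                      "underestimate R2*", RuntimeWarning, stacklevel=2)

    diagnostics = {"residual_norm": resid_map, "converged": conv_map,
                   "n_clipped_negative": clipped,
                   "n_dead_voxels": int(dead.sum()),
                   "valid": mask & ~np.isnan(r2s_hat)}
    return r2s_hat, s0_hat, diagnostics


# ----------------------------------------------------------------------
# Frequency mapping
# ----------------------------------------------------------------------

def spatial_unwrap(phase_3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Quality-guided spatial unwrapping within a mask.

    Wraps ``skimage.restoration.unwrap_phase`` on the masked volume;
    disconnected mask components are unwrapped independently (each keeps
    its own 2 pi k offset, which is logged).  The output equals the input
    modulo 2 pi at every voxel.
    """
    from skimage.restoration import unwrap_phase

    phase = np.asarray(phase_3d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _, n_comp = ndimage.label(mask)
    if n_comp > 1:
        warnings.warn(f"mask has {n_comp} disconnected components; each is "
                      "unwrapped with an independent 2*pi offset",
                      RuntimeWarning, stacklevel=2)
    ma = np.ma.masked_array(phase, mask=~mask)
    out = np.asarray(unwrap_phase(ma))
    result = phase.copy()
    result[mask] = out[mask]
    return result


def _has_spatial_wraps(phase: np.ndarray, mask: np.ndarray) -> bool:
    for ax in range(3):
        d = np.diff(phase, axis=ax)
        m = np.logical_and(np.take(mask, range(mask.shape[ax] - 1), axis=ax),
                           np.take(mask, range(1, mask.shape[ax]), axis=ax))
        if np.any(np.abs(d[m]) > np.pi):
            return True
    return False


def frequency_map(phase: np.ndarray, te_s, magnitude: np.ndarray,
                  mask: np.ndarray, spatial: str | bool = "auto") -> np.ndarray:
    """Tissue frequency shift f (Hz) by weighted multi-echo combination.

    Echo phases are unwrapped temporally (each echo against the linear
    prediction from earlier echoes); spatial unwrapping runs first when
    within-echo wraps are detected (or when forced).  The frequency is the
    weighted least-squares slope of phase vs. 2 pi TE with weights
    magnitude^2 * TE, fitted with an intercept to absorb any echo-time-
    independent phase offset.
    """
    te = np.asarray(te_s, dtype=float)
    if te.shape[0] < 2:
        raise ValueError("at least two echoes are required")
    phase = np.asarray(phase, dtype=float).copy()
    mag = np.asarray(magnitude, dtype=float)
    mask = np.asarray(mask, dtype=bool)

    ne = te.shape[0]
    if spatial is True or (spatial == "auto" and any(
            _has_spatial_wraps(phase[..., e], mask) for e in range(ne))):
        for e in range(ne):
            phase[..., e] = spatial_unwrap(phase[..., e], mask)

    # temporal unwrapping against the prediction from earlier echoes
    for e in range(1, ne):
        if e == 1:
            pred = phase[..., 0] * (te[1] / te[0])
        else:
            slope = (phase[..., e - 1] - phase[..., e - 2]) / (te[e - 1] - te[e - 2])
            pred = phase[..., e - 1] + slope * (te[e] - te[e - 1])
        phase[..., e] += 2.0 * np.pi * np.round((pred - phase[..., e]) / (2.0 * np.pi))

    w = mag ** 2 * te
    wsum = w.sum(axis=-1)
    wsum = np.where(wsum > 0, wsum, 1.0)
    x = 2.0 * np.pi * te
    xbar = (w * x).sum(axis=-1) / wsum
    ybar = (w * phase).sum(axis=-1) / wsum
    cov = (w * (x - xbar[..., None]) * (phase - ybar[..., None])).sum(axis=-1)
    var = (w * (x - xbar[..., None]) ** 2).sum(axis=-1)
    var = np.where(var > 0, var, 1.0)
    f = cov / var
    f[~mask] = 0.0
    return f


# ----------------------------------------------------------------------
# Background field removal (VSHARP)
# ----------------------------------------------------------------------

def _sphere_kernel_ft(shape, voxel_mm, radius_mm) -> np.ndarray:
    """FT of the normalized solid-sphere mean kernel (analytic form).

    S(k) = 3 (sin u - u cos u) / u^3 with u = 2 pi |k| R and S(0) = 1 —
    the continuum Fourier transform of a uniform ball, which preserves
    the spherical mean-value property far better than a voxelized ball.
    """
    ks = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, voxel_mm)]
    KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
    u = 2.0 * np.pi * np.sqrt(KX ** 2 + KY ** 2 + KZ ** 2) * radius_mm
    with np.errstate(invalid="ignore", divide="ignore"):
        S = 3.0 * (np.sin(u) - u * np.cos(u)) / u ** 3
    S[0, 0, 0] = 1.0
    return S


def _ball_structure(voxel_mm, radius_mm):
    r_vox = np.maximum(radius_mm / np.asarray(voxel_mm), 1e-9)
    half = np.ceil(r_vox).astype(int)
    grids = [np.arange(-h, h + 1) for h in half]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    return ((X / r_vox[0]) ** 2 + (Y / r_vox[1]) ** 2
            + (Z / r_vox[2]) ** 2) <= 1.0


def vsharp_background_removal(f_total: np.ndarray, mask: np.ndarray,
                              voxel_mm, radii_mm=None,
                              threshold: float = 0.05):
    """Variable-radius spherical-mean-value background-field removal.

    Applies the SMV high-pass (delta - S_r) * f with the largest feasible
    sphere radius per voxel, then deconvolves by (1 - S_rmin(k)) with
    truncated inverse filtering (``threshold``).  Returns
    (f_tissue_hz, eroded_mask) where the eroded mask is the region where
    at least the smallest sphere fits inside the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    f_total = np.asarray(f_total, dtype=float)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if radii_mm is None:
        radii_mm = (np.arange(6, 0, -1) * float(voxel_mm.min())).tolist()
    radii = sorted(radii_mm, reverse=True)
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly descending")

    Fk = np.fft.fftn(f_total * mask)
    highpass = np.zeros_like(f_total)
    assigned = np.zeros(mask.shape, dtype=bool)
    S_dec = None
    for r in radii:
        S = _sphere_kernel_ft(mask.shape, voxel_mm, r)
        if S_dec is None:
            S_dec = S            # deconvolve with the largest radius
        # feasibility: the sphere lies entirely inside the mask
        feasible = ndimage.binary_erosion(mask, _ball_structure(voxel_mm, r))
        take = feasible & ~assigned
        if take.any():
            h = f_total - np.fft.ifftn(Fk * S).real
            highpass[take] = h[take]
            assigned |= take
    eroded_mask = assigned
    if not eroded_mask.any():
        raise ValueError("mask is smaller than the smallest SMV sphere")

    # truncated inverse of (1 - S): the largest-radius kernel governs most
    # of the eroded region; bins below the threshold (very low spatial
    # frequencies, which belong to the removed background) are zeroed
    denom = 1.0 - S_dec
    inv = np.where(np.abs(denom) > threshold,
                   1.0 / np.where(denom == 0, 1.0, denom), 0.0)
    f_tissue = np.fft.ifftn(np.fft.fftn(highpass * eroded_mask) * inv).real
    f_tissue *= eroded_mask
    return f_tissue, eroded_mask


# ----------------------------------------------------------------------
# Dipole inversion
# ----------------------------------------------------------------------

def dipole_inversion(f_tissue_hz: np.ndarray, mask: np.ndarray,
                     b0_tesla: float, voxel_mm, method: str = "tkd",
                     param: float = 0.2) -> np.ndarray:
    """Closed-form dipole inversion, output in ppb (brain-mean referenced).

    ``tkd``: thresholded k-space division with threshold ``param`` in
    (0, 1]; ``tikhonov``: chi_k = D / (D^2 + lambda) with lambda =
    ``param`` >= 0.  The brain-mask mean is subtracted afterwards
    (tissue-reference convention).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    f = np.asarray(f_tissue_hz, dtype=float) * mask
    D = dipole_kernel(mask.shape, voxel_mm)
    Fk = np.fft.fftn(f / (b0_tesla * GAMMA_HZ_PER_T * 1e-9))
    if method == "tkd":
        if not 0 < param <= 1:
            raise ValueError("tkd threshold must be in (0, 1]")
        Dsafe = np.where(np.abs(D) >= param, D,
                         param * np.where(D >= 0, 1.0, -1.0))
        chi = np.fft.ifftn(Fk / Dsafe).real
        # amplitude correction: clipping the kernel attenuates the point
        # spread function's central value by mean(D / Dsafe); rescale so
        # compact sources keep their magnitude
        chi /= float(np.mean(D / Dsafe))
    elif method == "tikhonov":
        if param < 0:
            raise ValueError("tikhonov lambda must be >= 0")
        chi = np.fft.ifftn(Fk * D / (D ** 2 + param)).real
    else:
        raise ValueError(f"unknown method {method!r}")
    chi = chi * mask
    chi[mask] -= chi[mask].mean()
    return chi


# ----------------------------------------------------------------------
# Convenience chain
# ----------------------------------------------------------------------

def quantify_image(image, mask: np.ndarray, b0_tesla: float = 3.0,
                   vsharp_radii_mm=None, vsharp_threshold: float = 0.05,
                   inversion: str = "tkd", inversion_param: float = 0.2,
                   compute_chi: bool = True) -> QuantMaps:
    """Run the full quantification chain on one multi-echo image."""
    mag = np.abs(image.data)
    phase = np.angle(image.data)
    r2s, s0, diag = fit_r2star(mag, image.te_s, mask)
    f_total = frequency_map(phase, image.te_s, mag, mask)
    f_tissue, eroded = vsharp_background_removal(
        f_total, mask, image.voxel_mm, vsharp_radii_mm, vsharp_threshold)
    if compute_chi:
        chi = dipole_inversion(f_tissue, eroded, b0_tesla, image.voxel_mm,
                               inversion, inversion_param)
    else:
        chi = np.zeros_like(f_tissue)
    return QuantMaps(r2s_hat=r2s, s0_hat=s0, f_hat=f_tissue, chi_hat=chi,
                     mask=eroded, fit_diagnostics=diag)
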