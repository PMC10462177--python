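"""Test-retest reliability statistics.

The central metric for magnitude images is the normalized absolute
difference (NAD): |m1 - m2| divided by the pair mean, voxel by voxel.
Quantitative maps are compared by the voxelwise absolute inter-scan
difference |dR2*|, |df|, |dchi|.  Headline scalars are medians (the CDF
value at fraction 0.5); averaging curves report the median |d| as a
function of the number of repetition averages, where averaging is done
over the per-repetition quantitative maps, never over the complex data.
Monte Carlo thermal-noise floors are obtained by adding circular complex
Gaussian noise to a reference image pair and running the same
quantification; chi is excluded from the noise floor because its noise
response is specific to the dipole-inversion regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

# median of |N(0, 1)| — folded-normal half-width used by closed-form
# noise-floor oracles: median|X1 - X2| = MEDIAN_ABS_NORMAL * sqrt(2) * sd
MEDIAN_ABS_NORMAL = float(stats.norm.ppf(0.75))


@dataclass
class ReliabilityReport:
    """Maps, CDFs, medians, curves and ROI consistency of one comparison."""

    nad: dict = field(default_factory=dict)
    abs_diff: dict = field(default_factory=dict)
    cdf: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)
    averaging_curve: dict = field(default_factory=dict)
    noise_floor: dict = field(default_factory=dict)
    roi_table: object = None


# ----------------------------------------------------------------------
# Voxelwise metrics
# ----------------------------------------------------------------------

def nad_map(m1: np.ndarray, m2: np.ndarray, mask: np.ndarray,
            eps_rel: float = 1e-12):
    """Normalized absolute difference |m1 - m2| / ((m1 + m2)/2).

    Voxels whose pair mean is below ``eps_rel`` times the grid maximum
    are excluded (NaN) and counted.  Works on 3D maps or (..., echo)
    stacks (NAD is computed per echo).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("maps must share a grid")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    mean = 0.5 * (m1 + m2)
    eps = eps_rel * max(m1.max(), m2.max())
    ok = mean > eps
    with np.errstate(invalid="ignore", divide="ignore"):
        nad = np.abs(m1 - m2) / mean
    nad[~ok] = np.nan
    if m1.ndim == mask.ndim:
        nad[~mask] = np.nan
        n_excluded = int((mask & ~ok).sum())
    else:
        nad[~mask, ...] = np.nan
        n_excluded = int((mask[..., None] & ~ok).sum())
    return nad, n_excluded


def interscan_abs_diff(map1: np.ndarray, map2: np.ndarray,
                       mask: np.ndarray) -> np.ndarray:
    """Voxelwise |map1 - map2| restricted to the mask (NaN elsewhere)."""
    map1 = np.asarray(map1, dtype=float)
    map2 = np.asarray(map2, dtype=float)
    if map1.shape != map2.shape:
        raise ValueError("maps must share a grid")
    mask = np.asarray(mask, dtype=bool)
    out = np.abs(map1 - map2)
    out[~mask] = np.nan
    return out


def masked_median(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    return float(np.median(v))


def empirical_cdf(values: np.ndarray, mask: np.ndarray | None = None):
    """Right-continuous empirical CDF and its median.

    Returns (sorted_values, cumulative_fractions, median); the median is
    the CDF-0.5 point with linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty input")
    s = np.sort(v)
    frac = np.arange(1, s.size + 1) / s.size
    return s, frac, float(np.median(s))


# ----------------------------------------------------------------------
# Averaging and noise floors
# ----------------------------------------------------------------------

def averaging_curve(per_rep_maps_scan1, per_rep_maps_scan2, mask,
                    n_max: int | None = None) -> np.ndarray:
    """Median |d| of N-average maps vs. N.

    For each N the first N per-repetition maps of each scan are averaged
    (as maps, not as complex data), the inter-scan absolute difference is
    taken and its masked median reported.  Entry i corresponds to
    N = i + 1.
    """
    s1 = [np.asarray(m, dtype=float) for m in per_rep_maps_scan1]
    s2 = [np.asarray(m, dtype=float) for m in per_rep_maps_scan2]
    if not s1 or not s2:
        raise ValueError("both scans need at least one repetition map")
    if n_max is None:
        n_max = min(len(s1), len(s2))
    if n_max > min(len(s1), len(s2)):
        raise ValueError("N exceeds the available repetitions")
    out = np.empty(n_max)
    for n in range(1, n_max + 1):
        a = np.mean(s1[:n], axis=0)
        b = np.mean(s2[:n], axis=0)
        out[n - 1] = masked_median(interscan_abs_diff(a, b, mask))
    return out


def monte_carlo_noise_floor(reference, sigma: float, n_trials: int,
                            metrics=("nad", "dr2s", "df"), seed: int = 0,
                            mask: np.ndarray | None = None,
                            n_averages: int = 1) -> dict:
    """Thermal-noise floors by complex-noise Monte Carlo on a reference.

    Per trial, two independent scan sides are synthesized; each side is
    ``n_averages`` circular complex Gaussian noise realizations (complex
    SD ``sigma``) added to the reference multi-echo image.  The requested
    metrics are computed between the two sides — quantitative maps are
    fitted per realization and averaged as maps, magnitudes are averaged
    directly — and their masked medians collected.  chi is refused: its
    noise floor would be specific to the dipole-inversion regularization.
    """
    from .quantify import fit_r2star, frequency_map

    metrics = tuple(metrics)
    if "dchi" in metrics or "chi" in metrics:
        raise ValueError("chi is excluded from the noise-floor simulation: "
                         "its |dchi| depends on the dipole-inversion "
                         "regularization")
    bad = set(metrics) - {"nad", "dr2s", "df"}
    if bad:
        raise ValueError(f"unknown metrics: {sorted(bad)}")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")

    data = reference.data
    te = reference.te_s
    if mask is None:
        mask = np.abs(data[..., 0]) > 0.05 * np.abs(data[..., 0]).max()
    rng = np.random.default_rng(seed)
    out = {m: [] for m in metrics}

    def noisy():
        n = rng.normal(0.0, sigma / np.sqrt(2.0), size=(*data.shape, 2))
        return data + n[..., 0] + 1j * n[..., 1]

    for _ in range(n_trials):
        sides = [[noisy() for _ in range(n_averages)] for _ in range(2)]
        mags = [[np.abs(p) for p in side] for side in sides]
        if "nad" in metrics:
            avg = [np.mean(ms, axis=0).mean(axis=-1) for ms in mags]
            nad, _ = nad_map(avg[0], avg[1], mask)
            out["nad"].append(masked_median(nad))
        if "dr2s" in metrics:
            r = [np.mean([fit_r2star(m, te, mask)[0] for m in ms], axis=0)
                 for ms in mags]
            out["dr2s"].append(masked_median(
                interscan_abs_diff(r[0], r[1], mask)))
        if "df" in metrics:
            f = [np.mean([frequency_map(np.angle(p), te, m, mask)
                          for p, m in zip(side, ms)], axis=0)
                 for side, ms in zip(sides, mags)]
            out["df"].append(masked_median(
                interscan_abs_diff(f[0], f[1], mask)))
    return {m: np.asarray(v) for m, v in out.items()}


# ----------------------------------------------------------------------
# Inter-scan coregistration (translation-only)
# ----------------------------------------------------------------------

def coregister_translation(moving: np.ndarray, fixed: np.ndarray,
                           upsample: int = 50, min_peak: float = 0.05,
                           alias_vectors=None):
    """Subvoxel translation estimate and spline-resampled moving image.

    The shift is estimated by Fourier phase correlation with subpixel
    refinement and applied with cubic-spline resampling.  The same stored
    shift is meant to be reused for companion quantitative maps via
    :func:`apply_shift`.  On regularly undersampled (zero-filled) images
    the correlation is ambiguous modulo the replica lattice of the
    sampling pattern; ``alias_vectors`` (voxel displacement vectors of
    that lattice, including the CAIPI stagger) lets the estimator snap to
    the physically small shift by subtracting the nearest lattice vector.
    Returns (shift_voxels, resampled_moving).
    """
    from skimage.registration import phase_cross_correlation

    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("images must share a grid")
    shift, _, _ = phase_cross_correlation(fixed, moving,
                                          upsample_factor=upsample,
                                          normalization=None)
    if alias_vectors is not None:
        shift = _snap_to_lattice(shift, alias_vectors, moving.shape)
    denom = np.linalg.norm(fixed) * np.linalg.norm(moving)
    if denom == 0 or _corr_at_shift(moving, fixed, shift) < min_peak:
        import warnings
        warnings.warn("correlation peak below threshold; assuming zero shift",
                      RuntimeWarning, stacklevel=2)
        shift = np.zeros(moving.ndim)
    return shift, apply_shift(moving, shift)


def _snap_to_lattice(shift, alias_vectors, shape):
    """Subtract the replica-lattice vector nearest to the estimated shift."""
    shift = np.asarray(shift, dtype=float)
    n = np.asarray(shape, dtype=float)
    best = shift
    best_norm = np.inf
    for v in alias_vectors:
        v = np.asarray(v, dtype=float)
        # minimal signed representative of the candidate, per axis
        resid = shift - v
        resid = (resid + n / 2) % n - n / 2
        r = np.linalg.norm(resid)
        if r < best_norm:
            best, best_norm = resid, r
    return best


def replica_lattice(pattern_lines, ny: int, nz: int):
    """Voxel displacement vectors (0, dy, dz) of a sampling pattern's
    replica (ghost) lattice: all (dy, dz) whose phase is unity on every
    sampled (ky, kz) line."""
    ky = np.asarray(pattern_lines)[:, 0]
    kz = np.asarray(pattern_lines)[:, 1]
    vecs = []
    for dy in range(ny):
        ph_y = ky * dy / ny
        for dz in range(nz):
            ph = ph_y + kz * dz / nz
            if np.allclose(ph - np.round(ph), 0.0, atol=1e-9):
                vecs.append((0, dy, dz))
    return vecs


def _corr_at_shift(moving, fixed, shift) -> float:
    shifted = apply_shift(moving, shift)
    a = shifted - shifted.mean()
    b = fixed - fixed.mean()
    d = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / d) if d > 0 else 0.0


def apply_shift(volume: np.ndarray, shift_voxels, order: int = 3) -> np.ndarray:
    """Cubic-spline resampling by a (possibly subvoxel) translation."""
    if not np.any(np.asarray(shift_voxels)):
        return np.asarray(volume, dtype=float).copy()
    return ndimage.shift(np.asarray(volume, dtype=float), shift_voxels,
                         order=order, mode="grid-wrap")


# ----------------------------------------------------------------------
# ROI consistency
# ----------------------------------------------------------------------

def roi_consistency(map_a: np.ndarray, map_b: np.ndarray,
                    labels: np.ndarray, roi_ids):
    """Per-ROI means of two maps with their Pearson CC and OLS slope.

    Empty ROIs are excluded with a warning.  Returns a pandas DataFrame
    (roi, mean_a, mean_b) plus the scalar (cc, slope) of b-means
    regressed on a-means.
    """
    import warnings

    import pandas as pd

    roi_ids = list(roi_ids)
    if len(roi_ids) < 3:
        raise ValueError("at least 3 ROIs are required")
    rows = []
    for roi in roi_ids:
        sel = labels == roi
        a = np.asarray(map_a, dtype=float)[sel]
        b = np.asarray(map_b, dtype=float)[sel]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            warnings.warn(f"ROI {roi} is empty; excluded", RuntimeWarning,
                          stacklevel=2)
            continue
        rows.append({"roi": roi, "mean_a": a.mean(), "mean_b": b.mean()})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("fewer than 3 non-empty ROIs")
    cc = float(stats.pearsonr(table["mean_a"], table["mean_b"])[0])
    slope = float(np.polyfit(table["mean_a"], table["mean_b"], 1)[0])
    return table, cc, slope
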