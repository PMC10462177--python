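"""Acquisition protocols and shot-resolved k-space simulation.

Three protocol presets mirror the study design: a multi-echo 3D GRE (which
is an EPI protocol with EPI factor 1) and multi-shot multi-echo 3D EPI with
EPI factors 3 and 5.  Readout bandwidth grows with the EPI factor so the
total acquisition time per echo is matched, and the EPI scans are repeated
by the EPI factor so that averaging the repetitions returns the GRE SNR.

The simulator is an inverse-crime forward model: for every shot s and echo
e the image-domain signal

    m0 * exp(-R2* TE_e) * exp(i 2 pi (f_chi(r) + a_s + g_s . r) TE_e)

is translated by the shot's rigid translation (Fourier shift) and its
assigned CAIPI k-space lines are extracted from the unitary 3D DFT, with
i.i.d. circular complex Gaussian noise added per sample.  Because the
per-shot physiological phase is global + spatially linear it factorizes over
the axes, so each line is evaluated with dense matrix products (partial DFT
via BLAS) instead of one FFT per shot; the result is identical to the
FFT-based computation to rounding error, an order of magnitude faster on a
single core.

Axis conventions: readout = x, first phase encode = y, second phase
encode = z (also the B0 axis); k-space centre at index N/2 in the shifted
view; the DFT is unitary (1/sqrt(N) per axis).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .phantom import GAMMA_HZ_PER_T, FieldMap, Phantom, ShotTimeline, chi_to_field


# ----------------------------------------------------------------------
# Protocols
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """One acquisition configuration (SI units: s, Hz, mm, mT/m)."""

    name: str
    matrix: tuple[int, int, int]
    fov_mm: tuple[float, float, float]
    te_s: tuple[float, ...]
    tr_s: float
    flip_deg: float
    bw_hz_per_px: float
    epi_factor: int
    etl_s: float
    accel: tuple[int, int]
    caipi: bool
    repetitions: int
    gmax_mt_per_m: float = 40.0
    slew_mt_per_m_per_ms: float = 200.0

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.te_s, self.te_s[1:])):
            raise ValueError("echo times must be strictly increasing")
        if self.epi_factor < 1 or self.repetitions < 1:
            raise ValueError("epi_factor and repetitions must be >= 1")

    @property
    def n_echoes(self) -> int:
        return len(self.te_s)

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.asarray(self.fov_mm) / np.asarray(self.matrix)

    def n_lines(self) -> int:
        ry, rz = self.accel
        return (self.matrix[1] // ry) * (self.matrix[2] // rz)

    def n_shots(self) -> int:
        """Shots per repetition (ceil of lines / EPI factor)."""
        return -(-self.n_lines() // self.epi_factor)

    def scan_time_s(self) -> float:
        """Predicted acquisition time (shots x TR x repetitions).

        Exposed for orientation only; vendor sequences include overheads
        and sampling reductions that simple matrix/TR arithmetic does not
        reproduce.
        """
        return self.n_shots() * self.tr_s * self.repetitions

    def with_geometry(self, matrix, voxel_mm) -> "Protocol":
        """Desk-scaled variant: same timing/bandwidth on a different grid."""
        matrix = tuple(int(n) for n in matrix)
        fov = tuple(float(n * d) for n, d in zip(matrix, voxel_mm))
        return replace(self, matrix=matrix, fov_mm=fov)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        d = json.loads(text)
        for k in ("matrix", "fov_mm", "te_s", "accel"):
            d[k] = tuple(d[k])
        return cls(**d)


def protocol_presets() -> dict[str, Protocol]:
    """The three study protocols: GRE (EPI factor 1), EPI x3, EPI x5.

    1 mm isotropic over a 240 x 180 x 144 mm FOV, 4 echoes, 2x2 CAIPI,
    flip 20 deg; bandwidth / EPI factor / repetitions matched so every
    protocol spends the same total acquisition time per echo.
    """
    fov = (240.0, 180.0, 144.0)
    matrix = (240, 180, 144)
    common = dict(matrix=matrix, fov_mm=fov, flip_deg=20.0, accel=(2, 2),
                  caipi=True, gmax_mt_per_m=40.0, slew_mt_per_m_per_ms=200.0)
    gre = Protocol(name="GRE", te_s=(0.014, 0.025, 0.036, 0.047), tr_s=0.060,
                   bw_hz_per_px=125.0, epi_factor=1, etl_s=0.008,
                   repetitions=1, **common)
    epi3 = Protocol(name="EPIx3", te_s=(0.013, 0.025, 0.037, 0.049), tr_s=0.064,
                    bw_hz_per_px=372.0, epi_factor=3, etl_s=0.010,
                    repetitions=3, **common)
    epi5 = Protocol(name="EPIx5", te_s=(0.013, 0.026, 0.039, 0.052), tr_s=0.066,
                    bw_hz_per_px=631.0, epi_factor=5, etl_s=0.010,
                    repetitions=5, **common)
    return {"GRE": gre, "EPIx3": epi3, "EPIx5": epi5}


# ----------------------------------------------------------------------
# Sampling pattern and shot segmentation
# ----------------------------------------------------------------------

@dataclass
class SamplingPattern:
    """Ordered (ky, kz) line coordinates of a CAIPI lattice."""

    lines: np.ndarray          # (n_lines, 2) int
    ny: int
    nz: int
    accel: tuple[int, int]
    caipi_shift: int


def caipi_pattern(ny: int, nz: int, ry: int, rz: int,
                  caipi_shift: int = 0) -> SamplingPattern:
    """Regular 2D undersampling lattice with CAIPI kz stagger.

    Keeps every ry-th ky and every rz-th kz; successive kept ky rows have
    their kz comb shifted by ``caipi_shift`` (mod rz).  Ordering is
    kz-major, ky-minor.
    """
    if ry < 1 or rz < 1:
        raise ValueError("acceleration factors must be >= 1")
    if ny % ry or nz % rz:
        raise ValueError("matrix must be divisible by the acceleration factors")
    lines = []
    for iz in range(nz // rz):
        for iy in range(ny // ry):
            ky = iy * ry
            kz = (iz * rz + caipi_shift * (iy % rz)) % nz
            lines.append((ky, kz))
    lines = np.asarray(lines, dtype=np.int64)
    if len(np.unique(lines[:, 0] * nz + lines[:, 1])) != len(lines):
        raise AssertionError("CAIPI lattice produced duplicate lines")
    return SamplingPattern(lines=lines, ny=ny, nz=nz, accel=(ry, rz),
                           caipi_shift=caipi_shift)


def segment_shots(pattern: SamplingPattern, epi_factor: int,
                  ordering: str = "interleaved") -> list[np.ndarray]:
    """Assign pattern lines to shots of ``epi_factor`` lines each.

    ``sequential`` groups consecutive lines; ``interleaved`` places a
    shot's lines maximally far apart in the pattern order (line j of shot
    s is pattern index j*n_shots + s).  Every line is assigned exactly
    once; trailing shots may be short (flagged via their length).
    """
    n = len(pattern.lines)
    if epi_factor < 1:
        raise ValueError("epi_factor must be >= 1")
    if epi_factor > n:
        raise ValueError("epi_factor exceeds the number of sampled lines")
    n_shots = -(-n // epi_factor)
    if ordering == "sequential":
        return [np.arange(s * epi_factor, min((s + 1) * epi_factor, n))
                for s in range(n_shots)]
    if ordering == "interleaved":
        return [np.arange(s, n, n_shots) for s in range(n_shots)]
    raise ValueError(f"unknown ordering {ordering!r}")


# ----------------------------------------------------------------------
# Timing / noise arithmetic
# ----------------------------------------------------------------------

def thermal_noise_sigma(bw_hz_per_px: float, ref_sigma: float,
                        ref_bw_hz_per_px: float) -> float:
    """Predict complex-noise SD at a new readout bandwidth.

    sigma = ref_sigma * sqrt(bw / ref_bw): thermal noise power is
    proportional to the sampling bandwidth, which is how the EPI noise
    level follows from the GRE noise level.
    """
    if bw_hz_per_px <= 0 or ref_bw_hz_per_px <= 0:
        raise ValueError("bandwidths must be positive")
    if ref_sigma < 0:
        raise ValueError("ref_sigma must be >= 0")
    return ref_sigma * math.sqrt(bw_hz_per_px / ref_bw_hz_per_px)


def navigator_tr_count(nav_matrix, accel, lines_per_tr: int) -> int:
    """TRs needed to acquire one navigator volume.

    ceil((PE1/accel1) * (PE2/accel2) / lines_per_tr); the study navigator
    (40x32x12 matrix, 4x2 CAIPI, 8 lines per TR) takes 6 TRs.
    """
    _, p1, p2 = (int(v) for v in nav_matrix)
    a1, a2 = (int(v) for v in accel)
    if lines_per_tr < 1:
        raise ValueError("lines_per_tr must be >= 1")
    if p1 % a1 or p2 % a2:
        raise ValueError("PE dims must be divisible by the acceleration factors")
    return -(-(p1 // a1) * (p2 // a2) // lines_per_tr)


def readout_train_length(bw_hz_per_px: float, epi_factor: int) -> float:
    """Idealized ramp-free echo-train duration: epi_factor / bandwidth.

    Excludes inter-line gradient ramps, so it reproduces the GRE value
    (1/125 Hz/px = 8 ms) exactly while the EPI columns of the protocol
    table, which include gradient overheads, come out slightly shorter
    (e.g. 3/372 = 8.06 ms vs. the printed 10 ms).
    """
    if bw_hz_per_px <= 0:
        raise ValueError("bandwidth must be positive")
    return epi_factor / bw_hz_per_px


def max_epi_factor(gmax_mt_per_m: float, slew_mt_per_m_per_ms: float,
                   fov_mm: float, n_readout: int, etl_s: float) -> int:
    """Largest EPI factor fitting in one echo train.

    Per-line duration = flat-top + 2 ramps with flat-top-only sampling:
    flat-top = (n_readout / fov_m) / (gamma * G) and ramp = G / slew.
    Returns floor(etl / line_duration); 0 when a single line does not fit.
    """
    if min(gmax_mt_per_m, slew_mt_per_m_per_ms, fov_mm, n_readout, etl_s) <= 0:
        raise ValueError("all inputs must be positive")
    g_t_per_m = gmax_mt_per_m * 1e-3
    k_extent = n_readout / (fov_mm * 1e-3)            # cycles/m
    flat_s = k_extent / (GAMMA_HZ_PER_T * g_t_per_m)
    ramp_s = (gmax_mt_per_m / slew_mt_per_m_per_ms) * 1e-3
    line_s = flat_s + 2.0 * ramp_s
    if line_s > etl_s:
        return 0
    return int(etl_s / line_s)


# ----------------------------------------------------------------------
# k-space container
# ----------------------------------------------------------------------

@dataclass
class KSpaceData:
    """Shot-resolved k-space lines of one repetition.

    ``data`` holds the complex readout samples as (n_echoes, nx, n_lines);
    ``lines`` the (ky, kz) coordinate of each column and ``line_shot`` the
    shot each column belongs to.  ``iter_shots`` exposes the per-shot
    record view.
    """

    data: np.ndarray
    lines: np.ndarray
    line_shot: np.ndarray
    shots: list[np.ndarray]
    protocol: Protocol
    noise_sigma: float
    voxel_mm: np.ndarray
    rep_index: int = 0
    calib: dict | None = None

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    def partial_shots(self) -> list[int]:
        return [s for s, idx in enumerate(self.shots)
                if len(idx) < self.protocol.epi_factor]

    def iter_shots(self):
        for s, idx in enumerate(self.shots):
            yield {"shot": s,
                   "partial": len(idx) < self.protocol.epi_factor,
                   "echoes": [[(tuple(self.lines[l]), self.data[e, :, l])
                               for l in idx] for e in range(self.n_echoes)]}

    def copy(self) -> "KSpaceData":
        return replace(self, data=self.data.copy())


def save_kspace(kdata: KSpaceData, path) -> None:
    """Persist to HDF5: line data as complex datasets, protocol as JSON."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=kdata.data)
        f.create_dataset("lines", data=kdata.lines)
        f.create_dataset("line_shot", data=kdata.line_shot)
        f.attrs["protocol"] = kdata.protocol.to_json()
        f.attrs["noise_sigma"] = kdata.noise_sigma
        f.attrs["voxel_mm"] = kdata.voxel_mm
        f.attrs["rep_index"] = kdata.rep_index
        if kdata.calib is not None:
            g = f.create_group("calib")
            for k, v in kdata.calib.items():
                g.create_dataset(k, data=v)


def load_kspace(path) -> KSpaceData:
    import h5py

    with h5py.File(path, "r") as f:
        protocol = Protocol.from_json(f.attrs["protocol"])
        line_shot = f["line_shot"][()]
        shots = [np.flatnonzero(line_shot == s) for s in range(line_shot.max() + 1)]
        calib = None
        if "calib" in f:
            calib = {k: f["calib"][k][()] for k in f["calib"]}
        return KSpaceData(data=f["data"][()], lines=f["lines"][()],
                          line_shot=line_shot, shots=shots, protocol=protocol,
                          noise_sigma=float(f.attrs["noise_sigma"]),
                          voxel_mm=np.asarray(f.attrs["voxel_mm"]),
                          rep_index=int(f.attrs["rep_index"]), calib=calib)


# ----------------------------------------------------------------------
# Forward simulation
# ----------------------------------------------------------------------

def _dft_matrix(n: int, dtype) -> np.ndarray:
    """Unitary 1D DFT matrix, bins in numpy fft order."""
    k = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(k, k) / n).astype(dtype) / np.sqrt(n)


def _signed_freq(idx: np.ndarray, n: int) -> np.ndarray:
    """Signed frequency (cycles/sample) of DFT bin indices."""
    return ((idx + n // 2) % n - n // 2) / n


def ideal_echo_images(phantom: Phantom, te_s, field: FieldMap | None = None,
                      dtype=np.complex128) -> np.ndarray:
    """Noise-free complex multi-echo images (ne, nx, ny, nz)."""
    if field is None:
        field = chi_to_field(phantom)
    te = np.asarray(te_s)
    out = np.empty((len(te), *phantom.shape), dtype=dtype)
    for e, t in enumerate(te):
        out[e] = (phantom.m0 * np.exp(-phantom.r2s * t)
                  * np.exp(2j * np.pi * field.hz * t))
    return out


def _physio_phase_factors(protocol, timeline, voxel_mm, shape, echo, dtype):
    """Separable per-shot phase ramps for one echo.

    Returns (scalar (n_shots,), px (n_shots, nx), ey (n_shots, ny),
    ez (n_shots, nz)) such that the image-domain physiological phase of
    shot s is scalar[s] * px[s, x] * ey[s, y] * ez[s, z].
    """
    te = protocol.te_s[echo]
    coords = [(np.arange(n) - n / 2.0) * d for n, d in zip(shape, voxel_mm)]
    scalar = np.exp(2j * np.pi * timeline.global_hz * te).astype(dtype)
    g = timeline.grad_hz_per_mm
    px = np.exp(2j * np.pi * te * np.outer(g[:, 0], coords[0])).astype(dtype)
    ey = np.exp(2j * np.pi * te * np.outer(g[:, 1], coords[1])).astype(dtype)
    ez = np.exp(2j * np.pi * te * np.outer(g[:, 2], coords[2])).astype(dtype)
    return scalar, px, ey, ez


def _translation_phase(kdata_lines, line_shot, timeline, shape, voxel_mm, dtype):
    """k-space phase of the per-shot translations, (nx, n_lines)."""
    nx, ny, nz = shape
    t_vox = timeline.trans_mm / np.asarray(voxel_mm)
    fx = np.fft.fftfreq(nx)
    fy = _signed_freq(kdata_lines[:, 0], ny)
    fz = _signed_freq(kdata_lines[:, 1], nz)
    tx = t_vox[line_shot, 0]
    line_phase = fy * t_vox[line_shot, 1] + fz * t_vox[line_shot, 2]
    return np.exp(-2j * np.pi * (np.outer(fx, tx) + line_phase[None, :])).astype(dtype)


def build_line_dft(pattern_lines, shape, dtype) -> np.ndarray:
    """Static PE-plane DFT weights W0[(y,z), line] (unitary)."""
    nx, ny, nz = shape
    y = np.arange(ny)
    z = np.arange(nz)
    ky = pattern_lines[:, 0]
    kz = pattern_lines[:, 1]
    wy = np.exp(-2j * np.pi * np.outer(y, ky) / ny)         # (ny, L)
    wz = np.exp(-2j * np.pi * np.outer(z, kz) / nz)         # (nz, L)
    W0 = (wy[:, None, :] * wz[None, :, :]).reshape(ny * nz, -1)
    return (W0 / np.sqrt(ny * nz)).astype(dtype)


def simulate_scan(phantom: Phantom, protocol: Protocol, timeline: ShotTimeline,
                  noise_sigma: float, seed: int, *,
                  ordering: str = "interleaved", dtype=np.complex128,
                  field: FieldMap | None = None,
                  base_images: np.ndarray | None = None,
                  ghost_phase: tuple[float, float] | None = None) -> KSpaceData:
    """Simulate one repetition of shot-resolved noisy k-space.

    The timeline must have exactly one entry per shot of the protocol's
    segmentation.  ``noise_sigma`` is the complex SD per k-space sample
    (sqrt(E|n|^2)); with the unitary DFT this equals the image-domain
    complex noise SD at full sampling.  ``ghost_phase`` = (constant_rad,
    linear_rad_per_sample) injects an odd/even readout phase error and a
    matching ky=kz=0 calibration line pair.  Deterministic per seed.
    """
    if tuple(protocol.matrix) != tuple(phantom.shape):
        raise ValueError("protocol matrix must match the phantom grid "
                         f"({protocol.matrix} vs {phantom.shape})")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    shape = phantom.shape
    nx, ny, nz = shape
    ry, rz = protocol.accel
    pattern = caipi_pattern(ny, nz, ry, rz, 1 if protocol.caipi else 0)
    shots = segment_shots(pattern, protocol.epi_factor, ordering)
    if timeline.n_shots != len(shots):
        raise ValueError(f"timeline has {timeline.n_shots} shots, "
                         f"protocol segmentation needs {len(shots)}")

    if base_images is None:
        base_images = ideal_echo_images(phantom, protocol.te_s, field, dtype)
    base_images = base_images.astype(dtype, copy=False)
    lines = pattern.lines
    n_lines = len(lines)
    line_shot = np.empty(n_lines, dtype=np.int64)
    for s, idx in enumerate(shots):
        line_shot[idx] = s

    W0 = build_line_dft(lines, shape, dtype)
    Fx = _dft_matrix(nx, dtype)
    rng = np.random.default_rng(seed)
    has_grad = timeline.has_gradient()
    has_trans = bool(timeline.trans_mm.any())

    data = np.empty((protocol.n_echoes, nx, n_lines), dtype=dtype)
    for e in range(protocol.n_echoes):
        scalar, px, ey, ez = _physio_phase_factors(
            protocol, timeline, phantom.voxel_mm, shape, e, dtype)
        base_mat = base_images[e].reshape(nx, ny * nz)
        if has_grad:
            ramp = (ey[line_shot].T[:, None, :] * ez[line_shot].T[None, :, :])
            W = W0 * ramp.reshape(ny * nz, n_lines)
        else:
            W = W0
        M = base_mat @ W                                   # (nx, n_lines)
        if has_grad:
            M *= px[line_shot].T
        K = Fx @ M                                          # (nx, n_lines)
        K *= scalar[line_shot][None, :]
        if has_trans:
            K *= _translation_phase(lines, line_shot, timeline, shape,
                                    phantom.voxel_mm, dtype)
        data[e] = K

    calib = None
    if ghost_phase is not None:
        c, m = ghost_phase
        ramp = c + m * (np.arange(nx) - nx / 2.0)
        err = np.exp(1j * ramp).astype(dtype)
        # calibration pair: central (ky=kz=0) line with both polarities,
        # captured before the error is applied to the imaging lines
        center = int(np.flatnonzero((lines[:, 0] == 0) & (lines[:, 1] == 0))[0])
        clean = data[0, :, center].copy()
        calib = {"even": clean, "odd": clean * err}
        # odd train positions carry the alternating-polarity phase error
        for idx in shots:
            odd = idx[1::2]
            data[:, :, odd] *= err[None, :, None]

    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma / np.sqrt(2.0),
                           size=(*data.shape, 2))
        data += (noise[..., 0] + 1j * noise[..., 1]).astype(dtype)
        if calib is not None:
            for k in calib:
                n = rng.normal(0.0, noise_sigma / np.sqrt(2.0), size=(nx, 2))
                calib[k] = calib[k] + (n[:, 0] + 1j * n[:, 1]).astype(dtype)

    return KSpaceData(data=data, lines=lines, line_shot=line_shot, shots=shots,
                      protocol=protocol, noise_sigma=float(noise_sigma),
                      voxel_mm=np.asarray(phantom.voxel_mm, dtype=float),
                      calib=calib)


def simulate_multirep_scan(phantom: Phantom, protocol: Protocol,
                           timeline: ShotTimeline, noise_sigma: float,
                           seed: int, **kwargs) -> list[KSpaceData]:
    """Simulate all repetitions of one scan.

    The timeline spans the whole scan (repetitions are contiguous in
    time); it is sliced per repetition so physiological drift carries
    across repetition boundaries.
    """
    n_per_rep = protocol.n_shots()
    need = n_per_rep * protocol.repetitions
    if timeline.n_shots != need:
        raise ValueError(f"scan timeline needs {need} shots, got {timeline.n_shots}")
    if "base_images" not in kwargs or kwargs["base_images"] is None:
        kwargs["base_images"] = ideal_echo_images(
            phantom, protocol.te_s, kwargs.get("field"),
            kwargs.get("dtype", np.complex128))
    reps = []
    rng = np.random.default_rng(seed)
    for r in range(protocol.repetitions):
        sub = timeline.slice(r * n_per_rep, (r + 1) * n_per_rep)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        k = simulate_scan(phantom, protocol, sub, noise_sigma, sub_seed, **kwargs)
        k.rep_index = r
        reps.append(k)
    return reps
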