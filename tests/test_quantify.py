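import numpy as np
import pytest

import epiqsm as eq
from epiqsm.phantom import dipole_kernel


GRE_TES = (0.014, 0.025, 0.036, 0.047)


class TestFitR2star:
    def test_two_point_exact_exponential(self):
        mag = np.array([[[[100.0, 36.788]]]])
        r2s, s0, _ = eq.fit_r2star(mag, [0.010, 0.060],
                                   np.ones((1, 1, 1), bool))
        assert r2s[0, 0, 0] == pytest.approx(np.log(100 / 36.788) / 0.05,
                                             abs=1e-6)
        assert s0[0, 0, 0] == pytest.approx(122.14, abs=0.01)

    def test_noiseless_recovery(self):
        te = np.asarray(GRE_TES)
        truth = np.linspace(5, 80, 200)
        mag = 50.0 * np.exp(-np.outer(truth, te)).reshape(200, 1, 1, 4)
        r2s, _, diag = eq.fit_r2star(mag, te, np.ones((200, 1, 1), bool))
        assert np.abs(r2s[:, 0, 0] - truth).max() < 1e-6
        assert diag["converged"].all()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        te = np.asarray(GRE_TES)
        mag = np.abs(rng.normal(10, 1, (50, 1, 1, 1))
                     * np.exp(-np.outer(rng.uniform(10, 60, 50), te)
                              ).reshape(50, 1, 1, 4))
        mask = np.ones((50, 1, 1), bool)
        r1, s1, _ = eq.fit_r2star(mag, te, mask)
        r2, s2, _ = eq.fit_r2star(3.7 * mag, te, mask)
        assert np.allclose(r1, r2, atol=1e-9)
        assert np.allclose(3.7 * s1, s2, rtol=1e-9)

    def test_all_zero_voxel_flagged_nan(self):
        te = np.asarray(GRE_TES)
        mag = np.ones((3, 1, 1, 4))
        mag[1] = 0.0
        r2s, _, diag = eq.fit_r2star(mag, te, np.ones((3, 1, 1), bool))
        assert np.isnan(r2s[1, 0, 0])
        assert diag["n_dead_voxels"] == 1
        assert not diag["valid"][1, 0, 0]

    def test_rician_bias_small_at_snr50(self):
        """Mean R2* bias < 2% with Rician magnitudes at first-echo SNR 50."""
        rng = np.random.default_rng(7)
        te = np.asarray(GRE_TES)
        true_r2s, s0 = 20.0, 100.0
        n = 10_000
        clean = s0 * np.exp(-true_r2s * te)
        sigma = clean[0] / 50.0
        noisy = np.abs(clean[None, :]
                       + rng.normal(0, sigma, (n, 4))
                       + 1j * rng.normal(0, sigma, (n, 4)))
        r2s, _, _ = eq.fit_r2star(noisy.reshape(n, 1, 1, 4), te,
                                  np.ones((n, 1, 1), bool))
        bias = np.nanmean(r2s) - true_r2s
        assert abs(bias) / true_r2s < 0.02


class TestFrequencyMap:
    def phase_stack(self, f_hz, te):
        return np.asarray([2 * np.pi * f_hz * t for t in te]).transpose(1, 2, 3, 0)

    def test_exact_noiseless_frequency(self):
        te = np.asarray(GRE_TES)
        f = 4.0 * np.ones((4, 4, 4))
        phase = self.phase_stack(f, te)
        mag = np.ones_like(phase)
        out = eq.frequency_map(phase, te, mag, np.ones(f.shape, bool))
        assert np.abs(out - 4.0).max() < 1e-10

    def test_temporal_unwrapping_at_25_hz(self):
        """25 Hz wraps beyond pi at the later echoes; the prediction-based
        unwrap recovers it exactly (wrap counts known by construction)."""
        te = np.asarray(GRE_TES)
        f = 25.0 * np.ones((4, 4, 4))
        wrapped = np.angle(np.exp(1j * self.phase_stack(f, te)))
        mag = np.ones_like(wrapped)
        out = eq.frequency_map(wrapped, te, mag, np.ones(f.shape, bool),
                               spatial=False)
        assert np.abs(out - 25.0).max() < 1e-6

    def test_magnitude_weighting_reduces_variance(self):
        """With phase noise inversely proportional to magnitude, the
        magnitude^2-weighted estimate beats the unweighted one."""
        rng = np.random.default_rng(3)
        te = np.asarray(GRE_TES)
        n, trials = 1000, 100
        mag_e = 100.0 * np.exp(-30.0 * te)        # decaying magnitude
        var_w, var_u = [], []
        x = 2 * np.pi * te
        for _ in range(trials):
            noise = rng.normal(0, 1.0 / mag_e, (n, 4))
            phase = 2 * np.pi * 5.0 * te[None, :] + noise
            mag = np.broadcast_to(mag_e, (n, 4)).reshape(n, 1, 1, 4)
            fw = eq.frequency_map(phase.reshape(n, 1, 1, 4), te, mag,
                                  np.ones((n, 1, 1), bool), spatial=False)
            # unweighted ordinary least squares slope (phase = f * 2*pi*te)
            xc = x - x.mean()
            fu = (phase @ xc) / (xc @ xc)
            var_w.append(np.var(fw))
            var_u.append(np.var(fu))
        assert np.mean(var_w) <= np.mean(var_u)

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError):
            eq.frequency_map(np.zeros((2, 2, 2, 1)), [0.01],
                             np.ones((2, 2, 2, 1)), np.ones((2, 2, 2), bool))


class TestSpatialUnwrap:
    def test_wrap_free_phase_unchanged(self):
        rng = np.random.default_rng(0)
        phase = 0.3 * rng.normal(size=(12, 12, 12))
        mask = np.ones(phase.shape, bool)
        out = eq.spatial_unwrap(phase, mask)
        assert np.allclose(out, phase, atol=1e-9)

    def test_linear_ramp_recovered_modulo_global_offset(self):
        n = 32
        x = np.arange(n)
        truth = (6 * np.pi * x / (n - 1))[:, None, None] * np.ones((1, n, 8))
        wrapped = np.angle(np.exp(1j * truth))
        mask = np.ones(truth.shape, bool)
        out = eq.spatial_unwrap(wrapped, mask)
        resid = out - truth
        k = np.round(resid.mean() / (2 * np.pi))
        assert np.abs(resid - 2 * np.pi * k).max() < 1e-6

    def test_modulo_2pi_property(self):
        rng = np.random.default_rng(5)
        phase = np.angle(np.exp(1j * rng.normal(0, 3, (10, 10, 10))))
        mask = np.ones(phase.shape, bool)
        out = eq.spatial_unwrap(phase, mask)
        wraps = (out - phase) / (2 * np.pi)
        assert np.abs(wraps - np.round(wraps)).max() < 1e-9


def sphere_phantom(n=48, radius=6, dchi=100.0):
    idx = np.arange(n) - n // 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    r2 = X ** 2 + Y ** 2 + Z ** 2
    chi = np.where(r2 <= radius ** 2, dchi, 0.0)
    ph = eq.Phantom(m0=np.ones_like(chi), r2s=np.zeros_like(chi), chi=chi,
                    labels=np.zeros_like(chi, dtype=np.int32),
                    mask=np.ones_like(chi, dtype=bool),
                    voxel_mm=np.ones(3), b0_tesla=3.0)
    return ph, r2


class TestVsharp:
    def test_zero_field_gives_zero(self):
        mask = np.zeros((32, 32, 32), bool)
        mask[4:28, 4:28, 4:28] = True
        out, eroded = eq.vsharp_background_removal(np.zeros(mask.shape), mask,
                                                   np.ones(3))
        assert np.allclose(out, 0)
        assert eroded.any()

    def test_external_source_suppressed(self):
        """Field from a chi source outside the mask is background and must
        be removed almost entirely inside the eroded mask.

        The source is a compact Gaussian blob: the harmonicity that the
        spherical-mean filter exploits holds for band-limited discrete
        fields only when the source itself is band-limited.
        """
        n = 48
        idx = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        chi = 5000.0 * np.exp(-((X + 20) ** 2 + Y ** 2 + Z ** 2)
                              / (2 * 2.0 ** 2))
        ph = eq.Phantom(m0=np.ones_like(chi), r2s=np.zeros_like(chi), chi=chi,
                        labels=np.zeros_like(chi, dtype=np.int32),
                        mask=np.ones_like(chi, dtype=bool),
                        voxel_mm=np.ones(3), b0_tesla=3.0)
        field = eq.chi_to_field(ph).hz
        mask = (X ** 2 + Y ** 2 + Z ** 2) <= 14 ** 2
        out, eroded = eq.vsharp_background_removal(field, mask, np.ones(3))
        rms_in = np.sqrt(np.mean(field[eroded] ** 2))
        rms_out = np.sqrt(np.mean(out[eroded] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_internal_source_preserved(self):
        """Field from an internal compact source far from the boundary
        correlates > 0.95 with the input inside the eroded mask."""
        n = 48
        idx = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        r2 = X ** 2 + Y ** 2 + Z ** 2
        chi = 100.0 * np.exp(-r2 / (2 * 2.0 ** 2))
        ph = eq.Phantom(m0=np.ones_like(chi), r2s=np.zeros_like(chi), chi=chi,
                        labels=np.zeros_like(chi, dtype=np.int32),
                        mask=np.ones_like(chi, dtype=bool),
                        voxel_mm=np.ones(3), b0_tesla=3.0)
        field = eq.chi_to_field(ph).hz
        mask = r2 <= 18 ** 2
        out, eroded = eq.vsharp_background_removal(field, mask, np.ones(3))
        sel = eroded & (r2 > 6 ** 2)        # outside the source itself
        cc = np.corrcoef(field[sel], out[sel])[0, 1]
        assert cc > 0.95

    def test_mask_smaller_than_sphere_rejected(self):
        mask = np.zeros((32, 32, 32), bool)
        mask[15:17, 15:17, 15:17] = True
        with pytest.raises(ValueError):
            eq.vsharp_background_removal(np.zeros(mask.shape), mask,
                                         np.ones(3), radii_mm=[8.0])


class TestDipoleInversion:
    def test_zero_field_gives_zero_chi(self):
        mask = np.ones((16, 16, 16), bool)
        chi = eq.dipole_inversion(np.zeros(mask.shape), mask, 3.0, np.ones(3))
        assert np.allclose(chi, 0)

    def test_sphere_forward_then_invert_tkd(self):
        """Forward field of a 6-voxel sphere (100 ppb) inverted with TKD 0.2
        recovers the sphere mean within 15%."""
        ph, r2 = sphere_phantom(n=48, radius=6, dchi=100.0)
        field = eq.chi_to_field(ph).hz
        mask = np.ones(field.shape, bool)
        chi = eq.dipole_inversion(field, mask, 3.0, np.ones(3), "tkd", 0.2)
        chi_ref = chi - chi[r2 > 20 ** 2].mean()   # re-reference to far field
        sphere_mean = chi_ref[r2 <= 5 ** 2].mean()
        assert abs(sphere_mean - 100.0) / 100.0 < 0.15

    def test_brain_mean_referencing_exact(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((16, 16, 16), bool)
        mask[3:13, 3:13, 3:13] = True
        chi = eq.dipole_inversion(rng.normal(size=mask.shape), mask, 3.0,
                                  np.ones(3), "tikhonov", 0.1)
        assert abs(chi[mask].mean()) < 1e-10 * np.abs(chi[mask]).max()

    def test_invalid_inputs(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            eq.dipole_inversion(np.zeros(mask.shape), np.zeros_like(mask),
                                3.0, np.ones(3))
        with pytest.raises(ValueError):
            eq.dipole_inversion(np.zeros(mask.shape), mask, 3.0, np.ones(3),
                                "tkd", 1.5)


class TestEndToEnd:
    def test_quantification_identity_noiseless(self, small_phantom):
        """sigma = 0, null timeline: R2* within 0.1 1/s and f within
        0.05 Hz of the ground truth over the eroded mask."""
        prot = eq.protocol_presets()["EPIx3"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        tl = eq.ShotTimeline.null(prot.n_shots())
        img = eq.reconstruct(
            eq.simulate_scan(small_phantom, prot, tl, 0.0, 0),
            "uncorrected", tl)
        q = eq.quantify_image(img, small_phantom.mask,
                              small_phantom.b0_tesla, compute_chi=False)
        valid = q.mask & np.isfinite(q.r2s_hat)
        assert np.abs((q.r2s_hat - small_phantom.r2s)[valid]).max() < 0.1
        f_true = eq.chi_to_field(small_phantom).hz
        f_true_t, _ = eq.vsharp_background_removal(
            f_true, small_phantom.mask, small_phantom.voxel_mm)
        assert np.abs((q.f_hat - f_true_t)[valid]).max() < 0.05

    def test_quantmaps_chi_reference_invariant(self, small_phantom):
        prot = eq.protocol_presets()["GRE"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        tl = eq.ShotTimeline.null(prot.n_shots())
        img = eq.reconstruct(
            eq.simulate_scan(small_phantom, prot, tl, 0.0, 0),
            "uncorrected", tl)
        q = eq.quantify_image(img, small_phantom.mask, small_phantom.b0_tesla)
        assert abs(q.chi_hat[q.mask].mean()) < 1e-8
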