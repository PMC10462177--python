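import numpy as np
import pytest
from dataclasses import replace

import epiqsm as eq
from epiqsm.acquisition import caipi_pattern, segment_shots


class TestProtocolPresets:
    def test_gre_echo_times(self):
        gre = eq.protocol_presets()["GRE"]
        assert gre.te_s == (0.014, 0.025, 0.036, 0.047)

    @pytest.mark.parametrize("name,epi,reps,bw,tr,etl", [
        ("GRE", 1, 1, 125.0, 0.060, 0.008),
        ("EPIx3", 3, 3, 372.0, 0.064, 0.010),
        ("EPIx5", 5, 5, 631.0, 0.066, 0.010),
    ])
    def test_table_parameters(self, name, epi, reps, bw, tr, etl):
        p = eq.protocol_presets()[name]
        assert p.epi_factor == epi
        assert p.repetitions == reps
        assert p.bw_hz_per_px == bw
        assert p.tr_s == tr
        assert p.etl_s == etl
        assert p.matrix == (240, 180, 144)
        assert p.fov_mm == (240.0, 180.0, 144.0)
        assert p.flip_deg == 20.0
        assert p.accel == (2, 2) and p.caipi
        assert p.gmax_mt_per_m == 40.0
        assert p.slew_mt_per_m_per_ms == 200.0
        # echo spacing is uniform and the 4th echo matches the table
        te = np.asarray(p.te_s)
        assert np.allclose(np.diff(te), te[1] - te[0])

    def test_repetition_train_consistency(self):
        for p in eq.protocol_presets().values():
            lines = p.n_lines()
            assert (p.repetitions * lines) % p.epi_factor == 0

    def test_json_roundtrip(self):
        p = eq.protocol_presets()["EPIx3"]
        assert eq.Protocol.from_json(p.to_json()) == p

    def test_nonincreasing_te_rejected(self):
        with pytest.raises(ValueError):
            replace(eq.protocol_presets()["GRE"], te_s=(0.02, 0.02, 0.03, 0.04))


class TestCaipiPattern:
    def test_full_sampling_covers_everything(self):
        pat = caipi_pattern(8, 8, 1, 1, 0)
        assert len(pat.lines) == 64
        assert len(set(map(tuple, pat.lines))) == 64

    def test_2x2_count_and_stagger(self):
        pat = caipi_pattern(8, 8, 2, 2, 1)
        assert len(pat.lines) == 16
        pat0 = caipi_pattern(8, 8, 2, 2, 0)
        assert len(pat0.lines) == 16
        assert set(map(tuple, pat.lines)) != set(map(tuple, pat0.lines))

    def test_non_divisible_matrix_rejected(self):
        with pytest.raises(ValueError):
            caipi_pattern(9, 8, 2, 2, 1)


class TestSegmentShots:
    def test_gre_table_geometry_shot_count(self):
        pat = caipi_pattern(180, 144, 2, 2, 1)
        assert len(pat.lines) == 6480
        assert len(segment_shots(pat, 1)) == 6480
        assert len(segment_shots(pat, 5)) == 1296

    def test_sequential_remainder_handling(self):
        pat = caipi_pattern(10, 1, 1, 1, 0)
        shots = segment_shots(pat, 3, "sequential")
        assert [len(s) for s in shots] == [3, 3, 3, 1]

    @pytest.mark.parametrize("ordering", ["sequential", "interleaved"])
    def test_line_conservation(self, ordering):
        pat = caipi_pattern(16, 12, 2, 2, 1)
        shots = segment_shots(pat, 5, ordering)
        used = np.concatenate(shots)
        assert len(used) == len(pat.lines)
        assert len(np.unique(used)) == len(pat.lines)

    def test_epi_factor_larger_than_lines_rejected(self):
        pat = caipi_pattern(4, 4, 2, 2, 1)
        with pytest.raises(ValueError):
            segment_shots(pat, 5)


class TestTimingArithmetic:
    def test_noise_sigma_identity_and_scaling(self):
        assert eq.thermal_noise_sigma(125, 1.5, 125) == 1.5
        assert np.isclose(eq.thermal_noise_sigma(631, 1.0, 125),
                          np.sqrt(631 / 125))
        with pytest.raises(ValueError):
            eq.thermal_noise_sigma(0, 1, 125)

    def test_navigator_tr_count(self):
        assert eq.navigator_tr_count((40, 32, 12), (4, 2), 8) == 6
        assert eq.navigator_tr_count((40, 32, 12), (1, 1), 8) == 48
        assert eq.navigator_tr_count((40, 32, 12), (4, 2), 7) == 7
        with pytest.raises(ValueError):
            eq.navigator_tr_count((40, 30, 12), (4, 2), 8)

    def test_readout_train_length(self):
        assert eq.readout_train_length(125, 1) == pytest.approx(0.008)
        assert eq.readout_train_length(372, 3) == pytest.approx(3 / 372)
        assert eq.readout_train_length(1e9, 5) < 1e-8
        with pytest.raises(ValueError):
            eq.readout_train_length(0, 1)

    def test_max_epi_factor(self):
        assert eq.max_epi_factor(40, 200, 240, 240, 0.010) == 10
        assert eq.max_epi_factor(40, 200, 240, 240, 0.020) == 20
        assert eq.max_epi_factor(20, 200, 240, 240, 0.010) == 7
        assert eq.max_epi_factor(40, 200, 240, 240, 1e-5) == 0


class TestSimulateScan:
    def test_inverse_crime_identity_full_sampling(self, small_phantom):
        prot = eq.protocol_presets()["GRE"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        prot = replace(prot, accel=(1, 1), caipi=False)
        tl = eq.ShotTimeline.null(prot.n_shots())
        k = eq.simulate_scan(small_phantom, prot, tl, 0.0, 0)
        img = eq.reconstruct(k, "uncorrected", tl)
        ideal = np.moveaxis(eq.ideal_echo_images(small_phantom, prot.te_s),
                            0, -1)
        scale = np.abs(ideal).max()
        assert np.abs(img.data - ideal).max() < 1e-10 * scale

    def test_constant_global_offset_phase_closed_form(self, small_phantom):
        prot = eq.protocol_presets()["GRE"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        prot = replace(prot, accel=(1, 1), caipi=False)
        n = prot.n_shots()
        delta = 3.0
        tl = eq.ShotTimeline(np.full(n, delta), np.zeros((n, 3)),
                             np.zeros((n, 3)))
        k = eq.simulate_scan(small_phantom, prot, tl, 0.0, 0)
        img = eq.reconstruct(k, "uncorrected",
                             eq.ShotTimeline.null(n))  # no demodulation
        ideal = np.moveaxis(eq.ideal_echo_images(small_phantom, prot.te_s),
                            0, -1)
        brain = small_phantom.mask
        for e, te in enumerate(prot.te_s):
            dphi = np.angle(img.data[..., e][brain]
                            * np.conj(ideal[..., e][brain]))
            expected = np.angle(np.exp(2j * np.pi * delta * te))
            assert np.abs(np.angle(np.exp(1j * (dphi - expected)))).max() < 1e-8

    def test_image_noise_sd_matches_declared_normalization(self, small_phantom):
        prot = eq.protocol_presets()["GRE"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        prot = replace(prot, accel=(1, 1), caipi=False)
        tl = eq.ShotTimeline.null(prot.n_shots())
        sigma = 0.01
        k0 = eq.simulate_scan(small_phantom, prot, tl, 0.0, 0)
        k1 = eq.simulate_scan(small_phantom, prot, tl, sigma, 1)
        img = eq.reconstruct(k1, "uncorrected", tl)
        noise = img.data - eq.reconstruct(k0, "uncorrected", tl).data
        bg = small_phantom.m0 == 0
        samples = noise[bg]
        assert samples.size > 1e4
        sd = np.sqrt(np.mean(np.abs(samples) ** 2))
        assert abs(sd - sigma) / sigma < 0.05

    def test_seed_determinism_and_noise_independence(self, small_phantom):
        prot = eq.protocol_presets()["EPIx3"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        tl = eq.ShotTimeline.null(prot.n_shots())
        sigma = 0.02
        a = eq.simulate_scan(small_phantom, prot, tl, sigma, 42)
        b = eq.simulate_scan(small_phantom, prot, tl, sigma, 42)
        assert np.array_equal(a.data, b.data)
        c = eq.simulate_scan(small_phantom, prot, tl, sigma, 43)
        diff = (a.data - c.data).ravel()
        assert diff.size > 1e5
        sd = np.sqrt(np.mean(np.abs(diff) ** 2))
        assert abs(sd - sigma * np.sqrt(2)) / (sigma * np.sqrt(2)) < 0.05
        assert abs(diff.mean()) < 5 * sd / np.sqrt(diff.size)

    def test_snr_matching_across_protocols(self, small_phantom):
        """Averaging the N repetitions of EPIxN at N-fold bandwidth returns
        the single-repetition GRE image-noise level (the matched-SNR design)."""
        presets = eq.protocol_presets()
        gre = presets["GRE"].with_geometry(small_phantom.shape,
                                           small_phantom.voxel_mm)
        epi5 = presets["EPIx5"].with_geometry(small_phantom.shape,
                                              small_phantom.voxel_mm)
        sigma_gre = 0.01
        sigma_epi = eq.thermal_noise_sigma(epi5.bw_hz_per_px, sigma_gre,
                                           gre.bw_hz_per_px)
        bg = small_phantom.m0 == 0

        tlg = eq.ShotTimeline.null(gre.n_shots())
        ref_g = eq.reconstruct(eq.simulate_scan(small_phantom, gre, tlg, 0.0, 0),
                               "uncorrected", tlg).data
        img_g = eq.reconstruct(eq.simulate_scan(small_phantom, gre, tlg,
                                                sigma_gre, 1),
                               "uncorrected", tlg).data
        sd_gre = np.sqrt(np.mean(np.abs((img_g - ref_g)[bg]) ** 2))

        tle = eq.ShotTimeline.null(epi5.n_shots() * epi5.repetitions)
        reps = eq.simulate_multirep_scan(small_phantom, epi5, tle, sigma_epi, 2)
        ref_e = eq.reconstruct(
            eq.simulate_scan(small_phantom, epi5,
                             eq.ShotTimeline.null(epi5.n_shots()), 0.0, 0),
            "uncorrected").data
        avg = np.mean([eq.reconstruct(k, "uncorrected").data for k in reps],
                      axis=0)
        sd_epi = np.sqrt(np.mean(np.abs((avg - ref_e)[bg]) ** 2))
        assert abs(sd_epi - sd_gre) / sd_gre < 0.05

    def test_timeline_length_mismatch_rejected(self, small_phantom):
        prot = eq.protocol_presets()["GRE"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        with pytest.raises(ValueError, match="shots"):
            eq.simulate_scan(small_phantom, prot,
                             eq.ShotTimeline.null(10), 0.0, 0)

    def test_partial_shot_flagging(self, small_phantom):
        prot = eq.protocol_presets()["EPIx5"].with_geometry(
            small_phantom.shape, small_phantom.voxel_mm)
        tl = eq.ShotTimeline.null(prot.n_shots())
        k = eq.simulate_scan(small_phantom, prot, tl, 0.0, 0)
        # 48*48/4 = 576 lines, epi 5 -> 116 shots, some short
        assert k.n_shots == 116
        assert len(k.partial_shots()) >= 1
        rec = next(iter(k.iter_shots()))
        assert {"shot", "partial", "echoes"} <= set(rec)


def test_kspace_hdf5_roundtrip(tmp_path, small_phantom):
    prot = eq.protocol_presets()["EPIx3"].with_geometry(
        small_phantom.shape, small_phantom.voxel_mm)
    tl = eq.ShotTimeline.null(prot.n_shots())
    k = eq.simulate_scan(small_phantom, prot, tl, 0.01, 5,
                         ghost_phase=(0.1, 0.001))
    path = tmp_path / "scan.h5"
    eq.save_kspace(k, path)
    back = eq.load_kspace(path)
    assert np.array_equal(back.data, k.data)
    assert np.array_equal(back.lines, k.lines)
    assert back.protocol == k.protocol
    assert np.array_equal(back.calib["odd"], k.calib["odd"])
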