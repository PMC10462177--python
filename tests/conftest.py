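"""Shared fixtures.

``study`` is the expensive session fixture: the full test-retest
experiment (three protocols, two reconstruction modes, 20 independent
scan-pair seeds) on the default 64 x 64 x 48 phantom, plus the EPI x5
Monte Carlo thermal floor.  Acceptance-level reliability properties and
the pipeline-level qualitative checks all read from it.
"""

import warnings

import numpy as np
import pytest

import epiqsm as eq

N_SEED_PAIRS = 20


@pytest.fixture(scope="session")
def phantom():
    return eq.build_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 phantom for cheap simulation tests."""
    return eq.build_phantom((48, 48, 48), (3.0, 3.0, 3.0), seed=1)


@pytest.fixture(scope="session")
def fieldmap(phantom):
    return eq.chi_to_field(phantom)


@pytest.fixture(scope="session")
def desk_protocols(phantom):
    presets = eq.protocol_presets()
    return {name: p.with_geometry(phantom.shape, phantom.voxel_mm)
            for name, p in presets.items()}


@pytest.fixture(scope="session")
def sigma_gre(phantom, desk_protocols, fieldmap):
    return eq.gre_sigma_for_snr(phantom, desk_protocols["GRE"], 50.0, fieldmap)


@pytest.fixture(scope="session")
def study(phantom, fieldmap, desk_protocols, sigma_gre):
    """Aggregated reliability results over N_SEED_PAIRS scan pairs."""
    rng_pairs = [(1000 + 2 * i, 1001 + 2 * i) for i in range(N_SEED_PAIRS)]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, protocol in desk_protocols.items():
            sigma_k = eq.protocol_sigma(protocol, sigma_gre)
            base = eq.ideal_echo_images(phantom, protocol.te_s, fieldmap,
                                        np.complex64)
            acc = {mode: {"nad": [], "dr2s": [], "dr2s_single": [],
                          "curves": []}
                   for mode in ("corrected", "uncorrected")}
            for seeds in rng_pairs:
                pair = eq.run_scan_pair(
                    phantom, protocol, seeds, sigma_k=sigma_k,
                    physio=dict(eq.DEFAULT_PHYSIO),
                    metrics=("nad", "dr2s"), dtype=np.complex64,
                    fieldmap=fieldmap, base_images=base)
                for mode, r in pair.items():
                    acc[mode]["nad"].append(r["nad_median"])
                    acc[mode]["dr2s"].append(r["dr2s_median"])
                    acc[mode]["dr2s_single"].append(r["dr2s_median_single"])
                    acc[mode]["curves"].append(r["dr2s_curve"])
            out[name] = {
                mode: {"nad": float(np.mean(v["nad"])),
                       "dr2s": float(np.mean(v["dr2s"])),
                       "dr2s_single": float(np.mean(v["dr2s_single"])),
                       "dr2s_curve": np.mean(v["curves"], axis=0),
                       "nad_all": np.asarray(v["nad"]),
                       "dr2s_all": np.asarray(v["dr2s"])}
                for mode, v in acc.items()}

        # EPI x5 thermal floor, through the same estimator chain
        pr5 = desk_protocols["EPIx5"]
        sk5 = eq.protocol_sigma(pr5, sigma_gre)
        base5 = eq.ideal_echo_images(phantom, pr5.te_s, fieldmap, np.complex64)
        k0 = eq.simulate_scan(phantom, pr5,
                              eq.ShotTimeline.null(pr5.n_shots()), 0.0, 0,
                              dtype=np.complex64, base_images=base5)
        ref = eq.reconstruct(k0, "uncorrected")
        sig_img = float(np.sqrt(np.prod(pr5.accel))) * sk5
        floors = eq.monte_carlo_noise_floor(
            ref, sig_img, 5, metrics=("dr2s",), seed=5, mask=phantom.mask,
            n_averages=pr5.repetitions)
        out["floor_epix5_dr2s"] = float(np.median(floors["dr2s"]))
    return out
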