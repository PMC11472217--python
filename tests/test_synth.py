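"""Generator tests: protocol bookkeeping, traces, schedules, depth maps, nuisance."""

import numpy as np
import pytest

from laminarhrf.protocol import GasBlock, GasProtocol, default_protocol
from laminarhrf.synth import (
    DEPTH_BINS,
    calibrated_hrf,
    linear_profile,
    make_depth_probability_maps,
    make_end_tidal_traces,
    make_nuisance_series,
    make_stimulus_schedule,
)
from laminarhrf.fir import laminar_average
from laminarhrf.hrfmodel import quantify_curve

TR = 0.85


class TestProtocol:
    def test_default_run_bookkeeping(self, protocol):
        assert protocol.duration == pytest.approx(697.0)
        assert round(protocol.duration / TR) == 820
        labels = [b.label for b in protocol.blocks]
        assert labels == ["baseline", "room_air", "hc5", "hc10", "ho", "room_air"]
        assert protocol.block_at(250.0).dpetco2 == 5.0
        assert protocol.block_at(400.0).dpetco2 == 10.0
        assert protocol.block_at(500.0).dpeto2 == 350.0

    def test_invalid_blocks_rejected(self):
        with pytest.raises(ValueError):
            GasBlock("hc5", duration=-1.0)
        with pytest.raises(ValueError):
            GasBlock("hc5", 10.0, dpetco2=-5.0)
        with pytest.raises(ValueError):
            GasBlock("unknown_label", 10.0)


class TestEndTidalTraces:
    def test_instant_transitions_hit_targets_exactly(self):
        proto = default_protocol(transition_tau=0.0)
        trace = make_end_tidal_traces(proto, TR, jitter_sd=0.0)
        assert len(trace) == 820
        for label, dco2, do2 in [("hc5", 5.0, 0.0), ("hc10", 10.0, 0.0), ("ho", 0.0, 350.0)]:
            sel = trace.block_labels == label
            assert trace.dpetco2[sel].mean() == pytest.approx(dco2, abs=1e-12)
            assert trace.dpeto2[sel].mean() == pytest.approx(do2, abs=1e-12)

    def test_zero_targets_give_constant_baseline(self):
        proto = GasProtocol(blocks=(GasBlock("baseline", 85.0), GasBlock("room_air", 85.0)))
        trace = make_end_tidal_traces(proto, TR, jitter_sd=0.0)
        assert np.allclose(trace.petco2, proto.baseline_petco2)
        assert np.allclose(trace.peto2, proto.baseline_peto2)

    def test_exponential_approach_matches_scalar_recursion_oracle(self):
        # independent scalar recursion for the expected (jitter-free) trace
        proto = default_protocol(transition_tau=10.0)
        tau, n = 10.0, 820
        decay = np.exp(-TR / tau)
        edges = proto.boundaries
        expected = np.empty(n)
        level = proto.baseline_petco2
        for i in range(n):
            t = i * TR
            blk = proto.blocks[min(np.searchsorted(edges, t, side="right") - 1, len(proto.blocks) - 1)]
            target = proto.baseline_petco2 + blk.dpetco2
            level = target if i == 0 else target + (level - target) * decay
            expected[i] = level
        hc10 = proto.labels_at(np.arange(n) * TR) == "hc10"
        oracle_mean = expected[hc10].mean()

        trace = make_end_tidal_traces(proto, TR, jitter_sd=0.5, seed=1)
        n_hc10 = hc10.sum()
        tol = 5.0 * 0.5 / np.sqrt(n_hc10)  # jitter SE on the block mean
        assert trace.petco2[hc10].mean() == pytest.approx(oracle_mean, abs=tol)
        # and the jitter-free generator matches the oracle to machine precision
        clean = make_end_tidal_traces(proto, TR, jitter_sd=0.0)
        assert np.allclose(clean.petco2, expected, atol=1e-10)

    def test_determinism_and_validation(self, protocol):
        a = make_end_tidal_traces(protocol, TR, jitter_sd=0.5, seed=9)
        b = make_end_tidal_traces(protocol, TR, jitter_sd=0.5, seed=9)
        assert np.array_equal(a.petco2, b.petco2) and np.array_equal(a.peto2, b.peto2)
        with pytest.raises(ValueError):
            make_end_tidal_traces(protocol, TR, jitter_sd=-1.0)
        with pytest.raises(ValueError):
            make_end_tidal_traces(protocol, tr=0.9)  # 697 s not a multiple of 0.9


class TestStimulusSchedule:
    def test_default_schedule_invariants_across_seeds(self, protocol):
        for seed in range(100):
            s = make_stimulus_schedule(protocol=protocol, seed=seed)
            assert len(s) == 71
            isis = np.diff(s.onsets)
            assert np.all(isis >= 3.0 - 1e-9) and np.all(isis <= 28.0 + 1e-9)
            assert s.onsets[0] >= 30.0
            assert s.onsets[-1] <= 697.0 - 20.0
            assert set(s.conditions) <= {"room_air", "hc5", "hc10", "ho"}

    def test_single_event(self, protocol):
        s = make_stimulus_schedule(n_events=1, protocol=protocol, seed=0)
        assert len(s) == 1 and s.onsets[0] >= 30.0

    def test_condition_counts_monte_carlo(self, protocol):
        # oracle: brute-force counting over 200 generated schedules; the
        # room-air : hypercapnic ratio tracks the 200 s : 120 s block ratio
        counts = {"room_air": 0, "hc5": 0, "hc10": 0, "ho": 0}
        n_seeds = 200
        for seed in range(n_seeds):
            s = make_stimulus_schedule(protocol=protocol, seed=seed)
            for c in counts:
                counts[c] += int(np.sum(s.conditions == c))
        means = {c: v / n_seeds for c, v in counts.items()}
        assert sum(means.values()) == pytest.approx(71.0)
        # frozen from the Monte-Carlo oracle itself (200 seeds): ~13.8 events
        # per 120 s challenge block, ~29.7 in room air (200 s block + tail),
        # i.e. the same 200:120 exposure ratio the block design implies
        assert means["hc5"] == pytest.approx(13.85, abs=1.0)
        assert means["hc10"] == pytest.approx(13.77, abs=1.0)
        assert means["ho"] == pytest.approx(13.72, abs=1.0)
        assert means["room_air"] == pytest.approx(29.67, abs=1.5)

    def test_infeasible_schedule_rejected(self, protocol):
        with pytest.raises(ValueError, match="infeasible"):
            make_stimulus_schedule(n_events=500, protocol=protocol, seed=0)

    def test_snap_to_grid_keeps_invariants(self, protocol):
        s = make_stimulus_schedule(protocol=protocol, seed=3, snap_to_grid=True, tr=TR)
        frac = s.onsets / TR
        assert np.allclose(frac, np.round(frac), atol=1e-9)
        isis = np.diff(s.onsets)
        assert np.all(isis >= 3.0) and np.all(isis <= 28.0)


class TestDepthProbabilityMaps:
    def test_one_hot_identity(self):
        dp = make_depth_probability_maps(n_voxels_per_bin=5, mixing=0.0, seed=0)
        assert np.all(np.isin(dp.probs, [0.0, 1.0]))
        truth = np.arange(7.0)
        per_bin, _ = laminar_average(dp.mix(truth), dp, exclude_veins_from_laminae=False)
        assert np.allclose(per_bin, truth)

    def test_rows_sum_to_one(self):
        dp = make_depth_probability_maps(n_voxels_per_bin=60, mixing=0.3, seed=7)
        assert np.all(np.abs(dp.probs.sum(axis=1) - 1.0) < 1e-12)

    def test_mixed_linear_profile_matches_matrix_product_oracle(self):
        dp = make_depth_probability_maps(n_voxels_per_bin=40, mixing=0.3, seed=11)
        truth = linear_profile(1.0, 0.2)
        voxel_vals = dp.mix(truth)
        # explicit probability-matrix product oracle, independent loops
        P = dp.probs
        for b in range(7):
            num = sum(P[v, b] * voxel_vals[v] for v in range(P.shape[0]))
            den = sum(P[v, b] for v in range(P.shape[0]))
            est, _ = laminar_average(voxel_vals, dp, exclude_veins_from_laminae=False)
            assert est[b] == pytest.approx(num / den, abs=1e-12)

    def test_vein_mask_threshold(self):
        dp = make_depth_probability_maps(n_voxels_per_bin=10, mixing=0.25, seed=1)
        vein_col = dp.bins.index("pial_vein")
        assert np.array_equal(dp.vein_mask, dp.probs[:, vein_col] > 0.5)
        assert dp.vein_mask.sum() == 10  # exactly the home-bin voxels of the vein bin


class TestNuisanceSeries:
    def test_zero_amplitude_and_determinism(self):
        z = make_nuisance_series(100, TR, seed=3, amplitude=0.0)
        assert not z.motion.any() and not z.rvt.any() and not z.bpm.any()
        a = make_nuisance_series(200, TR, seed=5)
        b = make_nuisance_series(200, TR, seed=5)
        assert np.array_equal(a.motion, b.motion) and np.array_equal(a.rvt, b.rvt)

    def test_sample_variance_matches_configured(self):
        z = make_nuisance_series(820, TR, seed=3, amplitude=1.5)
        for series in [z.rvt, z.bpm, z.motion[:, 0]]:
            assert np.var(series, ddof=1) == pytest.approx(1.5**2, rel=1e-10)


class TestCalibratedHRF:
    def test_descriptors_match_planted_values(self):
        h = calibrated_hrf(amplitude=2.17, ttp=4.09, fwhm=3.66)
        t = np.arange(0.0, 24.0, 0.001)
        q = quantify_curve(t, h(t))
        assert q["amplitude"] == pytest.approx(2.17, abs=2e-3)
        assert q["ttp"] == pytest.approx(4.09, abs=2e-3)
        assert q["fwhm"] == pytest.approx(3.66, abs=5e-3)

    def test_zero_amplitude_gives_zero_curve(self):
        h = calibrated_hrf(0.0, 4.0, 3.0)
        assert not h(np.linspace(0, 20, 50)).any()
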