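"""Design-construction tests: DCT bases, canonical kernel, localizer and FIR designs."""

import math

import numpy as np
import pytest

from laminarhrf.design import (
    build_fir_design,
    build_localizer_design,
    canonical_hrf,
    dct_basis,
    double_gamma,
    event_regressor,
    highpass_remove_gas,
)
from laminarhrf.protocol import default_protocol
from laminarhrf.synth import (
    StimulusSchedule,
    make_end_tidal_traces,
    make_nuisance_series,
    make_stimulus_schedule,
)

TR = 0.85
NVOL = 820


def _count_frequencies_below(n, tr, cutoff):
    # independent enumeration oracle: cosines k/(2T) < cutoff, k >= 1
    T = n * tr
    return sum(1 for k in range(1, n) if k / (2 * T) < cutoff)


class TestDCTBasis:
    def test_cutoff_zero_empty(self):
        assert dct_basis(NVOL, TR, 0.0).shape == (NVOL, 0)

    @pytest.mark.parametrize("cutoff", [7e-4, 0.01, 0.005])
    def test_count_matches_frequency_enumeration_oracle(self, cutoff):
        X = dct_basis(NVOL, TR, cutoff)
        assert X.shape[1] == _count_frequencies_below(NVOL, TR, cutoff)

    def test_study_cutoffs(self):
        # 697 s run: detrend cutoff keeps only the constant, high-pass keeps 13
        assert dct_basis(NVOL, TR, 7e-4).shape[1] == 0
        assert dct_basis(NVOL, TR, 0.01).shape[1] == 13

    def test_orthogonality(self):
        X = dct_basis(200, 1.0, 0.05)
        G = X.T @ X
        assert np.allclose(G, np.eye(X.shape[1]), atol=1e-10)


class TestCanonicalHRF:
    def test_unit_peak(self):
        h = canonical_hrf(TR)
        assert h.max() == pytest.approx(1.0)
        assert len(h) == math.ceil(32.0 / TR)

    def test_dense_grid_ttp_near_five_seconds(self, canonical_descriptors):
        # 1 ms grid argmax oracle
        assert canonical_descriptors["ttp"] == pytest.approx(5.0, abs=0.05)

    def test_zero_event_train_gives_zero_regressor(self):
        reg = event_regressor(np.array([]), NVOL, TR, canonical_hrf(TR))
        assert not reg.any()


@pytest.fixture(scope="module")
def inputs():
    proto = default_protocol(transition_tau=0.0)
    trace = make_end_tidal_traces(proto, TR, jitter_sd=0.0)
    schedule = make_stimulus_schedule(protocol=proto, seed=4)
    nuis = make_nuisance_series(NVOL, TR, seed=4)
    return proto, trace, schedule, nuis


class TestLocalizerDesign:

    def test_gas_regressor_block_means_equal_targets(self, inputs):
        proto, trace, schedule, nuis = inputs
        dm = build_localizer_design(trace, schedule, nuis, tr=TR, n_volumes=NVOL)
        co2 = dm.frame["dpetco2"].to_numpy()
        labels = trace.block_labels
        assert co2[labels == "hc5"].mean() == pytest.approx(5.0)
        assert co2[labels == "hc10"].mean() == pytest.approx(10.0)
        assert co2[labels == "room_air"].mean() == pytest.approx(0.0)
        o2 = dm.frame["dpeto2"].to_numpy()
        assert o2[labels == "ho"].mean() == pytest.approx(350.0)

    def test_empty_schedule_zero_visual(self, inputs):
        proto, trace, _, nuis = inputs

        class Empty:
            onsets = np.array([])

        dm = build_localizer_design(trace, Empty(), nuis, tr=TR, n_volumes=NVOL)
        assert not dm.frame["visual"].to_numpy().any()

    def test_condition_number_within_oracle_bound(self, inputs):
        # one-off SVD oracle established the default design's conditioning
        # scale (~2e3, driven by the 0..350 mmHg O2 range); assert an order-of
        # -magnitude ceiling so regressions in scaling are caught
        proto, trace, schedule, nuis = inputs
        dm = build_localizer_design(trace, schedule, nuis, tr=TR, n_volumes=NVOL)
        X = dm.matrix / np.linalg.norm(dm.matrix, axis=0)
        assert np.linalg.cond(X) < 50.0

    def test_rank_deficiency_rejected(self, inputs):
        proto, trace, schedule, nuis = inputs

        class TwinTrace:
            dpetco2 = trace.dpetco2
            dpeto2 = trace.dpetco2  # duplicated column

        with pytest.raises(ValueError, match="rank deficient"):
            build_localizer_design(TwinTrace(), schedule, nuis, tr=TR, n_volumes=NVOL)


@pytest.fixture(scope="module")
def trace():
    return make_end_tidal_traces(default_protocol(), TR, jitter_sd=0.0)


class TestHighpassRemoveGas:

    def test_pure_gas_response_annihilated(self, trace):
        y = 3.0 + 0.5 * trace.dpetco2 + 0.01 * trace.dpeto2
        out = highpass_remove_gas(y[None, :], trace, tr=TR)
        assert np.linalg.norm(out) <= 1e-6 * np.linalg.norm(y)

    def test_orthogonal_input_unchanged(self, trace):
        n = len(trace)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(n)
        Z = np.column_stack(
            [np.ones(n), dct_basis(n, TR, 0.01), trace.dpetco2, trace.dpeto2]
        )
        y -= Z @ np.linalg.lstsq(Z, y, rcond=None)[0]  # orthogonalize first
        out = highpass_remove_gas(y[None, :], trace, tr=TR)[0]
        assert np.allclose(out, y, atol=1e-10)

    def test_variance_removed_matches_projection_oracle(self, trace):
        n = len(trace)
        rng = np.random.default_rng(1)
        y = rng.standard_normal((5, n)) + 0.3 * trace.dpetco2
        out = highpass_remove_gas(y, trace, tr=TR)
        Z = np.column_stack([np.ones(n), dct_basis(n, TR, 0.01), trace.dpetco2, trace.dpeto2])
        H = Z @ np.linalg.pinv(Z)
        oracle = y - y @ H.T
        assert np.allclose(out, oracle, atol=1e-8)


class TestFIRDesign:
    def test_lag_count_matches_ceil_oracle(self):
        sched = StimulusSchedule(onsets=np.array([34.0]), conditions=np.array(["room_air"]))
        d = build_fir_design(sched, tr=TR, n_volumes=NVOL, window=20.0)
        assert d.n_lags == math.ceil(20.0 / TR) == 24

    def test_disjoint_conditions_orthogonal_blocks(self):
        sched = StimulusSchedule(
            onsets=np.array([34.0, 85.0]), conditions=np.array(["room_air", "hc5"])
        )
        d = build_fir_design(sched, tr=TR, n_volumes=NVOL, window=20.0)
        A = d.interest[:, d.lag_block("room_air")]
        B = d.interest[:, d.lag_block("hc5")]
        assert not (A.T @ B).any()

    def test_unknown_event_label_rejected(self):
        sched = StimulusSchedule(onsets=np.array([34.0]), conditions=np.array(["baseline"]))
        with pytest.raises(ValueError, match="labels outside"):
            build_fir_design(sched, tr=TR, n_volumes=NVOL, conditions=["room_air"])
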