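import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations

import popcode as pc
from popcode.metrics import TrialTensor


def tensor_of(values, timecourses=None, source="dff"):
    return TrialTensor(np.asarray(values, dtype=float), 2.0, source, 16.0,
                       None if timecourses is None else np.asarray(timecourses, float))


class TestTrialTensor:
    def test_constant_trace_constant_entries(self, gratings_session):
        proto = gratings_session.protocol
        traces = np.full((2, proto.total_frames), 3.5)
        t = pc.build_trial_tensor(traces, proto, 2.0)
        np.testing.assert_allclose(t.values, 3.5)

    def test_gratings_shape(self, gratings_session, gratings_dff):
        t = pc.build_trial_tensor(gratings_dff.dff, gratings_session.protocol, 2.0)
        assert t.values.shape == (30, 8, 16)

    def test_window_mean_matches_manual_slice(self, gratings_session):
        proto = gratings_session.protocol
        rng = np.random.default_rng(0)
        traces = rng.normal(0, 1, (1, proto.total_frames))
        t = pc.build_trial_tensor(traces, proto, 1.0)
        p = proto.presentations[5]
        manual = traces[0, p.onset_frame : p.onset_frame + 16].mean()
        assert t.values[0, p.label, 0 if p.label != 5 else 0] == pytest.approx(manual)

    def test_long_window_truncated(self, gratings_session, caplog):
        proto = gratings_session.protocol
        traces = np.zeros((1, proto.total_frames))
        t = pc.build_trial_tensor(traces, proto, 10.0)
        assert t.timecourses is None


class TestResponsiveness:
    def test_flat_neuron_not_responsive(self):
        vals = np.full((1, 8, 16), 2.0)
        blanks = np.full((1, 128), 2.0)
        assert not pc.classify_visually_responsive(tensor_of(vals), blanks)[0]

    def test_tuned_neuron_responsive(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.05, (1, 8, 16))
        vals[0, 3] += 2.0
        blanks = rng.normal(0, 0.05, (1, 128))
        assert pc.classify_visually_responsive(tensor_of(vals), blanks)[0]

    def test_null_type_one_rate_calibrated(self):
        """Pure-noise neurons: false-positive rate <= 0.015 at the 0.01
        criterion (2000 simulated neurons)."""
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (2000, 8, 16))
        blanks = rng.normal(0, 1, (2000, 128))
        flags = pc.classify_visually_responsive(tensor_of(vals), blanks)
        assert flags.mean() <= 0.015


class TestTuning:
    def test_single_peak_curve(self):
        vals = np.zeros((1, 8, 2))
        vals[0, 3] = 10.0
        t = pc.compute_tuning(tensor_of(vals))
        assert t.preferred_direction[0] == 3
        assert t.max_response[0] == 10.0
        assert t.centered_curve[0, 0] == 10.0

    def test_uniform_tie_breaks_low(self):
        t = pc.compute_tuning(tensor_of(np.ones((1, 8, 4))))
        assert t.preferred_direction[0] == 0

    def test_all_zero_flagged(self):
        t = pc.compute_tuning(tensor_of(np.zeros((1, 8, 4))))
        assert t.max_response[0] == 0 and t.osi[0] == 0 and not t.osi_defined[0]

    def test_preferred_direction_recovery(self):
        """von Mises neurons at generator-like SNR: argmax recovers the true
        preferred direction in >= 95% of 200 neurons."""
        rng = np.random.default_rng(3)
        kappa, n = 1.5, 200
        pref = rng.integers(0, 8, n)
        theta = np.arange(8) * 45.0
        curves = np.exp(kappa * (np.cos(np.deg2rad(theta[None] - 45.0 * pref[:, None])) - 1))
        vals = curves[:, :, None] + rng.normal(0, 0.25, (n, 8, 16))
        t = pc.compute_tuning(tensor_of(vals))
        assert (t.preferred_direction == pref).mean() >= 0.95

    def test_baseline_subtraction_restores_scale_invariance(self):
        rng = np.random.default_rng(4)
        curve = np.exp(1.5 * (np.cos(np.deg2rad(np.arange(8) * 45.0)) - 1))
        vals = 0.3 + curve[None, :, None] + np.zeros((1, 8, 6))
        scaled = 0.3 + 0.6 * curve[None, :, None] + np.zeros((1, 8, 6))
        b = np.full(1, 0.3)
        t1 = pc.compute_tuning(tensor_of(vals), baseline=b)
        t2 = pc.compute_tuning(tensor_of(scaled), baseline=b)
        assert t1.osi[0] == pytest.approx(t2.osi[0], abs=1e-12)


class TestOsi:
    @pytest.mark.parametrize(
        "curve, expected",
        [
            ([10, 0, 0, 0, 10, 0, 0, 0], 1.0),
            ([5, 5, 5, 5, 5, 5, 5, 5], 0.0),
            ([6, 0, 2, 0, 6, 0, 2, 0], 0.5),
        ],
    )
    def test_reference_values(self, curve, expected):
        osi, defined = pc.compute_osi(np.array(curve, dtype=float))
        assert defined and osi == expected

    def test_zero_denominator_flagged(self):
        osi, defined = pc.compute_osi(np.zeros(8))
        assert osi == 0.0 and not defined

    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        curve = rng.uniform(0, 5, 8)
        assert pc.compute_osi(curve)[0] == pytest.approx(
            pc.compute_osi(scale * curve)[0], abs=1e-12
        )


class TestReliability:
    def test_identical_trials(self):
        trials = np.tile(np.sin(np.linspace(0, 6, 32)), (5, 1))
        assert pc.reliability_index(trials) == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        x = np.sin(np.linspace(0, 6, 32))
        assert pc.reliability_index(np.vstack([x, -x])) == pytest.approx(-1.0)

    def test_enumerated_pair_oracle(self):
        """Equals the mean over all C(4,2) trial-pair Pearson correlations."""
        rng = np.random.default_rng(5)
        trials = rng.normal(0, 1, (4, 10))
        expected = np.mean(
            [np.corrcoef(trials[a], trials[b])[0, 1] for a, b in combinations(range(4), 2)]
        )
        assert pc.reliability_index(trials) == pytest.approx(expected, abs=1e-12)

    def test_white_noise_near_zero(self):
        vals = []
        rng = np.random.default_rng(6)
        for _ in range(100):
            vals.append(pc.reliability_index(rng.normal(0, 1, (32, 32))))
        assert -0.05 < np.mean(vals) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        trials = rng.normal(0, 1, (6, 20))
        scaled = 3.0 * trials + 11.0
        assert pc.reliability_index(scaled) == pytest.approx(
            pc.reliability_index(trials), abs=1e-12
        )

    def test_zero_variance_trial_skipped(self):
        x = np.vstack([np.zeros(10), np.arange(10.0), 2 * np.arange(10.0)])
        assert pc.reliability_index(x) == pytest.approx(1.0)  # only defined pair

    def test_preferred_movie_selection(self, movie_session):
        d = pc.compute_dff(movie_session.recording)
        t = pc.build_trial_tensor(d.dff, movie_session.protocol, 2.0, keep_time=True)
        rel = pc.neuron_reliability(t)
        assert rel.shape == (20,)
        assert np.isfinite(rel).all()


class TestTables:
    def test_neuron_metrics_frame(self):
        vals = np.zeros((3, 8, 2))
        vals[:, 1] = 1.0
        t = pc.compute_tuning(tensor_of(vals))
        df = pc.neuron_metrics_frame(np.array([True, False, True]), t,
                                     firing_rate=np.array([1.0, 2.0, 3.0]))
        assert list(df.columns) == [
            "neuron_id", "responsive", "preferred_direction", "osi",
            "max_response", "firing_rate",
        ]
        assert len(df) == 3 and df["responsive"].sum() == 2

    def test_correlation_frame(self):
        rng = np.random.default_rng(20)
        cs = pc.pairwise_correlation(rng.normal(0, 1, (4, 100)))
        df = cs.to_frame()
        assert list(df.columns) == ["i", "j", "kind", "r"] and len(df) == 6


class TestPairwiseCorrelation:
    def test_linear_dependence(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 500)
        cs = pc.pairwise_correlation(np.vstack([x, 2 * x]))
        assert cs.values[0] == pytest.approx(1.0)

    def test_pair_count(self):
        rng = np.random.default_rng(9)
        cs = pc.pairwise_correlation(rng.normal(0, 1, (3, 200)))
        assert len(cs.values) == 3

    def test_independent_neurons_uncorrelated(self):
        rng = np.random.default_rng(10)
        cs = pc.pairwise_correlation(rng.normal(0, 1, (6, 100_000)))
        assert abs(np.nanmean(cs.values)) < 0.02

    def test_protocol_restricts_to_on_frames(self, gratings_session):
        proto = gratings_session.protocol
        rng = np.random.default_rng(11)
        act = rng.normal(0, 1, (2, proto.total_frames))
        off = proto.frame_labels() < 0
        act[1] = act[0]
        act[1, off] = -act[0, off]  # disagreement only during OFF frames
        cs = pc.pairwise_correlation(act, proto)
        assert cs.values[0] == pytest.approx(1.0)


class TestSignalCorrelation:
    def test_identical_tuning(self):
        rng = np.random.default_rng(12)
        base = np.array([1, 2, 5, 2, 1, 0.5, 0.2, 0.5])
        vals = np.stack([base[:, None] + rng.normal(0, 0.01, (8, 6)) for _ in range(2)])
        cs = pc.signal_correlation(tensor_of(vals))
        assert cs.values[0] > 0.99

    def test_orthogonal_preferences_negative(self):
        theta = np.deg2rad(np.arange(8) * 45.0)
        a = np.exp(1.5 * (np.cos(theta) - 1))
        b = np.exp(1.5 * (np.cos(theta - np.pi / 2) - 1))
        vals = np.stack([np.tile(a[:, None], 3), np.tile(b[:, None], 3)])
        cs = pc.signal_correlation(tensor_of(vals))
        assert cs.values[0] < 0

    def test_shuffled_labels_decorrelate(self):
        rng = np.random.default_rng(13)
        base = np.array([1, 2, 5, 2, 1, 0.5, 0.2, 0.5])
        means = []
        for _ in range(200):
            vals = np.stack(
                [np.tile(base[:, None], 3), np.tile(base[rng.permutation(8), None], 3)]
            )
            means.append(pc.signal_correlation(tensor_of(vals)).values[0])
        assert abs(np.mean(means)) < 0.1


class TestNoiseCorrelation:
    def test_hand_zscore_oracle(self):
        """Matches a hand z-scored computation on a 2-neuron, 2-condition,
        3-trial toy."""
        vals = np.array(
            [[[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]],
             [[2.0, 1.0, 3.0], [10.0, 6.0, 2.0]]]
        )
        def z(x):
            return (x - x.mean()) / x.std(ddof=1)
        v0 = np.concatenate([z(vals[0, 0]), z(vals[0, 1])])
        v1 = np.concatenate([z(vals[1, 0]), z(vals[1, 1])])
        expected = np.corrcoef(v0, v1)[0, 1]
        cs = pc.noise_correlation(tensor_of(vals))
        assert cs.values[0] == pytest.approx(expected, abs=1e-12)

    def test_shared_jitter_raises_noise_correlation(self):
        rng = np.random.default_rng(14)
        curve = np.array([1, 2, 5, 2, 1, 0.5, 0.2, 0.5])
        prev = -1.0
        for sd in (0.1, 0.4, 0.8):
            shared = rng.normal(0, sd, (1, 8, 16))
            vals = curve[None, :, None] * np.exp(
                np.concatenate([shared, shared]) + rng.normal(0, 0.05, (2, 8, 16))
            )
            r = pc.noise_correlation(tensor_of(vals)).values[0]
            assert r > prev
            prev = r

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(0, 1, (40, 8, 16))
        cs = pc.noise_correlation(tensor_of(vals))
        assert abs(np.nanmean(cs.values)) < 0.02

    def test_zscoring_removes_tuning(self):
        """Tuned neurons with independent noise: signal correlation 1 but
        noise correlation ~ 0."""
        rng = np.random.default_rng(16)
        curve = np.array([1, 2, 5, 2, 1, 0.5, 0.2, 0.5])
        rs = []
        for _ in range(50):
            vals = curve[None, :, None] + rng.normal(0, 0.3, (2, 8, 16))
            rs.append(pc.noise_correlation(tensor_of(vals)).values[0])
        sig = pc.signal_correlation(
            tensor_of(np.tile(curve[None, :, None], (2, 1, 3)))
        ).values[0]
        assert sig == pytest.approx(1.0)
        assert abs(np.mean(rs)) < 0.05

    def test_degenerate_condition_dropped(self):
        vals = np.ones((2, 2, 3))
        vals[0, 0] = [1, 2, 3]
        vals[1, 0] = [3, 1, 2]
        vals[0, 1] = [1, 1, 1]  # zero variance for neuron 0, condition 1
        vals[1, 1] = [5, 6, 7]
        cs = pc.noise_correlation(tensor_of(vals))
        expected = np.corrcoef(
            (np.array([1, 2, 3]) - 2) / 1.0, (np.array([3, 1, 2]) - 2) / 1.0
        )[0, 1]
        assert cs.values[0] == pytest.approx(expected, abs=1e-12)
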