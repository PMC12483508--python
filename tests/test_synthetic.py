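import numpy as np
import pytest

import popcode as pc
from popcode.synthetic import EVENT_AMPLITUDE, make_population, simulate_rates


def cfg(**kw):
    kw.setdefault("n_neurons", 20)
    kw.setdefault("seed", 1)
    return pc.SimulationConfig(**kw)


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="fractions"):
            cfg(frac_tuned=0.8, frac_behavior_coupled=0.3)
        with pytest.raises(ValueError, match="must be >= 0"):
            cfg(baseline_rate_hz=-1)

    def test_knockout_factory_axes(self):
        c, k = pc.SimulationConfig.control(10), pc.SimulationConfig.knockout(10)
        assert k.gain_factor < 1.0 == c.gain_factor
        assert k.trial_noise_sd > c.trial_noise_sd
        assert k.baseline_rate_hz < c.baseline_rate_hz


class TestPopulation:
    def test_all_tuned_when_fraction_one(self):
        t = make_population(cfg(frac_tuned=1.0, frac_behavior_coupled=0, frac_noise=0))
        assert t.is_tuned.all() and (t.tuning_gain > 0).all()

    def test_no_tuning_when_fraction_zero(self):
        t = make_population(cfg(frac_tuned=0.0))
        assert (t.tuning_gain == 0).all()

    def test_seed_determinism(self):
        a, b = make_population(cfg(seed=7)), make_population(cfg(seed=7))
        for f in ("preferred_direction", "tuning_gain", "behavior_weights",
                  "latent_loadings"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_preferred_directions_on_protocol_grid(self):
        t = make_population(cfg(n_neurons=200, frac_tuned=1.0,
                                frac_behavior_coupled=0, frac_noise=0))
        assert set(np.unique(t.preferred_direction)) <= set(np.arange(8) * 45.0)


class TestBehavior:
    def test_determinism(self):
        a = pc.simulate_behavior(500, seed=3)
        b = pc.simulate_behavior(500, seed=3)
        np.testing.assert_array_equal(a.running, b.running)
        np.testing.assert_array_equal(a.pupil, b.pupil)

    def test_zero_noise_constant(self):
        b = pc.simulate_behavior(200, seed=0, running_sigma=0.0, pupil_sigma=0.0)
        assert np.ptp(b.running) == 0 and np.ptp(b.pupil) == 0

    def test_pupil_slow_autocorrelation(self):
        """Pupil dynamics are slow: lag-1 autocorrelation > 0.9 on average."""
        acs = []
        for seed in range(30):
            p = pc.simulate_behavior(5000, seed=seed).pupil
            acs.append(np.corrcoef(p[:-1], p[1:])[0, 1])
        assert np.mean(acs) > 0.9

    def test_nonnegative(self):
        b = pc.simulate_behavior(3000, seed=9, running_sigma=6.0)
        assert b.running.min() >= 0 and b.pupil.min() >= 0


class TestRates:
    def quiet_truth(self, n=4, pref=0.0):
        gain = np.full(n, 5.0)
        return pc.GroundTruth(
            preferred_direction=np.full(n, pref),
            tuning_gain=gain,
            behavior_weights=np.zeros((n, 2)),
            is_tuned=np.ones(n, dtype=bool),
            is_behavior_coupled=np.zeros(n, dtype=bool),
            latent_loadings=np.zeros((n, 0)),
        )

    def test_untuned_rate_is_baseline(self):
        c = cfg(n_neurons=4, frac_tuned=0, frac_behavior_coupled=0, frac_noise=1,
                latent_dim=0, baseline_rate_hz=2.0)
        truth = make_population(c)
        proto = pc.make_protocol("gratings")
        beh = pc.simulate_behavior(proto.total_frames, seed=1)
        rates = simulate_rates(truth, proto, beh, c)
        np.testing.assert_allclose(rates, 2.0)

    def test_tuning_sharpens_with_kappa(self):
        """ON-frame response ratio preferred vs orthogonal grows with kappa."""
        proto = pc.make_protocol("gratings")
        beh = pc.simulate_behavior(proto.total_frames, seed=1)
        truth = self.quiet_truth(n=1, pref=0.0)
        ratios = []
        for kappa in (0.5, 1.0, 2.0, 4.0):
            c = cfg(n_neurons=1, tuning_kappa=kappa, trial_noise_sd=0.0, latent_dim=0,
                    baseline_rate_hz=0.0)
            r = simulate_rates(truth, proto, beh, c, seed=0)
            labels = proto.frame_labels()
            ratios.append(r[0, labels == 0].mean() / r[0, labels == 2].mean())
        assert all(np.diff(ratios) > 0)

    def test_gain_scaling_exact(self):
        """gain_factor scales the evoked rate above baseline exactly (pre-clip)."""
        proto = pc.make_protocol("gratings")
        beh = pc.simulate_behavior(proto.total_frames, seed=1)
        truth = self.quiet_truth()
        base = dict(n_neurons=4, latent_dim=0, baseline_rate_hz=1.0)
        r1 = simulate_rates(truth, proto, beh, cfg(gain_factor=1.0, **base),
                            seed=5, clip_negative=False)
        r06 = simulate_rates(truth, proto, beh, cfg(gain_factor=0.6, **base),
                             seed=5, clip_negative=False)
        np.testing.assert_allclose(r06 - 1.0, 0.6 * (r1 - 1.0), atol=1e-12)

    def test_behavior_length_mismatch_rejected(self):
        proto = pc.make_protocol("gratings")
        beh = pc.simulate_behavior(100, seed=1)
        with pytest.raises(ValueError, match="behavior length"):
            simulate_rates(self.quiet_truth(), proto, beh, cfg(n_neurons=4))


class TestSpikes:
    def test_zero_rate_zero_spikes(self):
        assert pc.spikes_from_rates(np.zeros((3, 100))).sum() == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            pc.spikes_from_rates(np.full((1, 10), -1.0))

    def test_poisson_mean_and_fano(self):
        """Constant 16 Hz at 16 Hz frames: ~1 count/frame, Fano ~ 1."""
        counts = pc.spikes_from_rates(np.full((1, 10000), 16.0), 16.0, seed=2)[0]
        se = 1.0 / np.sqrt(10000)
        assert abs(counts.mean() - 1.0) < 3 * se
        assert abs(counts.var() / counts.mean() - 1.0) < 0.05

    def test_independence_without_shared_sources(self):
        """latent_dim=0 and no behavior coupling: pairwise spike correlations
        vanish (|mean r| < 0.01 over 1e5 frames)."""
        rng = np.random.default_rng(0)
        rates = np.full((8, 100_000), 4.0)
        spk = pc.spikes_from_rates(rates, 16.0, seed=3).astype(float)
        cs = pc.pairwise_correlation(spk)
        assert abs(np.nanmean(cs.values)) < 0.01


class TestFluorescence:
    def test_single_event_exponential(self):
        c = cfg(n_neurons=1, noise_sd_fluo=0.0, neuropil_coupling=0.0)
        ev = np.zeros((1, 50))
        ev[0, 10] = 1
        rec = pc.fluorescence_from_spikes(ev, c, seed=0)
        trace = rec.F_raw[0] - rec.F_raw[0, 0]
        gamma = np.exp(-1.0 / (c.calcium_tau_s * c.frame_rate_hz))
        expected = np.zeros(50)
        expected[10:] = EVENT_AMPLITUDE * gamma ** np.arange(40)
        np.testing.assert_allclose(trace, expected, atol=1e-12)

    def test_flat_without_events_or_noise(self):
        c = cfg(n_neurons=2, noise_sd_fluo=0.0, neuropil_coupling=0.0)
        rec = pc.fluorescence_from_spikes(np.zeros((2, 100)), c, seed=0)
        assert np.ptp(rec.F_raw) == 0

    def test_kernel_mass_is_geometric_series(self):
        """Total fluorescence per unit event equals the geometric-series sum
        amplitude / (1 - gamma) exactly."""
        c = cfg(n_neurons=1, noise_sd_fluo=0.0, neuropil_coupling=0.0)
        ev = np.zeros((1, 2000))
        ev[0, 0] = 1
        rec = pc.fluorescence_from_spikes(ev, c, seed=0)
        gamma = np.exp(-1.0 / (c.calcium_tau_s * c.frame_rate_hz))
        mass = (rec.F_raw[0] - rec.F_raw[0, -1]).sum()
        np.testing.assert_allclose(mass, EVENT_AMPLITUDE / (1 - gamma), rtol=1e-6)

    def test_tau_validation(self):
        with pytest.raises(ValueError):
            pc.fluorescence_from_spikes(np.zeros((1, 10)), cfg(n_neurons=1, calcium_tau_s=0.0))


class TestSession:
    def test_full_determinism(self):
        a = pc.simulate_session(cfg(seed=11), "gratings")
        b = pc.simulate_session(cfg(seed=11), "gratings")
        np.testing.assert_array_equal(a.recording.F_raw, b.recording.F_raw)
        np.testing.assert_array_equal(a.spikes, b.spikes)

    def test_recording_matches_protocol_span(self, gratings_session):
        s = gratings_session
        assert s.recording.n_frames == s.protocol.total_frames
        assert s.truth.n_neurons == s.recording.n_neurons

    def test_hdf5_round_trip(self, tmp_path, movie_session):
        from popcode.session_io import load_session, save_session

        path = tmp_path / "session.h5"
        save_session(movie_session, path)
        back = load_session(path)
        np.testing.assert_array_equal(back.recording.F_raw, movie_session.recording.F_raw)
        np.testing.assert_array_equal(
            back.truth.preferred_direction, movie_session.truth.preferred_direction
        )
        assert back.protocol.presentations == movie_session.protocol.presentations
        assert back.config == movie_session.config

    def test_derived_trace_round_trip(self, tmp_path, gratings_session, gratings_dff):
        from popcode.session_io import read_traces, save_session, write_traces

        path = tmp_path / "session.h5"
        save_session(gratings_session, path)
        events = pc.deconvolve(
            pc.DffTraces(gratings_dff.dff[:4], gratings_dff.f0[:4], 16.0,
                         gratings_dff.valid[:4])
        )
        sub = pc.DffTraces(gratings_dff.dff[:4], gratings_dff.f0[:4], 16.0,
                           gratings_dff.valid[:4])
        write_traces(path, sub, events)
        dff_back, events_back = read_traces(path)
        np.testing.assert_array_equal(dff_back.dff, sub.dff)
        np.testing.assert_array_equal(events_back.events, events.events)
        assert events_back.tau_s == 0.5
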