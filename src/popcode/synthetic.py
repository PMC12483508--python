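"""Synthetic two-photon sessions with known ground truth.

The generator emulates an awake mouse V1 population recorded at 16 Hz under
the three stimulus protocols (gray screen, 8-direction drifting gratings,
7-clip natural movies), together with running-speed and pupil covariates.
Neurons are split into disjoint groups — orientation-tuned, behavior-coupled,
pure-noise, and untuned-but-latent-coupled — and spike counts are drawn from
an inhomogeneous Poisson process whose rate combines:

* a spontaneous baseline,
* a von Mises tuning term gated by the stimulus, scaled by a condition-level
  ``gain_factor`` and a per-presentation log-normal trial jitter,
* linear coupling to z-scored running and pupil series,
* a low-dimensional shared latent (correlated variability).

Fluorescence is the exponential-kernel convolution of the spike train plus a
shared low-pass neuropil signal mixed into the raw trace, additive Gaussian
noise, and a separate neuropil channel so preprocessing can invert the mixing.

The ``knockout`` condition models a reduced-inhibition phenotype along three
axes: lower evoked gain, lower spontaneous rate, and larger trial-to-trial
gain jitter; tuning preferences and the correlation-generating latent are
left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import Behavior, PopulationRecording
from .protocols import GRATING_DIRECTIONS_DEG, StimulusProtocol, make_protocol

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticSession",
    "make_population",
    "simulate_behavior",
    "simulate_rates",
    "spikes_from_rates",
    "fluorescence_from_spikes",
    "simulate_session",
]

# Fluorescence scale: one spike adds a transient of EVENT_AMPLITUDE on top of
# a unit somatic baseline, i.e. a single-spike dF/F of ~0.2 (jRGECO-like).
EVENT_AMPLITUDE = 0.2
SOMA_BASELINE = 1.0
NEUROPIL_BASELINE = 0.5
NEUROPIL_SD = 0.05
NEUROPIL_TAU_S = 1.5
# Mean peak evoked rate (Hz) of tuned neurons at their preferred direction;
# with the 0.2 dF/F single-event amplitude and a 0.5 s decay this drives peak
# evoked dF/F ~ 1, a strongly responsive V1 neuron.
EVOKED_RATE_HZ = 10.0
LATENT_TAU_S = 1.0
# Fraction of the trial-gain jitter variance shared across neurons (population
# gain fluctuation) when a shared latent is enabled (latent_dim >= 1); with
# latent_dim = 0 all trial jitter is private and neurons are independent.
SHARED_JITTER_RHO = 0.5


@dataclass
class SimulationConfig:
    """Knobs of one simulated session.

    The ``control``/``knockout`` factories encode the two experimental
    conditions; ``knockout`` differs along exactly three axes (evoked gain,
    spontaneous rate, trial gain jitter).
    """

    n_neurons: int
    frame_rate_hz: float = 16.0
    condition: str = "control"
    gain_factor: float = 1.0
    baseline_rate_hz: float = 1.0
    trial_noise_sd: float = 0.4
    tuning_kappa: float = 1.5
    frac_tuned: float = 0.6
    frac_behavior_coupled: float = 0.2
    frac_noise: float = 0.1
    latent_dim: int = 2
    calcium_tau_s: float = 0.5
    noise_sd_fluo: float = 0.02
    neuropil_coupling: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.condition not in ("control", "knockout"):
            raise ValueError("condition must be 'control' or 'knockout'")
        for name in ("gain_factor", "baseline_rate_hz", "trial_noise_sd",
                     "tuning_kappa", "calcium_tau_s", "noise_sd_fluo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fracs = (self.frac_tuned, self.frac_behavior_coupled, self.frac_noise)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("fractions must lie in [0,1] and sum to <= 1")
        if not 0 <= self.neuropil_coupling <= 1:
            raise ValueError("neuropil_coupling must lie in [0,1]")
        if self.latent_dim < 0:
            raise ValueError("latent_dim must be >= 0")

    @classmethod
    def control(cls, n_neurons: int, seed: int = 0, **kw) -> "SimulationConfig":
        return cls(n_neurons=n_neurons, condition="control", seed=seed, **kw)

    @classmethod
    def knockout(cls, n_neurons: int, seed: int = 0, **kw) -> "SimulationConfig":
        """Knockout condition: evoked gain 0.6x, baseline 0.7x, trial jitter 1.0."""
        kw.setdefault("gain_factor", 0.6)
        kw.setdefault("baseline_rate_hz", 0.7)
        kw.setdefault("trial_noise_sd", 1.0)
        return cls(n_neurons=n_neurons, condition="knockout", seed=seed, **kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """Generative parameters of each simulated neuron."""

    preferred_direction: np.ndarray   # degrees in [0, 360)
    tuning_gain: np.ndarray           # peak evoked rate, Hz; 0 for untuned
    behavior_weights: np.ndarray      # neurons x 2 (running, pupil), Hz per z-unit
    is_tuned: np.ndarray
    is_behavior_coupled: np.ndarray
    latent_loadings: np.ndarray       # neurons x latent_dim, Hz per latent z-unit

    def __post_init__(self) -> None:
        if np.any(self.tuning_gain[~self.is_tuned] != 0):
            raise ValueError("untuned neurons must have tuning_gain == 0")
        if np.any(self.behavior_weights[~self.is_behavior_coupled] != 0):
            raise ValueError("non-coupled neurons must have zero behavior weights")

    @property
    def n_neurons(self) -> int:
        return self.preferred_direction.size


@dataclass
class SyntheticSession:
    """One fully simulated session with its generative ground truth."""

    recording: PopulationRecording
    protocol: StimulusProtocol
    truth: GroundTruth
    config: SimulationConfig
    spikes: np.ndarray | None = None
    rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.recording.n_frames != self.protocol.total_frames:
            raise ValueError("recording length must equal the protocol span")
        if self.truth.n_neurons != self.recording.n_neurons:
            raise ValueError("ground-truth dimensions must match n_neurons")


def _sub_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


def make_population(config: SimulationConfig) -> GroundTruth:
    """Draw per-neuron generative parameters.

    Neurons are partitioned (by a seeded permutation) into tuned,
    behavior-coupled, pure-noise, and untuned groups according to the config
    fractions.  Preferred directions are uniform over the 8 protocol
    directions; peak evoked rates are log-normal around ``EVOKED_RATE_HZ``.
    Pure-noise neurons carry no latent loading.
    """
    rng = _sub_rng(config.seed, 0)
    n = config.n_neurons
    order = rng.permutation(n)
    n_tuned = int(round(config.frac_tuned * n))
    n_beh = int(round(config.frac_behavior_coupled * n))
    n_noise = int(round(config.frac_noise * n))
    is_tuned = np.zeros(n, dtype=bool)
    is_beh = np.zeros(n, dtype=bool)
    is_pure_noise = np.zeros(n, dtype=bool)
    is_tuned[order[:n_tuned]] = True
    is_beh[order[n_tuned : n_tuned + n_beh]] = True
    is_pure_noise[order[n_tuned + n_beh : n_tuned + n_beh + n_noise]] = True

    preferred = rng.integers(0, 8, size=n) * 45.0
    gain = np.where(
        is_tuned, EVOKED_RATE_HZ * np.exp(rng.normal(0.0, 0.2, size=n)), 0.0
    )
    weights = np.zeros((n, 2))
    weights[is_beh, 0] = rng.normal(0.5, 0.4, size=n_beh)   # running
    weights[is_beh, 1] = rng.normal(0.3, 0.3, size=n_beh)   # pupil
    loadings = np.zeros((n, config.latent_dim))
    if config.latent_dim > 0:
        loadings[:, 0] = np.abs(rng.normal(0.8, 0.3, size=n))
        if config.latent_dim > 1:
            loadings[:, 1:] = rng.normal(0.0, 0.3, size=(n, config.latent_dim - 1))
        loadings[is_pure_noise] = 0.0
    return GroundTruth(preferred, gain, weights, is_tuned, is_beh, loadings)


def _ou_series(
    n_frames: int, dt: float, mean: float, tau_s: float, sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-reverting (Ornstein–Uhlenbeck) series started at its mean."""
    x = np.empty(n_frames)
    x[0] = mean
    noise = rng.standard_normal(n_frames - 1) if n_frames > 1 else np.empty(0)
    a = dt / tau_s
    s = sigma * np.sqrt(dt)
    for t in range(1, n_frames):
        x[t] = x[t - 1] + (mean - x[t - 1]) * a + s * noise[t - 1]
    return x


def simulate_behavior(
    n_frames: int,
    frame_rate_hz: float = 16.0,
    seed: int = 0,
    running_sigma: float = 2.0,
    pupil_sigma: float = 4.0,
) -> Behavior:
    """Slowly varying, positive running-speed and pupil-diameter series.

    Both are mean-reverting processes clipped at zero: running speed with a
    3 s timescale around 4 cm/s, pupil diameter with an 8 s timescale around
    40 a.u. (lag-1 autocorrelation ~0.99 at 16 Hz).
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    running = _ou_series(n_frames, dt, mean=4.0, tau_s=3.0, sigma=running_sigma, rng=rng)
    pupil = _ou_series(n_frames, dt, mean=40.0, tau_s=8.0, sigma=pupil_sigma, rng=rng)
    return Behavior(np.clip(running, 0.0, None), np.clip(pupil, 0.0, None))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _condition_angles(protocol: StimulusProtocol) -> np.ndarray:
    if protocol.kind == "gratings":
        return GRATING_DIRECTIONS_DEG.copy()
    # Movie clips have no intrinsic angle; clips are spread over the circle so
    # the same tuning machinery yields heterogeneous clip preferences.
    return np.arange(protocol.n_conditions) * (360.0 / max(protocol.n_conditions, 1))


def _stimulus_envelopes(
    n_neurons: int, protocol: StimulusProtocol, seed: int
) -> np.ndarray | None:
    """Per-(neuron, clip) smooth temporal envelope, mean 1, trial-invariant.

    Movies drive time-varying, stimulus-locked responses; gratings are modeled
    as sustained.  The envelope is what makes repeated movie trials correlate
    in time (the substrate of the reliability index).
    """
    if protocol.kind != "movies" or not protocol.presentations:
        return None
    dur = protocol.presentations[0].duration_frames
    rng = np.random.default_rng(np.random.SeedSequence((seed, 977)).generate_state(2))
    raw = rng.standard_normal((n_neurons, protocol.n_conditions, dur))
    env = gaussian_filter1d(raw, sigma=3.0, axis=-1, mode="wrap")
    env = np.clip(env * 2.0 + 1.0, 0.05, None)
    env /= env.mean(axis=-1, keepdims=True)  # exact mean 1 per (neuron, clip)
    return env


def simulate_rates(
    truth: GroundTruth,
    protocol: StimulusProtocol,
    behavior: Behavior,
    config: SimulationConfig,
    seed: int | None = None,
    clip_negative: bool = True,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of every neuron at every frame.

    rate = baseline
         + jitter * gain_factor * tuning_gain * vonMises(theta - preferred) * envelope
         + behavior_weights . z(behavior)
         + latent_loadings . latent(t)

    with the tuning term present only during ON frames, a log-normal
    per-(neuron, presentation) jitter of log-scale sd ``trial_noise_sd``
    (unit mean), and the result floored at zero unless ``clip_negative`` is
    off.  Multiplying ``gain_factor`` by g scales the mean evoked rate above
    baseline by exactly g (before flooring).
    """
    if behavior.n_frames != protocol.total_frames:
        raise ValueError("behavior length must equal protocol span")
    if seed is None:
        seed = config.seed
    rng = _sub_rng(seed, 2)
    n, T = truth.n_neurons, protocol.total_frames
    rate = np.full((n, T), config.baseline_rate_hz)

    angles = _condition_angles(protocol)
    kappa = config.tuning_kappa
    envelopes = _stimulus_envelopes(n, protocol, seed)
    rho = SHARED_JITTER_RHO if config.latent_dim >= 1 else 0.0
    for p_idx, p in enumerate(protocol.presentations):
        delta = np.deg2rad(angles[p.label] - truth.preferred_direction)
        vm = np.exp(kappa * (np.cos(delta) - 1.0))
        z = rho * rng.standard_normal() + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        jitter = np.exp(config.trial_noise_sd * z - 0.5 * config.trial_noise_sd**2)
        evoked = jitter * config.gain_factor * truth.tuning_gain * vm
        block = evoked[:, None]
        if envelopes is not None:
            block = block * envelopes[:, p.label, :]
        rate[:, p.onset_frame : p.offset_frame] += block

    if np.any(truth.behavior_weights):
        beh = np.vstack([_zscore(behavior.running), _zscore(behavior.pupil)])
        rate += truth.behavior_weights @ beh
    if config.latent_dim > 0 and np.any(truth.latent_loadings):
        dt = 1.0 / config.frame_rate_hz
        latent = np.vstack(
            [
                _zscore(_ou_series(T, dt, 0.0, LATENT_TAU_S, 1.0, rng))
                for _ in range(config.latent_dim)
            ]
        )
        rate += truth.latent_loadings @ latent
    return np.clip(rate, 0.0, None) if clip_negative else rate


def spikes_from_rates(
    rates: np.ndarray, frame_rate_hz: float = 16.0, seed: int = 0
) -> np.ndarray:
    """Inhomogeneous Poisson spike counts per frame (mean rate / frame rate)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(rates / frame_rate_hz)


def fluorescence_from_spikes(
    events: np.ndarray,
    config: SimulationConfig,
    behavior: Behavior | None = None,
    seed: int | None = None,
) -> PopulationRecording:
    """Raw + neuropil fluorescence from a spike-count matrix.

    The somatic trace is a unit baseline plus the exponential-kernel
    convolution of the events (decay ``calcium_tau_s``); a shared low-pass
    neuropil signal is mixed into the raw channel with per-neuron coupling
    around ``neuropil_coupling``, and emitted separately (plus independent
    sensor noise on both channels) so preprocessing can subtract it.
    """
    events = np.asarray(events, dtype=float)
    if np.any(events < 0):
        raise ValueError("event counts must be nonnegative")
    if config.calcium_tau_s <= 0:
        raise ValueError("calcium_tau_s must be positive")
    if seed is None:
        seed = config.seed
    rng = _sub_rng(seed, 4)
    n, T = events.shape
    gamma = np.exp(-1.0 / (config.calcium_tau_s * config.frame_rate_hz))
    from scipy.signal import lfilter

    calcium = lfilter([EVENT_AMPLITUDE], [1.0, -gamma], events, axis=1)

    shared = _ou_series(T, 1.0 / config.frame_rate_hz, 0.0, NEUROPIL_TAU_S,
                        NEUROPIL_SD * 3.0, rng)
    shared = NEUROPIL_SD * _zscore(shared)
    coupling = np.clip(
        rng.normal(config.neuropil_coupling, 0.1 * config.neuropil_coupling, size=n),
        0.0, 1.0,
    )
    F_neuropil = (
        NEUROPIL_BASELINE
        + shared[None, :]
        + config.noise_sd_fluo * 0.5 * rng.standard_normal((n, T))
    )
    F_raw = (
        SOMA_BASELINE
        + calcium
        + coupling[:, None] * F_neuropil
        + config.noise_sd_fluo * rng.standard_normal((n, T))
    )
    return PopulationRecording(F_raw, F_neuropil, config.frame_rate_hz, behavior)


def simulate_session(config: SimulationConfig, kind: str = "gratings") -> SyntheticSession:
    """Generate a full session: protocol, behavior, rates, spikes, fluorescence.

    One master seed (``config.seed``) deterministically derives the per-stage
    streams, so sessions that share a seed but differ in one config knob see
    identical draws everywhere else.
    """
    protocol = make_protocol(kind, config.frame_rate_hz)
    truth = make_population(config)
    ss = np.random.SeedSequence(config.seed).spawn(6)
    behavior = simulate_behavior(
        protocol.total_frames, config.frame_rate_hz,
        seed=ss[1].generate_state(1)[0] % (2**31),
    )
    rates = simulate_rates(truth, protocol, behavior, config, seed=config.seed)
    spikes = spikes_from_rates(
        rates, config.frame_rate_hz, seed=ss[3].generate_state(1)[0] % (2**31)
    )
    recording = fluorescence_from_spikes(spikes, config, behavior, seed=config.seed)
    return SyntheticSession(recording, protocol, truth, config, spikes=spikes, rates=rates)
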