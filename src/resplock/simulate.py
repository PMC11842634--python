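"""Synthetic response-coupled EEG cohorts.

Generates epoched sessions that emulate the maze-observation paradigm: an
agent acts every action window; with some probability the move is wrong and
the observer produces a fronto-central error-related potential (ErrP).
Concurrently the screen flickers at a fixed frequency for the first part of
each window, driving a parieto-occipital steady-state visual evoked
potential (SSVEP) that is phase-locked to the stimulus with a near-constant
stimulus-to-response phase lag.

Every epoch is the sum of

* pink (1/f) background noise per channel,
* a phase-lagged SSVEP sinusoid active only while the flicker is on,
  delayed from the action onset by the physiological response delay,
* on error trials, a biphasic theta-band ErrP transient over fronto-central
  channels, and an optional attenuation/phase perturbation of the SSVEP
  ("coupling effect"),
* optional spike/blink artifacts, present only to exercise the
  threshold-based rejection rule downstream.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
so identical (config, seed) pairs give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MONTAGE_12",
    "SimulationConfig",
    "ErrPTemplate",
    "SessionData",
    "make_errp_template",
    "pink_noise",
    "simulate_agent_actions",
    "synth_epoch",
    "simulate_session",
    "simulate_cohort",
]

#: The 12-channel montage (occipital, parietal, central, frontal).
MONTAGE_12: tuple[str, ...] = (
    "O1", "O2", "P3", "P4", "Pz", "C3", "C4", "Cz", "F3", "F4", "Fz", "Fpz",
)

# Per-channel SSVEP amplitude (uV): strongest over parieto-occipital sites,
# residual projection over central/frontal sites.  With the default pink-noise
# sigma of 4 uV this puts the 11-16 Hz band-power SNR at O1 near 0 dB.
_DEFAULT_SSVEP_GAIN: dict[str, float] = {
    "O1": 1.5, "O2": 1.5, "P3": 1.0, "P4": 1.0, "Pz": 1.0,
    "C3": 0.4, "C4": 0.4, "Cz": 0.4, "F3": 0.2, "F4": 0.2, "Fz": 0.2,
    "Fpz": 0.2,
}

# Per-channel ErrP amplitude (uV): fronto-central topography with a ~7 uV
# single-trial peak at Cz (typical of response-locked error potentials),
# zero over the parieto-occipital sites so that, absent coupling, the
# narrowband parieto-occipital configuration carries no class information.
_DEFAULT_ERRP_GAIN: dict[str, float] = {
    "O1": 0.0, "O2": 0.0, "P3": 0.0, "P4": 0.0, "Pz": 2.0,
    "C3": 4.5, "C4": 4.5, "Cz": 7.0, "F3": 3.5, "F4": 3.5, "Fz": 6.0,
    "Fpz": 2.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording session.

    Defaults reproduce the experimental conditions: 125 Hz sampling, 1.8 s
    action windows (1.6 s active 12.5 Hz flicker + 200 ms flicker-off),
    agent error probability 0.2, stimulus-to-response phase lag 4.05 rad and
    response delay 0.27 s.
    """

    sampling_rate: float = 125.0
    channels: tuple[str, ...] = MONTAGE_12
    window_s: float = 1.8
    active_s: float = 1.6
    off_s: float = 0.2
    flicker_hz: float = 12.5
    error_prob: float = 0.2
    n_episodes: int = 10
    actions_per_episode: int = 30
    phase_lag_rad: float = 4.05
    response_delay_s: float = 0.27
    ssvep_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SSVEP_GAIN))
    errp_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ERRP_GAIN))
    coupling_effect: float = 0.2
    noise_sigma: float = 4.0
    artifact_rate: float = 0.0
    flicker_phase_locked: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.window_s, self.active_s + self.off_s):
            raise ValueError(
                f"window_s ({self.window_s}) must equal active_s + off_s "
                f"({self.active_s} + {self.off_s})")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError("error_prob must lie in [0, 1]")
        if self.sampling_rate <= 2.0 * self.flicker_hz:
            raise ValueError("sampling_rate must exceed twice flicker_hz")
        if self.n_episodes < 1 or self.actions_per_episode < 1:
            raise ValueError("episode/action counts must be positive")
        for label in self.channels:
            if label not in self.ssvep_gain or label not in self.errp_gain:
                raise ValueError(f"missing gain entry for channel {label!r}")

    @property
    def n_samples(self) -> int:
        """Samples per action window."""
        return round(self.window_s * self.sampling_rate)

    @property
    def n_trials(self) -> int:
        return self.n_episodes * self.actions_per_episode


@dataclass(frozen=True)
class ErrPTemplate:
    """A biphasic error-potential waveform at the session sampling rate.

    The shape is a theta-carrier (6 Hz) under a Gaussian envelope producing
    a negative deflection near 250 ms and a positive one near 330 ms after
    the action onset, so the dominant spectral energy sits in the 4-8 Hz
    band.  The experimental reports constrain only the band and rough
    latency, not the waveform; this template is an explicit modelling
    choice.
    """

    waveform: np.ndarray
    latency_s: float
    band: tuple[float, float]


def make_errp_template(sampling_rate: float = 125.0,
                       window_s: float = 1.8,
                       latency_s: float = 0.25,
                       carrier_hz: float = 6.0,
                       envelope_sigma_s: float = 0.055) -> ErrPTemplate:
    """Build the default biphasic theta-band ErrP template.

    The waveform is ``-cos(2*pi*carrier*(t - latency)) * gauss(t)`` so the
    trough lands at ``latency_s`` and the compensating positive peak half a
    carrier period later.  It is identically zero outside the action window.
    """
    n = round(window_s * sampling_rate)
    t = np.arange(n) / sampling_rate
    center = latency_s + 0.5 / carrier_hz / 2.0  # envelope midway trough->peak
    envelope = np.exp(-0.5 * ((t - center) / envelope_sigma_s) ** 2)
    waveform = -np.cos(2.0 * np.pi * carrier_hz * (t - latency_s)) * envelope
    return ErrPTemplate(waveform=waveform, latency_s=latency_s,
                        band=(4.0, 8.0))


@dataclass
class SessionData:
    """Epoched EEG for one user: ``epochs`` is trials x channels x samples (uV)."""

    epochs: np.ndarray
    labels: np.ndarray
    onsets: np.ndarray
    config: SimulationConfig
    user_id: str = "user00"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must match trial count")
        if len(self.onsets) != self.epochs.shape[0]:
            raise ValueError("onsets length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.config.channels)

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage "
                           f"{self.channels}") from None

    def continuous(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Concatenate epochs along time: channels x (trials * samples).

        Valid because windows tile the recording back-to-back (onsets lie on
        the window grid).
        """
        idx = (slice(None) if labels is None
               else [self.channel_index(c) for c in labels])
        return np.concatenate(
            [self.epochs[i][idx] for i in range(self.n_trials)], axis=-1)

    def subset_trials(self, mask: np.ndarray) -> "SessionData":
        mask = np.asarray(mask, dtype=bool)
        return SessionData(epochs=self.epochs[mask],
                           labels=self.labels[mask],
                           onsets=self.onsets[mask],
                           config=self.config, user_id=self.user_id)

    def subset_channels(self, labels: Sequence[str]) -> "SessionData":
        idx = [self.channel_index(c) for c in labels]
        gains_s = {c: self.config.ssvep_gain[c] for c in labels}
        gains_e = {c: self.config.errp_gain[c] for c in labels}
        cfg = replace(self.config, channels=tuple(labels),
                      ssvep_gain=gains_s, errp_gain=gains_e)
        return SessionData(epochs=self.epochs[:, idx, :],
                           labels=self.labels, onsets=self.onsets,
                           config=cfg, user_id=self.user_id)


def pink_noise(n_samples: int, rng: np.random.Generator,
               sigma: float = 1.0) -> np.ndarray:
    """1/f-amplitude noise with standard deviation ``sigma``.

    White Gaussian noise is shaped in the frequency domain with a
    1/sqrt(f) amplitude profile (power spectral density proportional to 1/f)
    and rescaled to the requested RMS.
    """
    if sigma == 0.0:
        # Consume the same number of draws so seeds stay comparable.
        rng.standard_normal(n_samples)
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shaping, n_samples)
    std = x.std()
    if std > 0:
        x *= sigma / std
    return x


def simulate_agent_actions(error_prob: float, n_actions: int,
                           seed: int) -> np.ndarray:
    """Bernoulli label stream of the maze agent: 1 = erroneous move.

    Independent draws with per-action error probability ``error_prob``;
    reproducible for a fixed seed.
    """
    if not 0.0 <= error_prob <= 1.0:
        raise ValueError("error_prob must lie in [0, 1]")
    if n_actions < 1:
        raise ValueError("n_actions must be >= 1")
    rng = np.random.default_rng(seed)
    return (rng.random(n_actions) < error_prob).astype(int)


def _ssvep_component(config: SimulationConfig, rng: np.random.Generator,
                     is_error: bool) -> np.ndarray:
    """Single-channel unit-gain SSVEP for one window.

    ``sin(2*pi*F0*t + phase_lag)`` supported on
    [response_delay, response_delay + active_s) clipped to the window; the
    phase term enters with a plus sign so that cross-correlation maxima sit
    on the lattice ``tau = n/F0 - phase_lag/(2*pi*F0)``.  On error trials
    the coupling effect attenuates the amplitude and jitters the phase.
    """
    fs = config.sampling_rate
    n = config.n_samples
    t = np.arange(n) / fs
    amplitude = 1.0
    phase = config.phase_lag_rad
    if not config.flicker_phase_locked:
        # Flicker free-running w.r.t. the action grid: phase random per trial.
        phase = phase + rng.uniform(0.0, 2.0 * np.pi)
    if is_error and config.coupling_effect != 0.0:
        amplitude *= 1.0 - config.coupling_effect
        phase += rng.normal(0.0, 0.5 * config.coupling_effect)
    elif config.coupling_effect != 0.0:
        rng.normal()  # keep the draw count label-independent
    wave = amplitude * np.sin(2.0 * np.pi * config.flicker_hz * t + phase)
    start = config.response_delay_s
    stop = config.response_delay_s + config.active_s
    support = (t >= start) & (t < stop)
    out = wave * support
    # The delayed response to the previous window's flicker spills into the
    # start of this window (delay + active may exceed the window length).
    spill = stop - config.window_s
    if spill > 0:
        prev = amplitude * np.sin(
            2.0 * np.pi * config.flicker_hz * (t + config.window_s) + phase)
        out = out + prev * (t < spill)
    return out


def _inject_artifact(epoch: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator) -> None:
    """Add a rectangular spike or a frontal blink transient in place."""
    fs = config.sampling_rate
    n = epoch.shape[1]
    if rng.random() < 0.5:  # rectangular spike on a random channel
        ch = rng.integers(0, epoch.shape[0])
        start = rng.integers(0, n - 4)
        amp = rng.uniform(80.0, 130.0) * rng.choice([-1.0, 1.0])
        epoch[ch, start:start + 3] += amp
    else:  # blink: slow positive lobe over the frontal channels
        width = round(0.3 * fs)
        start = rng.integers(0, max(1, n - width))
        t = np.arange(width) / fs
        lobe = 100.0 * np.sin(np.pi * t / (width / fs)) ** 2
        for label in ("Fpz", "F3", "F4", "Fz"):
            if label in config.channels:
                scale = 1.0 if label == "Fpz" else 0.5
                epoch[config.channels.index(label),
                      start:start + width] += scale * lobe


def synth_epoch(config: SimulationConfig, label: int,
                trial_seed: int | np.random.SeedSequence) -> np.ndarray:
    """One channels x samples epoch for a trial with the given label."""
    rng = np.random.default_rng(trial_seed)
    n = config.n_samples
    n_ch = len(config.channels)
    epoch = np.empty((n_ch, n))
    template = make_errp_template(config.sampling_rate, config.window_s)
    ssvep = _ssvep_component(config, rng, is_error=bool(label))
    for i, ch in enumerate(config.channels):
        x = pink_noise(n, rng, config.noise_sigma)
        x = x + config.ssvep_gain[ch] * ssvep
        if label:
            x = x + config.errp_gain[ch] * template.waveform
        epoch[i] = x
    if config.artifact_rate > 0.0 and rng.random() < config.artifact_rate:
        _inject_artifact(epoch, config, rng)
    return epoch


def simulate_session(config: SimulationConfig,
                     user_id: str = "user00") -> SessionData:
    """Simulate a full session: n_episodes x actions_per_episode epochs."""
    root = np.random.SeedSequence(config.seed)
    label_ss, epoch_ss = root.spawn(2)
    n_trials = config.n_trials
    labels = simulate_agent_actions(
        config.error_prob, n_trials,
        seed=int(label_ss.generate_state(1, dtype=np.uint32)[0]))
    trial_seeds = epoch_ss.spawn(n_trials)
    n = config.n_samples
    epochs = np.stack([
        synth_epoch(config, labels[i], trial_seeds[i])
        for i in range(n_trials)
    ])
    onsets = np.arange(n_trials) * n
    return SessionData(epochs=epochs, labels=labels, onsets=onsets,
                       config=config, user_id=user_id)


def simulate_cohort(n_users: int, per_user_noise: Sequence[float],
                    base_config: SimulationConfig | None = None,
                    seed: int = 0) -> list[SessionData]:
    """One session per user, differing in noise level (and seed).

    ``per_user_noise`` is the handle that makes the SSVEP signal-to-noise
    ratio — and with it both the fidelity score and the detection accuracy —
    vary across the cohort.
    """
    if base_config is None:
        base_config = SimulationConfig()
    if n_users != len(per_user_noise):
        raise ValueError("n_users must equal len(per_user_noise)")
    seeds = np.random.SeedSequence(seed).spawn(n_users)
    cohort = []
    for i in range(n_users):
        user_seed = int(seeds[i].generate_state(1, dtype=np.uint32)[0]
                        % (2 ** 31))
        cfg = replace(base_config, noise_sigma=float(per_user_noise[i]),
                      seed=user_seed)
        cohort.append(simulate_session(cfg, user_id=f"user{i:02d}"))
    return cohort
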