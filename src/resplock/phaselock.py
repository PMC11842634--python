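"""Stimulus-response phase locking and cross-correlation delay analysis.

The flicker stimulus is modelled by its fundamental,
``S0(t) = A0 sin(2 pi F0 t)`` on the active segment of each action window,
and the recorded SSVEP by a copy lagged by a near-constant phase ``Phi``.
Both are lifted to analytic signals via the Hilbert transform; the wrapped
instantaneous phase difference feeds the phase-locking value

    PLV = (1/N) | sum_t exp(j dPhi(t)) |,

which is 1 for perfect locking and near 0 for unrelated phases.

Cross-correlating the stimulus template, advanced by a delay tau, against
the response gives (for a sinusoidal response with mean phase lag Phi)

    C(tau) = N A0 cos(2 pi F0 tau + Phi) * [envelope alignment term],

so local maxima sit on the lattice  tau = n/F0 - delta,  delta = Phi/(2 pi F0),
spaced one flicker period (80 ms at 12.5 Hz) apart.  The per-window delays of
the global maxima are histogrammed; inverting the lattice relation at those
delays recovers the mean phase lag by a circular mean.

The amplitude constants N and A0 scale the correlogram but never move its
maxima; templates default to A0 = 1, making the analysis scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from scipy.stats import circmean

__all__ = [
    "StimulusWaveform", "AnalyticSignal", "PLVSeries", "Correlogram",
    "DelayHistogram", "PhaseLagEstimate",
    "hilbert_analytic", "instantaneous_phase_lag", "plv", "sliding_plv",
    "make_stimulus_template", "cross_correlate", "windowed_correlograms",
    "peak_delay", "find_correlation_maxima", "peak_delay_histogram",
    "estimate_phase_lag",
    "lattice_delay", "occipital_response", "spectrogram",
]

MAX_REPETITIONS = 150


@dataclass(frozen=True)
class StimulusWaveform:
    """Synthetic flicker stimulus: ``repetitions`` action windows, each an
    active sinusoid segment followed by a flicker-off gap of zeros."""

    samples: np.ndarray
    f0: float
    a0: float
    active_s: float
    off_s: float
    repetitions: int
    sampling_rate: float

    @property
    def window_samples(self) -> int:
        return round((self.active_s + self.off_s) * self.sampling_rate)


@dataclass(frozen=True)
class AnalyticSignal:
    """Real series, its Hilbert transform, envelope and wrapped phase."""

    real: np.ndarray
    imag: np.ndarray
    envelope: np.ndarray
    phase: np.ndarray

    def __len__(self) -> int:
        return len(self.real)


@dataclass(frozen=True)
class PLVSeries:
    values: np.ndarray
    window_samples: int
    stride: int


@dataclass(frozen=True)
class Correlogram:
    """Unnormalized cross-correlation values per integer-sample delay."""

    values: np.ndarray
    delays_s: np.ndarray
    window_id: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DelayHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_zone: float


@dataclass(frozen=True)
class PhaseLagEstimate:
    """Mean phase lag (radians in [0, 2 pi)) and the lattice offset
    ``delta = phi_bar / (2 pi F0)`` in seconds."""

    phi_bar: float
    delta: float
    n_windows: int


def hilbert_analytic(x: np.ndarray) -> AnalyticSignal:
    """Analytic signal of a real series: envelope and wrapped phase.

    The imaginary part is the discrete Hilbert transform; phase is wrapped
    to (-pi, pi].
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need a 1-D series of length >= 8")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    analytic = sig.hilbert(x)
    return AnalyticSignal(real=x, imag=analytic.imag,
                          envelope=np.abs(analytic),
                          phase=np.angle(analytic))


def instantaneous_phase_lag(response: AnalyticSignal,
                            stimulus: AnalyticSignal) -> np.ndarray:
    """Per-sample wrapped phase difference response - stimulus, in (-pi, pi]."""
    if len(response) != len(stimulus):
        raise ValueError("series lengths differ")
    return np.angle(np.exp(1j * (response.phase - stimulus.phase)))


def plv(phase_lag: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean unit phasor of the lags."""
    phase_lag = np.asarray(phase_lag, dtype=float)
    if phase_lag.size == 0:
        raise ValueError("empty phase-lag series")
    return float(np.abs(np.mean(np.exp(1j * phase_lag))))


def sliding_plv(response: np.ndarray, stimulus: StimulusWaveform,
                window_s: float = 0.5, stride: int = 1,
                onset_exclude_s: float = 0.2) -> PLVSeries:
    """PLV of the stimulus-response phase lag over sliding windows.

    ``window_samples = floor(window_s * sampling_rate)`` (62 samples for
    0.5 s at 125 Hz).  The first ``onset_exclude_s`` of the series is
    skipped: there is minimal SSVEP activity before the response builds up.
    """
    response = np.asarray(response, dtype=float)
    fs = stimulus.sampling_rate
    window = int(np.floor(window_s * fs))
    n = min(len(response), len(stimulus.samples))
    start = round(onset_exclude_s * fs)
    if window > n - start:
        raise ValueError("window longer than the analyzable series")
    lag = instantaneous_phase_lag(hilbert_analytic(response[:n]),
                                  hilbert_analytic(stimulus.samples[:n]))
    phasors = np.exp(1j * lag)
    csum = np.concatenate([[0.0 + 0.0j], np.cumsum(phasors)])
    starts = np.arange(start, n - window + 1, stride)
    values = np.abs(csum[starts + window] - csum[starts]) / window
    return PLVSeries(values=values, window_samples=window, stride=stride)


def make_stimulus_template(f0: float = 12.5, a0: float = 1.0,
                           repetitions: int = 1,
                           sampling_rate: float = 125.0,
                           active_s: float = 1.6,
                           off_s: float = 0.2) -> StimulusWaveform:
    """Concatenate ``repetitions`` action-window stimulus segments.

    Each segment is ``active_s`` of ``a0 sin(2 pi f0 t)`` (20 full cycles at
    the 12.5 Hz / 1.6 s defaults) followed by ``off_s`` of zeros, one segment
    per action window.
    """
    if not 1 <= repetitions <= MAX_REPETITIONS:
        raise ValueError(f"repetitions must lie in [1, {MAX_REPETITIONS}]")
    n_active = round(active_s * sampling_rate)
    n_off = round(off_s * sampling_rate)
    t = np.arange(n_active) / sampling_rate
    segment = np.concatenate([a0 * np.sin(2.0 * np.pi * f0 * t),
                              np.zeros(n_off)])
    return StimulusWaveform(samples=np.tile(segment, repetitions),
                            f0=f0, a0=a0, active_s=active_s, off_s=off_s,
                            repetitions=repetitions,
                            sampling_rate=sampling_rate)


def cross_correlate(response: np.ndarray,
                    template: StimulusWaveform) -> Correlogram:
    """Unnormalized sliding inner product of the template against the response.

    ``C[k] = sum_j template[j] * response[j + k]`` for every delay ``k`` at
    which the template fits inside the response, i.e. the template is
    advanced by the delay, so a response lagging the stimulus by ``Phi``
    peaks on the lattice ``tau = n/F0 - Phi/(2 pi F0)``.
    """
    response = np.asarray(response, dtype=float)
    t = template.samples
    if len(t) > len(response):
        raise ValueError("template longer than response")
    values = sig.correlate(response, t, mode="valid")
    delays = np.arange(len(values)) / template.sampling_rate
    return Correlogram(values=values, delays_s=delays)


def windowed_correlograms(response: np.ndarray,
                          template: StimulusWaveform,
                          onsets: np.ndarray,
                          window_samples: int) -> list[Correlogram]:
    """Slice a full-recording correlogram into per-action-window pieces.

    Window ``i`` keeps the delays in ``[onset_i, onset_i + window_samples)``
    (re-expressed relative to the onset); trailing windows where the
    template no longer fits are dropped.
    """
    full = cross_correlate(response, template)
    fs = template.sampling_rate
    out: list[Correlogram] = []
    for i, onset in enumerate(np.asarray(onsets, dtype=int)):
        stop = onset + window_samples
        if stop > len(full.values):
            break
        values = full.values[onset:stop]
        delays = (np.arange(onset, stop) - onset) / fs
        out.append(Correlogram(values=values, delays_s=delays, window_id=i))
    return out


def peak_delay(correlogram: Correlogram, interpolate: bool = True) -> float:
    """Delay (s) of the correlogram's global maximum.

    With ``interpolate=True`` the integer-sample peak is refined by a
    parabolic fit through its two neighbours, giving sub-sample delay
    resolution (the correlogram near a maximum is locally a sampled
    cosine, which a parabola approximates well).
    """
    values = np.asarray(correlogram.values, dtype=float)
    i = int(np.argmax(values))
    delays = correlogram.delays_s
    if not interpolate or i == 0 or i == len(values) - 1:
        return float(delays[i])
    denom = values[i - 1] - 2.0 * values[i] + values[i + 1]
    if denom == 0.0:
        return float(delays[i])
    shift = 0.5 * (values[i - 1] - values[i + 1]) / denom
    dt = delays[1] - delays[0]
    return float(delays[i] + np.clip(shift, -0.5, 0.5) * dt)


def find_correlation_maxima(correlogram: Correlogram,
                            min_prominence: float = 0.5) -> np.ndarray:
    """Delays (s) of local maxima above ``min_prominence`` x the global max.

    The global-maximum delay is always included; an all-zero correlogram has
    no maxima; ties break toward the earliest delay.  Endpoints are admitted
    only when the series has no interior peak (e.g. a strictly monotone
    correlogram), since a window boundary cutting through a lobe is an
    artifact of the restriction, not a lattice maximum.
    """
    values = np.asarray(correlogram.values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty correlogram")
    if np.all(values == 0.0):
        return np.array([])
    global_idx = int(np.argmax(values))
    threshold = min_prominence * values[global_idx]
    peaks, _ = sig.find_peaks(values, height=threshold)
    candidates = [peaks, [global_idx]]
    if len(peaks) == 0:
        candidates.append([i for i in (0, len(values) - 1)
                           if values[i] >= threshold
                           and values[i] >= values[1 if i == 0 else -2]])
    idx = np.unique(np.concatenate(candidates).astype(int))
    return correlogram.delays_s[idx]


def peak_delay_histogram(peak_delays: np.ndarray,
                         bin_s: float = 0.008,
                         range_s: tuple[float, float] | None = None
                         ) -> DelayHistogram:
    """Histogram of per-window global-maximum delays.

    The default bin width of one sample (8 ms at 125 Hz) resolves the 80 ms
    maxima lattice.  ``modal_zone`` is the center of the most populated bin
    (earliest such bin on ties).
    """
    peak_delays = np.asarray(peak_delays, dtype=float)
    if peak_delays.size == 0:
        raise ValueError("need at least one window")
    if range_s is None:
        lo = np.floor(peak_delays.min() / bin_s) * bin_s
        hi = np.ceil((peak_delays.max() + 1e-12) / bin_s) * bin_s
        hi = max(hi, lo + bin_s)
        range_s = (lo, hi)
    n_bins = max(1, round((range_s[1] - range_s[0]) / bin_s))
    counts, edges = np.histogram(peak_delays, bins=n_bins, range=range_s)
    modal = 0.5 * (edges[:-1] + edges[1:])[int(np.argmax(counts))]
    return DelayHistogram(bin_edges=edges, counts=counts,
                          modal_zone=float(modal))


def estimate_phase_lag(peak_delays: np.ndarray,
                       f0: float) -> PhaseLagEstimate:
    """Invert the maxima-lattice condition ``2 pi F0 tau + Phi = 2 n pi``.

    Each observed peak delay contributes ``(-2 pi F0 tau) mod 2 pi``; the
    estimates are aggregated by a circular mean, reported in [0, 2 pi), and
    converted to the lattice offset ``delta = Phi / (2 pi F0)`` seconds.
    """
    peak_delays = np.asarray(peak_delays, dtype=float)
    if peak_delays.size == 0:
        raise ValueError("no peak delays supplied")
    phases = np.mod(-2.0 * np.pi * f0 * peak_delays, 2.0 * np.pi)
    phi_bar = float(np.mod(circmean(phases, high=2.0 * np.pi, low=0.0),
                           2.0 * np.pi))
    if 2.0 * np.pi - phi_bar < 1e-9:  # wrap the 2*pi boundary to 0
        phi_bar = 0.0
    return PhaseLagEstimate(phi_bar=phi_bar,
                            delta=phi_bar / (2.0 * np.pi * f0),
                            n_windows=len(peak_delays))


def lattice_delay(n: int, f0: float, phi_bar: float) -> float:
    """Forward lattice map: the n-th cross-correlation maximum delay,
    ``tau = n/F0 - phi_bar/(2 pi F0)`` seconds."""
    return n / f0 - phi_bar / (2.0 * np.pi * f0)


def occipital_response(session, channels: tuple[str, ...] = ("O1", "O2")
                       ) -> np.ndarray:
    """Average of the (typically O1/O2) channels over the concatenated
    recording; which occipital electrode(s) enter the analysis is
    configurable."""
    return session.continuous(list(channels)).mean(axis=0)


def spectrogram(x: np.ndarray, fs: float, nperseg: int = 64):
    """Basic short-time power spectrogram: (freqs, times, power)."""
    return sig.spectrogram(np.asarray(x, dtype=float), fs=fs,
                           nperseg=min(nperseg, len(x)))
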