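"""Filtering, channel selection, artifact rejection, and the 3x3 grid.

The analysis contrasts three electrode subsets (E1 all twelve channels, E2
fronto-central, E3 parieto-occipital) with three band-pass ranges (F1 1-40 Hz
broadband, F2 10-40 Hz theta-excluded, F3 11-16 Hz flicker neighbourhood),
giving nine spatio-spectral cells.  Filtering uses a zero-phase (forward-
backward) 4th-order Butterworth design so event-related latencies are not
shifted; the two-pass application doubles the effective roll-off.  Trials are
rejected when any channel deviates more than ``spike_uv`` from its epoch mean
or spans a peak-to-peak range above ``range_uv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SessionData

__all__ = [
    "BandConfig", "ElectrodeConfig", "BANDS", "ELECTRODES",
    "bandpass_array", "bandpass_filter", "select_electrodes",
    "reject_artifacts", "spatio_spectral_grid",
    "EpochBandpass", "ChannelSelector",
]


@dataclass(frozen=True)
class BandConfig:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError("require 0 < low_hz < high_hz")


@dataclass(frozen=True)
class ElectrodeConfig:
    name: str
    channels: tuple[str, ...]


#: Band-pass configurations.
BANDS: dict[str, BandConfig] = {
    "F1": BandConfig("F1", 1.0, 40.0),
    "F2": BandConfig("F2", 10.0, 40.0),
    "F3": BandConfig("F3", 11.0, 16.0),
}

#: Electrode subsets: all, fronto-central, parieto-occipital.
ELECTRODES: dict[str, ElectrodeConfig] = {
    "E1": ElectrodeConfig("E1", ("O1", "O2", "P3", "P4", "Pz",
                                 "C3", "C4", "Cz", "F3", "F4", "Fz", "Fpz")),
    "E2": ElectrodeConfig("E2", ("C3", "C4", "Cz", "F3", "F4", "Fz", "Fpz")),
    "E3": ElectrodeConfig("E3", ("O1", "O2", "P3", "P4", "Pz")),
}


def _design_sos(band: BandConfig, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.high_hz} Hz is at or above "
            f"Nyquist ({nyq} Hz)")
    return signal.butter(order, [band.low_hz, band.high_hz],
                         btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, band: BandConfig, fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Each epoch is filtered individually with even (reflection) padding of up
    to one window length to suppress edge transients.
    """
    sos = _design_sos(band, fs, order)
    x = np.asarray(x, dtype=float)
    padlen = min(x.shape[-1] - 1, x.shape[-1])
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def bandpass_filter(session: SessionData, band: BandConfig,
                    order: int = 4) -> SessionData:
    """Filter every channel of every epoch; shape is preserved."""
    filtered = bandpass_array(session.epochs, band,
                              session.sampling_rate, order)
    return SessionData(epochs=filtered, labels=session.labels,
                       onsets=session.onsets, config=session.config,
                       user_id=session.user_id)


def select_electrodes(session: SessionData,
                      config: ElectrodeConfig) -> SessionData:
    """Channel-subset view in the order given by ``config``."""
    return session.subset_channels(config.channels)


def reject_artifacts(session: SessionData, spike_uv: float = 75.0,
                     range_uv: float = 125.0
                     ) -> tuple[SessionData, pd.DataFrame]:
    """Threshold-based trial rejection.

    A trial is flagged when, on any channel, the absolute deviation from the
    channel's epoch mean exceeds ``spike_uv`` or the peak-to-peak range
    exceeds ``range_uv``.  Returns the surviving trials plus a mask table
    (columns: trial, kept, reason).
    """
    if spike_uv <= 0 or range_uv <= 0:
        raise ValueError("thresholds must be positive")
    x = session.epochs
    centered = x - x.mean(axis=-1, keepdims=True)
    spike_hit = (np.abs(centered) > spike_uv).any(axis=(1, 2))
    ptp = x.max(axis=-1) - x.min(axis=-1)
    range_hit = (ptp > range_uv).any(axis=1)
    kept = ~(spike_hit | range_hit)
    reasons = np.where(spike_hit, "spike",
                       np.where(range_hit, "range", ""))
    mask = pd.DataFrame({
        "trial": np.arange(session.n_trials),
        "kept": kept,
        "reason": reasons,
    })
    return session.subset_trials(kept), mask


def spatio_spectral_grid() -> list[tuple[ElectrodeConfig, BandConfig]]:
    """The nine (electrode, band) cells in fixed order E1F1 ... E3F3."""
    return [(ELECTRODES[e], BANDS[f])
            for e in ("E1", "E2", "E3")
            for f in ("F1", "F2", "F3")]


class EpochBandpass(BaseEstimator, TransformerMixin):
    """sklearn transformer applying the zero-phase band-pass to 3-D epochs."""

    def __init__(self, band: str = "F1", sampling_rate: float = 125.0,
                 order: int = 4):
        self.band = band
        self.sampling_rate = sampling_rate
        self.order = order

    def fit(self, X, y=None):
        _design_sos(BANDS[self.band], self.sampling_rate, self.order)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return bandpass_array(np.asarray(X), BANDS[self.band],
                              self.sampling_rate, self.order)


class ChannelSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer selecting channel rows of 3-D epochs by index."""

    def __init__(self, indices: Sequence[int] = ()):
        self.indices = indices

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected trials x channels x samples")
        if any(i >= X.shape[1] for i in self.indices):
            raise ValueError("channel index out of range")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X)[:, list(self.indices), :]
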