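"""Session and configuration I/O.

The native on-disk format is plain text: a directory holding the continuous
multichannel signal as a delimited matrix (``signals.csv``, one row per
channel), a CSV event table (``events.csv`` with columns trial,
onset_sample, label), and the simulation/recording parameters as YAML
(``config.yaml``).  EDF recordings are read through mne; EDF export needs an
EDF writer backend (``edfio``) and raises a clear error when none is
installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SessionData, SimulationConfig

__all__ = [
    "config_to_dict", "config_from_dict", "save_config", "load_config",
    "save_session_text", "load_session_text", "read_edf_session",
    "export_edf",
]


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["channels"] = list(d["channels"])
    d["ssvep_gain"] = dict(d["ssvep_gain"])
    d["errp_gain"] = dict(d["errp_gain"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "channels" in d:
        d["channels"] = tuple(d["channels"])
    return SimulationConfig(**d)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Serialize a SimulationConfig as YAML (or JSON if the suffix says so)."""
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(d)


def save_session_text(session: SessionData, directory: str | Path) -> None:
    """Write a session as delimited matrices plus a CSV event table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    continuous = session.continuous()
    header = ",".join(session.channels)
    np.savetxt(directory / "signals.csv", continuous.T, delimiter=",",
               header=header, comments="", fmt="%.6f")
    pd.DataFrame({
        "trial": np.arange(session.n_trials),
        "onset_sample": session.onsets,
        "label": session.labels,
    }).to_csv(directory / "events.csv", index=False)
    save_config(session.config, directory / "config.yaml")
    (directory / "user.txt").write_text(session.user_id + "\n")


def load_session_text(directory: str | Path) -> SessionData:
    """Re-epoch a text-format session directory into SessionData."""
    directory = Path(directory)
    config = load_config(directory / "config.yaml")
    table = np.loadtxt(directory / "signals.csv", delimiter=",", skiprows=1)
    continuous = np.atleast_2d(table).T  # channels x samples
    events = pd.read_csv(directory / "events.csv")
    n = config.n_samples
    epochs = np.stack([continuous[:, o:o + n]
                       for o in events["onset_sample"].to_numpy()])
    user_file = directory / "user.txt"
    user_id = user_file.read_text().strip() if user_file.exists() else "user00"
    return SessionData(epochs=epochs,
                       labels=events["label"].to_numpy(),
                       onsets=events["onset_sample"].to_numpy(),
                       config=config, user_id=user_id)


def read_edf_session(edf_path: str | Path, events_path: str | Path,
                     config: SimulationConfig | None = None) -> SessionData:
    """Read an EDF recording plus a CSV event table into SessionData.

    ``events_path`` must be a CSV with columns trial, onset_sample, label.
    When ``config`` is omitted, a default-parameter config is adapted to the
    file's sampling rate and channel names.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = pd.read_csv(events_path)
    if config is None:
        gains = {ch: 1.0 for ch in raw.ch_names}
        config = SimulationConfig(sampling_rate=raw.info["sfreq"],
                                  channels=tuple(raw.ch_names),
                                  ssvep_gain=gains, errp_gain=gains)
    n = config.n_samples
    epochs = np.stack([data[:, o:o + n]
                       for o in events["onset_sample"].to_numpy()])
    return SessionData(epochs=epochs,
                       labels=events["label"].to_numpy(),
                       onsets=events["onset_sample"].to_numpy(),
                       config=config, user_id=Path(edf_path).stem)


def export_edf(session: SessionData, path: str | Path) -> None:
    """Export a session as EDF with onset/label annotations.

    Requires an EDF writer backend for mne (the ``edfio`` package); raises
    RuntimeError with instructions when none is available.
    """
    import mne

    info = mne.create_info(list(session.channels),
                           sfreq=session.sampling_rate, ch_types="eeg")
    raw = mne.io.RawArray(session.continuous() * 1e-6, info, verbose="error")
    onsets_s = session.onsets / session.sampling_rate
    labels = ["error" if int(l) else "non-error" for l in session.labels]
    raw.set_annotations(mne.Annotations(
        onset=onsets_s,
        duration=[session.config.window_s] * session.n_trials,
        description=labels))
    try:
        raw.export(str(path), fmt="edf", overwrite=True)
    except (ImportError, RuntimeError, ValueError) as exc:
        raise RuntimeError(
            "EDF export requires mne's EDF writer backend (package "
            "'edfio'); install it or use save_session_text() for the "
            "plain-text format") from exc
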