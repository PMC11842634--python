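"""Unsupervised SSVEP fidelity scoring and its link to detection accuracy.

A user whose occipital response is reliably phase-locked to the flicker
produces cross-correlation maxima at a fixed delay in every action window;
a noisy or inattentive user scatters them.  The fidelity score quantifies
this *without ever reading trial labels*: it is the fraction of action
windows whose global cross-correlation peak falls within a tolerance of the
cohort's modal delay zone (the hypothetical ideal scenario — every window at
the fixed delay — scores 1).  An alternative reading of the same idea, the
rescaled mean absolute deviation of peak delays from the modal zone, is
available via ``method="mad"``; both are interpretations of the published
discrepancy metric, whose exact functional form is not public.

Scores are swept over stimulus-template repetition counts r = 1..150;
longer templates average the correlogram over more windows, sharpening the
peak for moderately noisy users.  Correlating per-user scores with per-user
balanced detection accuracy across the sweep locates the repetition count at
which the unsupervised score best predicts supervised performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .phaselock import (MAX_REPETITIONS, StimulusWaveform,
                        make_stimulus_template, occipital_response,
                        peak_delay, peak_delay_histogram,
                        windowed_correlograms)
from .preprocess import BANDS, bandpass_array
from .simulate import SessionData

__all__ = [
    "FidelityScore", "FidelityCurve", "CorrelationReport",
    "window_peak_delays", "cohort_modal_zone", "fidelity_score",
    "fidelity_sweep", "correlate_with_accuracy", "rank_and_reject_users",
]

#: Default tolerance: half an SSVEP period (40 ms at 12.5 Hz).
DEFAULT_TOLERANCE_S = 0.04


@dataclass(frozen=True)
class FidelityScore:
    user_id: str
    repetitions: int
    score: float


@dataclass(frozen=True)
class FidelityCurve:
    """Per-user fidelity scores indexed by template repetition count."""

    user_id: str
    scores: Mapping[int, float]

    @property
    def r_values(self) -> np.ndarray:
        return np.array(sorted(self.scores))

    @property
    def values(self) -> np.ndarray:
        return np.array([self.scores[r] for r in sorted(self.scores)])


@dataclass(frozen=True)
class CorrelationReport:
    r_values: np.ndarray
    pearson_r: np.ndarray
    p_values: np.ndarray
    best_r: int


def _resolve_template(session: SessionData,
                      template: StimulusWaveform | int) -> StimulusWaveform:
    if isinstance(template, StimulusWaveform):
        return template
    cfg = session.config
    return make_stimulus_template(f0=cfg.flicker_hz, repetitions=int(template),
                                  sampling_rate=cfg.sampling_rate,
                                  active_s=cfg.active_s, off_s=cfg.off_s)


def window_peak_delays(session: SessionData,
                       template: StimulusWaveform | int = 1,
                       preprocess: bool = True,
                       channels: tuple[str, ...] = ("O1", "O2")
                       ) -> np.ndarray:
    """Global cross-correlation peak delay (s) per analyzable action window.

    The selected occipital channels are averaged and the *continuous*
    concatenated trace band-passed to the flicker neighbourhood (F3,
    11-16 Hz) before correlation — filtering the continuous recording, not
    individual epochs, preserves the response tail that spills across
    window boundaries.  Pass ``preprocess=False`` for data already
    filtered.  Labels are never read.
    """
    stim = _resolve_template(session, template)
    series = occipital_response(session, channels)
    if preprocess:
        series = bandpass_array(series, BANDS["F3"],
                                session.config.sampling_rate)
    correlograms = windowed_correlograms(series, stim, session.onsets,
                                         session.config.n_samples)
    if not correlograms:
        raise ValueError("no analyzable action windows "
                         "(template longer than the recording?)")
    return np.array([peak_delay(c) for c in correlograms])


def cohort_modal_zone(sessions: Sequence[SessionData],
                      template: StimulusWaveform | int = 1,
                      bin_s: float = 0.008) -> float:
    """Cohort-level most common peak delay zone (the anchor of the score)."""
    delays = np.concatenate([window_peak_delays(s, template)
                             for s in sessions])
    return peak_delay_histogram(delays, bin_s=bin_s).modal_zone


def fidelity_score(session: SessionData,
                   template: StimulusWaveform | int = 1,
                   modal_zone: float | None = None,
                   tolerance_s: float = DEFAULT_TOLERANCE_S,
                   method: str = "in_zone",
                   preprocess: bool = True) -> FidelityScore:
    """Unsupervised data-quality score in [0, 1] for one user.

    ``method="in_zone"`` (default): fraction of windows whose peak delay lies
    within ``modal_zone +/- tolerance_s``.  ``method="mad"``: one minus the
    mean absolute deviation of peak delays from the modal zone, rescaled by
    half the action window.  ``modal_zone=None`` uses the session's own
    histogram mode (for cohorts, prefer :func:`cohort_modal_zone`).
    """
    delays = window_peak_delays(session, template, preprocess=preprocess)
    if modal_zone is None:
        modal_zone = peak_delay_histogram(delays).modal_zone
    if method == "in_zone":
        score = float(np.mean(np.abs(delays - modal_zone) <= tolerance_s))
    elif method == "mad":
        half_window = session.config.window_s / 2.0
        mad = float(np.mean(np.abs(delays - modal_zone)))
        score = float(np.clip(1.0 - mad / half_window, 0.0, 1.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    reps = (template.repetitions if isinstance(template, StimulusWaveform)
            else int(template))
    return FidelityScore(user_id=session.user_id, repetitions=reps,
                         score=score)


def fidelity_sweep(session: SessionData,
                   r_values: Sequence[int],
                   modal_zone: float | None = None,
                   tolerance_s: float = DEFAULT_TOLERANCE_S,
                   method: str = "in_zone") -> FidelityCurve:
    """Fidelity score for each template repetition count in ``r_values``."""
    r_values = [int(r) for r in r_values]
    if any(not 1 <= r <= MAX_REPETITIONS for r in r_values):
        raise ValueError(f"repetitions must lie in [1, {MAX_REPETITIONS}]")
    scores = {}
    for r in r_values:
        fs = fidelity_score(session, r, modal_zone=modal_zone,
                            tolerance_s=tolerance_s, method=method)
        scores[r] = fs.score
    return FidelityCurve(user_id=session.user_id, scores=scores)


def correlate_with_accuracy(curves: Sequence[FidelityCurve],
                            accuracies: Mapping[str, float]
                            ) -> CorrelationReport:
    """Pearson correlation between fidelity and balanced accuracy per r.

    ``accuracies`` maps user_id to balanced accuracy (%).  Degenerate cases
    (zero variance in either variable) yield NaN correlation at that r.
    ``best_r`` is the repetition count with the largest finite correlation.
    """
    if len(curves) < 3:
        raise ValueError("correlation needs at least 3 users")
    users = [c.user_id for c in curves]
    missing = [u for u in users if u not in accuracies]
    if missing:
        raise ValueError(f"accuracies missing for users {missing}")
    r_values = curves[0].r_values
    for c in curves[1:]:
        if not np.array_equal(c.r_values, r_values):
            raise ValueError("curves must share the same repetition grid")
    acc = np.array([accuracies[u] for u in users], dtype=float)
    pearson = np.full(len(r_values), np.nan)
    pvals = np.full(len(r_values), np.nan)
    for i, r in enumerate(r_values):
        scores = np.array([c.scores[int(r)] for c in curves])
        if np.std(scores) == 0.0 or np.std(acc) == 0.0:
            continue
        res = stats.pearsonr(scores, acc)
        pearson[i], pvals[i] = res.statistic, res.pvalue
    if np.isnan(pearson).all():
        best_r = int(r_values[0])
    else:
        best_r = int(r_values[int(np.nanargmax(pearson))])
    return CorrelationReport(r_values=r_values, pearson_r=pearson,
                             p_values=pvals, best_r=best_r)


def rank_and_reject_users(curves: Sequence[FidelityCurve], r: int,
                          quantile: float) -> tuple[list[str], list[str]]:
    """Flag users whose fidelity at repetition ``r`` sits below the cohort
    quantile.  Fully unsupervised: only fidelity scores are consulted.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    scores = {c.user_id: c.scores[int(r)] for c in curves}
    cutoff = float(np.quantile(list(scores.values()), quantile))
    rejected = [u for u, s in scores.items() if s < cutoff]
    kept = [u for u in scores if u not in rejected]
    return kept, rejected
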