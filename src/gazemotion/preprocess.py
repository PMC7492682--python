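"""Cleaning of raw gaze recordings.

The pipeline order is fixed: participant rejection check, gap interpolation,
low-pass filtering.  A participant whose overall fraction of lost (invalid)
samples exceeds 25% is dropped entirely; remaining gaps — typically blinks —
are filled by linear interpolation, and all channels are smoothed with a
zero-phase 4th-order Butterworth low-pass filter at 5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import GazeRecording
from .synth import Cohort

__all__ = [
    "loss_fraction",
    "reject_participants",
    "interpolate_gaps",
    "lowpass_filter",
    "preprocess_recording",
    "preprocess_cohort",
    "RejectionReport",
]


def loss_fraction(recording: GazeRecording) -> float:
    """Fraction of invalid samples in a recording."""
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    return float(np.mean(~recording.valid))


@dataclass
class RejectionReport:
    threshold: float
    loss_by_participant: dict = field(default_factory=dict)
    rejected: list = field(default_factory=list)

    @property
    def retained(self) -> list:
        return [p for p in self.loss_by_participant if p not in self.rejected]


def reject_participants(cohort: Cohort, threshold: float = 0.25) -> tuple[Cohort, RejectionReport]:
    """Drop participants whose pooled sample loss exceeds ``threshold``.

    Loss is evaluated per participant over the concatenation of all of that
    participant's recordings; rejection removes the participant completely.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    report = RejectionReport(threshold=threshold)
    for pid in cohort.participants:
        recs = cohort.recordings_of(pid)
        total = sum(r.n_samples for r in recs)
        lost = sum(int(np.sum(~r.valid)) for r in recs)
        frac = lost / total
        report.loss_by_participant[pid] = frac
        if frac > threshold:
            report.rejected.append(pid)
    keep = [p for p in cohort.participants if p not in report.rejected]
    retained = Cohort(
        config=cohort.config,
        movies=cohort.movies,
        participants=keep,
        recordings={k: v for k, v in cohort.recordings.items() if k[0] in keep},
        ground_truth={k: v for k, v in cohort.ground_truth.items() if k[0] in keep},
        luminance=cohort.luminance,
        participant_models={p: cohort.participant_models[p] for p in keep
                            if p in cohort.participant_models},
    )
    return retained, report


def interpolate_gaps(recording: GazeRecording) -> GazeRecording:
    """Fill invalid runs by linear interpolation between flanking valid samples.

    Leading and trailing gaps, which have only one flanking valid sample,
    are filled by nearest-value extension.  The output is fully valid.
    """
    valid = recording.valid
    if not valid.any():
        raise ValueError("recording has no valid samples to interpolate from")
    out = recording.copy()
    if valid.all():
        return out
    idx = np.arange(recording.n_samples)
    for name in recording.channels():
        ch = getattr(recording, name)
        setattr(out, name, np.interp(idx, idx[valid], ch[valid]))
    out.valid = np.ones(recording.n_samples, dtype=bool)
    return out


def lowpass_filter(recording: GazeRecording, cutoff_hz: float = 5.0, order: int = 4) -> GazeRecording:
    """Zero-phase Butterworth low-pass on gaze and pupil channels.

    The filter is applied forward and backward (``filtfilt``) so event
    timing is not lagged; the two passes square the single-pass magnitude
    response.
    """
    nyquist = recording.sample_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    b, a = signal.butter(order, cutoff_hz / nyquist)
    padlen = 3 * (max(len(a), len(b)) - 1)
    padlen = min(padlen, recording.n_samples - 1)
    out = recording.copy()
    for name in recording.channels():
        setattr(out, name, signal.filtfilt(b, a, getattr(recording, name), padlen=padlen))
    return out


def preprocess_recording(
    recording: GazeRecording, cutoff_hz: float = 5.0, order: int = 4
) -> GazeRecording:
    """Interpolate gaps, then low-pass filter (the fixed stage order)."""
    return lowpass_filter(interpolate_gaps(recording), cutoff_hz=cutoff_hz, order=order)


def preprocess_cohort(
    cohort: Cohort,
    threshold: float = 0.25,
    cutoff_hz: float = 5.0,
    order: int = 4,
) -> tuple[Cohort, RejectionReport]:
    """Apply rejection, interpolation and filtering to a whole cohort."""
    retained, report = reject_participants(cohort, threshold=threshold)
    clean = {
        key: preprocess_recording(rec, cutoff_hz=cutoff_hz, order=order)
        for key, rec in retained.recordings.items()
    }
    retained.recordings = clean
    return retained, report
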