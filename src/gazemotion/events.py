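"""Fixation and saccade detection on cleaned gaze streams.

Two standard identification algorithms are provided:

* **I-DT** (dispersion threshold): maximal windows whose x-dispersion plus
  y-dispersion stays below a threshold (default 1 degree of visual angle
  converted to pixels) and whose length reaches a minimum duration become
  fixations.
* **I-VT** (velocity threshold): point-to-point velocity is assigned to the
  transition between consecutive samples; a sample is fixational when at
  least one of its adjacent transitions is below the threshold, and runs of
  fixational samples of sufficient length become fixations.  This
  transition-based convention keeps fixation boundaries exact on
  noise-free data.

Saccades are derived between consecutive fixations: duration is the gap in
samples (possibly zero) and amplitude the Euclidean distance between the
two fixation centroids, which is robust to onset jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .recording import GazeRecording, ScreenGeometry

__all__ = ["Fixation", "Saccade", "detect_fixations", "derive_saccades", "detect_events"]


@dataclass(frozen=True)
class Fixation:
    """A detected fixation over the half-open sample window [start, end)."""

    start: int
    end: int
    cx: float
    cy: float

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.cx, self.cy)


@dataclass(frozen=True)
class Saccade:
    """The movement between two consecutive fixations."""

    start: int
    end: int
    amplitude: float  # px, centroid to centroid

    @property
    def duration(self) -> int:
        return self.end - self.start


def _make_fixation(x: np.ndarray, y: np.ndarray, start: int, end: int) -> Fixation:
    return Fixation(start, end, float(x[start:end].mean()), float(y[start:end].mean()))


def _detect_idt(
    x: np.ndarray, y: np.ndarray, dispersion_px: float, min_duration: int
) -> list[Fixation]:
    n = x.size
    fixations = []
    i = 0
    while i + min_duration <= n:
        j = i + min_duration
        xw, yw = x[i:j], y[i:j]
        xmin, xmax = xw.min(), xw.max()
        ymin, ymax = yw.min(), yw.max()
        if (xmax - xmin) + (ymax - ymin) > dispersion_px:
            i += 1
            continue
        while j < n:
            nxmin, nxmax = min(xmin, x[j]), max(xmax, x[j])
            nymin, nymax = min(ymin, y[j]), max(ymax, y[j])
            if (nxmax - nxmin) + (nymax - nymin) > dispersion_px:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        fixations.append(_make_fixation(x, y, i, j))
        i = j
    return fixations


def _detect_ivt(
    x: np.ndarray,
    y: np.ndarray,
    velocity_px_s: float,
    min_duration: int,
    sample_rate: float,
) -> list[Fixation]:
    n = x.size
    if n == 0:
        return []
    # velocity of the transition into sample i (i >= 1)
    v = np.hypot(np.diff(x), np.diff(y)) * sample_rate
    slow = v <= velocity_px_s
    stationary = np.zeros(n, dtype=bool)
    stationary[1:] |= slow  # slow transition from the previous sample
    stationary[:-1] |= slow  # slow transition to the next sample
    fixations = []
    i = 0
    while i < n:
        if not stationary[i]:
            i += 1
            continue
        j = i
        while j < n and stationary[j]:
            j += 1
        if j - i >= min_duration:
            fixations.append(_make_fixation(x, y, i, j))
        i = j
    return fixations


def detect_fixations(
    recording: GazeRecording,
    method: str = "idt",
    dispersion_px: Optional[float] = None,
    velocity_px_s: float = 500.0,
    min_duration: int = 6,
    screen: Optional[ScreenGeometry] = None,
) -> list[Fixation]:
    """Segment a cleaned recording into fixations.

    Parameters
    ----------
    method : {"idt", "ivt"}
        Dispersion-threshold or velocity-threshold identification.
    dispersion_px : float, optional
        I-DT dispersion threshold; defaults to 1 degree of visual angle
        converted through ``screen`` (about 34 px on the reference display).
    velocity_px_s : float
        I-VT velocity threshold (default 500 px/s, about 15 deg/s).
    min_duration : int
        Minimum fixation length in samples (default 6, i.e. 100 ms at 60 Hz).
    """
    if min_duration < 2:
        raise ValueError("min_duration must be at least 2 samples")
    if not recording.valid.all():
        raise ValueError("recording contains invalid samples; preprocess it first")
    x, y = recording.gaze_x, recording.gaze_y
    if method == "idt":
        if dispersion_px is None:
            dispersion_px = (screen or ScreenGeometry()).degrees_to_px(1.0)
        return _detect_idt(x, y, dispersion_px, min_duration)
    if method == "ivt":
        return _detect_ivt(x, y, velocity_px_s, min_duration, recording.sample_rate)
    raise ValueError(f"unknown method {method!r}")


def derive_saccades(fixations: list[Fixation], recording: Optional[GazeRecording] = None) -> list[Saccade]:
    """One saccade per consecutive fixation pair.

    Returns an empty list for fewer than two fixations.  A zero-length gap
    (adjacent fixations) yields a zero-duration saccade, which is retained.
    """
    saccades = []
    for prev, nxt in zip(fixations, fixations[1:]):
        if nxt.start < prev.end:
            raise ValueError("fixations must be ordered and non-overlapping")
        amplitude = float(np.hypot(nxt.cx - prev.cx, nxt.cy - prev.cy))
        saccades.append(Saccade(prev.end, nxt.start, amplitude))
    return saccades


def detect_events(
    recording: GazeRecording, method: str = "idt", **kwargs
) -> tuple[list[Fixation], list[Saccade]]:
    """Convenience wrapper: fixations plus the saccades between them."""
    fixations = detect_fixations(recording, method=method, **kwargs)
    return fixations, derive_saccades(fixations, recording)
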