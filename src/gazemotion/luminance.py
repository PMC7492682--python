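"""Luminance modelling and removal of its effect on pupil diameter.

Pupil diameter responds strongly to the light reaching the retina, so raw
pupil traces recorded while watching a movie are dominated by the movie's
luminance rather than by the viewer's emotional state.  This module models
that confound with a per-participant linear regression

    y_est = b0 + b1 * x

where ``y`` is the average pupil diameter of both eyes and ``x`` is the
frame luminance (the mean V channel of the HSV colour space, in [0, 1]).
The residual ``y_emo = y - y_est`` is the luminance-decorrelated pupil
trace used for feature extraction.

Two luminance variants are supported: the mean over the whole frame
(default) and the mean over a circular neighbourhood of the gaze point
(2 degrees of visual angle, about 68 px on the reference display).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .recording import GazeRecording, ScreenGeometry

__all__ = [
    "LuminanceSeries",
    "LuminanceModel",
    "frame_luminance",
    "neighbourhood_luminance",
    "neighbourhood_series",
    "align_luminance",
    "fit_luminance_model",
    "remove_luminance_effect",
    "luminance_diagnostics",
    "variant_correlation",
]


@dataclass
class LuminanceSeries:
    """Per-frame luminance of one movie, values in [0, 1]."""

    values: np.ndarray
    frame_rate: float
    movie_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("luminance series must be one-dimensional")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("luminance values must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass
class LuminanceModel:
    """Per-participant linear pupil-vs-luminance fit."""

    b0: float
    b1: float
    participant_id: str = ""

    def predict(self, luminance: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(luminance, dtype=float)


def _value_channel(frame: np.ndarray) -> np.ndarray:
    """HSV value channel of a frame, rescaled to [0, 1].

    Grayscale (2-D) frames are used directly; colour (H, W, 3) frames take
    the per-pixel channel maximum, which is the HSV V definition.  Integer
    frames are assumed 8-bit; float frames are assumed already in [0, 1]
    unless their range clearly indicates a 0..255 scale.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim == 3:
        v = frame.max(axis=2).astype(float)
    elif frame.ndim == 2:
        v = frame.astype(float)
    else:
        raise ValueError("frame must be 2-D grayscale or 3-D colour")
    if np.issubdtype(np.asarray(frame).dtype, np.integer) or v.max() > 1.0 + 1e-9:
        v = v / 255.0
    return v


def frame_luminance(frame: np.ndarray) -> float:
    """Mean luminance (HSV value) of a whole frame, in [0, 1]."""
    return float(_value_channel(frame).mean())


def neighbourhood_luminance(
    frame: np.ndarray,
    gaze_px: tuple[float, float],
    diameter_px: float = 68.0,
    screen: Optional[ScreenGeometry] = None,
) -> float:
    """Mean luminance within a circle around the gaze point.

    ``gaze_px`` and ``diameter_px`` are in screen pixels; when ``screen`` is
    given the frame is assumed to span the full display and coordinates are
    rescaled to the frame grid, otherwise they are taken as frame pixels.
    Gaze points outside the frame are clipped to it, and the circle is
    intersected with the frame.
    """
    v = _value_channel(frame)
    h, w = v.shape
    gx, gy = float(gaze_px[0]), float(gaze_px[1])
    radius = diameter_px / 2.0
    if screen is not None:
        sx = w / screen.width_px
        sy = h / screen.height_px
        gx, gy = gx * sx, gy * sy
        radius *= 0.5 * (sx + sy)
    gx = min(max(gx, 0.0), w - 1.0)
    gy = min(max(gy, 0.0), h - 1.0)
    yy, xx = np.ogrid[:h, :w]
    mask = (xx - gx) ** 2 + (yy - gy) ** 2 <= radius**2
    if not mask.any():  # tiny radius: fall back to nearest pixel
        return float(v[int(round(gy)), int(round(gx))])
    return float(v[mask].mean())


def neighbourhood_series(
    frames: np.ndarray,
    recording: GazeRecording,
    frame_rate: float,
    diameter_px: float = 68.0,
    screen: Optional[ScreenGeometry] = None,
) -> np.ndarray:
    """Per-sample gaze-neighbourhood luminance over a whole recording.

    Vectorized variant of :func:`neighbourhood_luminance`: the circular
    mask is precomputed as pixel offsets and gathered per sample from the
    frame active at the sample's timestamp (sample-and-hold, as in
    :func:`align_luminance`).  Pixels falling outside the frame are
    dropped from the mean.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, H, W) stack")
    screen = screen or ScreenGeometry()
    n_frames, h, w = frames.shape
    v = frames.astype(float)
    if np.issubdtype(frames.dtype, np.integer) or v.max() > 1.0 + 1e-9:
        v = v / 255.0
    sx, sy = w / screen.width_px, h / screen.height_px
    radius = diameter_px / 2.0 * 0.5 * (sx + sy)
    r_int = max(int(np.ceil(radius)), 0)
    dy, dx = np.mgrid[-r_int: r_int + 1, -r_int: r_int + 1]
    disk = dx**2 + dy**2 <= radius**2
    if not disk.any():
        disk[r_int, r_int] = True
    offx, offy = dx[disk], dy[disk]

    t = recording.timestamps - recording.timestamps[0]
    fidx = np.clip(np.floor(t * frame_rate).astype(int), 0, n_frames - 1)
    gx = np.clip(np.round(recording.gaze_x * sx).astype(int), 0, w - 1)
    gy = np.clip(np.round(recording.gaze_y * sy).astype(int), 0, h - 1)
    px = gx[:, None] + offx[None, :]
    py = gy[:, None] + offy[None, :]
    inside = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    px = np.clip(px, 0, w - 1)
    py = np.clip(py, 0, h - 1)
    vals = v[fidx[:, None], py, px]
    return (vals * inside).sum(axis=1) / inside.sum(axis=1)


def align_luminance(series: LuminanceSeries, recording: GazeRecording) -> np.ndarray:
    """Per-sample luminance by sample-and-hold on the nearest active frame.

    Frame ``i`` is on screen during ``[i/fps, (i+1)/fps)``; each gaze sample
    receives the value of the frame active at its timestamp.
    """
    if series.n_frames == 0:
        raise ValueError("empty luminance series")
    t = recording.timestamps - recording.timestamps[0]
    idx = np.floor(t * series.frame_rate).astype(int)
    idx = np.clip(idx, 0, series.n_frames - 1)
    return series.values[idx]


def fit_luminance_model(
    pupil: np.ndarray,
    luminance: np.ndarray,
    participant_id: str = "",
) -> LuminanceModel:
    """Ordinary least-squares fit of pupil diameter against luminance.

    ``pupil`` should be the average of both eyes after preprocessing; all of
    a participant's samples (across movies) are fitted jointly.

    Raises
    ------
    ValueError
        If the series lengths differ, or luminance is constant (the slope
        would be unidentifiable).
    """
    pupil = np.asarray(pupil, dtype=float)
    luminance = np.asarray(luminance, dtype=float)
    if pupil.shape != luminance.shape:
        raise ValueError("pupil and luminance series must have equal length")
    if pupil.size < 2 or np.ptp(luminance) == 0:
        raise ValueError("luminance must take at least two distinct values")
    fit = stats.linregress(luminance, pupil)
    return LuminanceModel(b0=float(fit.intercept), b1=float(fit.slope), participant_id=participant_id)


def remove_luminance_effect(
    pupil: np.ndarray, model: LuminanceModel, luminance: np.ndarray
) -> np.ndarray:
    """Residual pupil trace ``y_emo = y - (b0 + b1 x)``.

    On the data the model was fitted to, the residual is orthogonal to
    luminance (zero correlation) and has zero mean, by the OLS normal
    equations.
    """
    pupil = np.asarray(pupil, dtype=float)
    luminance = np.asarray(luminance, dtype=float)
    if pupil.shape != luminance.shape:
        raise ValueError("pupil and luminance series must have equal length")
    return pupil - model.predict(luminance)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def variant_correlation(residual_a: np.ndarray, residual_b: np.ndarray) -> float:
    """Correlation between pupil traces corrected with two luminance variants."""
    return _safe_corr(residual_a, residual_b)


def luminance_diagnostics(
    pupil_by_recording: Mapping[tuple[str, str], np.ndarray],
    luminance_by_recording: Mapping[tuple[str, str], np.ndarray],
    residual_by_recording: Mapping[tuple[str, str], np.ndarray],
) -> dict:
    """Correlation diagnostics for the luminance correction.

    Keys of the mappings are ``(participant_id, movie_id)`` pairs.  Returns
    per-participant correlations between pupil and luminance before and
    after correction (on concatenated samples), their means, and the
    per-participant correlation of per-movie mean pupil against per-movie
    mean luminance before/after correction with the medians across
    participants.
    """
    participants = sorted({pid for pid, _ in pupil_by_recording})
    pre, post = {}, {}
    movie_pre, movie_post = {}, {}
    for pid in participants:
        keys = sorted(k for k in pupil_by_recording if k[0] == pid)
        y = np.concatenate([pupil_by_recording[k] for k in keys])
        x = np.concatenate([luminance_by_recording[k] for k in keys])
        r = np.concatenate([residual_by_recording[k] for k in keys])
        pre[pid] = _safe_corr(y, x)
        post[pid] = _safe_corr(r, x)
        my = np.array([pupil_by_recording[k].mean() for k in keys])
        mx = np.array([luminance_by_recording[k].mean() for k in keys])
        mr = np.array([residual_by_recording[k].mean() for k in keys])
        movie_pre[pid] = _safe_corr(my, mx)
        movie_post[pid] = _safe_corr(mr, mx)
    return {
        "per_participant_pre": pre,
        "per_participant_post": post,
        "mean_pre": float(np.nanmean(list(pre.values()))),
        "mean_post": float(np.nanmean(list(post.values()))),
        "per_movie_pre_median": float(np.nanmedian(list(movie_pre.values()))),
        "per_movie_post_median": float(np.nanmedian(list(movie_post.values()))),
    }
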