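"""Containers for raw gaze streams and the display geometry.

A :class:`GazeRecording` holds one participant's eye-tracking stream for one
movie: gaze point coordinates in screen pixels, pupil diameter of both eyes
in device units, and a per-sample validity flag (samples lost to blinks or
tracking failures are flagged invalid).  Streams are uniformly sampled, by
default at 60 Hz.

:class:`ScreenGeometry` describes the monitor the stimuli were shown on and
converts visual angle to on-screen pixels, which is how dispersion thresholds
and gaze-neighbourhood sizes are specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["GazeRecording", "ScreenGeometry"]


@dataclass
class ScreenGeometry:
    """Monitor geometry used to convert visual angle to pixels.

    Defaults describe a 1920x1080 monitor viewed from 60 cm.  With the
    default physical width, 2 degrees of visual angle subtend about 68 px,
    i.e. 1 degree is roughly 34 px.

    Parameters
    ----------
    width_px, height_px : int
        Display resolution in pixels.
    viewing_distance_cm : float
        Eye-to-screen distance.
    screen_width_cm : float
        Physical width of the display area; sets the pixel pitch.
    center : (float, float), optional
        Screen centre in pixels; defaults to the geometric centre.
    """

    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_cm: float = 60.0
    screen_width_cm: float = 58.8
    center: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen resolution must be positive")
        if self.center is None:
            self.center = (self.width_px / 2.0, self.height_px / 2.0)

    @property
    def px_per_cm(self) -> float:
        return self.width_px / self.screen_width_cm

    def degrees_to_px(self, degrees: float) -> float:
        """Convert a visual angle to the pixel length it subtends on screen."""
        chord_cm = 2.0 * self.viewing_distance_cm * np.tan(np.radians(degrees) / 2.0)
        return chord_cm * self.px_per_cm


@dataclass
class GazeRecording:
    """One participant x movie eye-tracking stream.

    All channel arrays have equal length and timestamps are uniform at
    ``sample_rate``.  Invalid samples (``valid == False``) may carry NaN in
    the signal channels; preprocessing fills them by linear interpolation.
    """

    participant_id: str
    movie_id: str
    sample_rate: float
    timestamps: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("timestamps", "gaze_x", "gaze_y", "pupil_left", "pupil_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.valid is None:
            self.valid = np.ones(self.timestamps.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.timestamps.size
        for name in ("gaze_x", "gaze_y", "pupil_left", "pupil_right", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from timestamps")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / self.sample_rate) > 1e-6):
                raise ValueError("timestamps must be strictly increasing and uniform")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def pupil_mean(self) -> np.ndarray:
        """Average pupil diameter of both eyes, sample by sample."""
        return 0.5 * (self.pupil_left + self.pupil_right)

    def channels(self) -> tuple[str, ...]:
        return ("gaze_x", "gaze_y", "pupil_left", "pupil_right")

    def copy(self, **changes) -> "GazeRecording":
        base = {
            name: np.array(getattr(self, name), copy=True)
            for name in ("timestamps", "gaze_x", "gaze_y", "pupil_left", "pupil_right", "valid")
        }
        base.update(changes)
        return replace(self, **base)
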