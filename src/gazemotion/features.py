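"""The 18 eye-tracking features and per-participant standardization.

Per participant x movie, the feature vector comprises: the number of
fixations and the overall fixation vector (both normalized by movie length
in samples so they do not correlate with clip duration), and four moment
blocks — mean, variance, skewness, kurtosis — of fixation durations
(samples), saccade amplitudes (pixels), saccade durations (samples) and the
luminance-corrected pupil diameter (device units).

The overall fixation vector (OFV) is the duration-weighted vector sum of
fixation positions relative to the screen centre,

    OFV = sum_i t_i * (x_i - x_c, y_i - y_c),

reduced to a scalar by its Euclidean norm and divided by the recording
length.  Features are z-scored within participant across that participant's
movies before classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import Fixation, Saccade
from .recording import ScreenGeometry

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "overall_fixation_vector",
    "moment_features",
    "extract_features",
    "features_table",
    "zscore_per_participant",
]

FEATURE_NAMES = (
    "f01_num_fixations",
    "f02_overall_fixation_vector",
    "f03_fixation_duration_mean",
    "f04_fixation_duration_var",
    "f05_fixation_duration_skew",
    "f06_fixation_duration_kurt",
    "f07_saccade_amplitude_mean",
    "f08_saccade_amplitude_var",
    "f09_saccade_amplitude_skew",
    "f10_saccade_amplitude_kurt",
    "f11_saccade_duration_mean",
    "f12_saccade_duration_var",
    "f13_saccade_duration_skew",
    "f14_saccade_duration_kurt",
    "f15_pupil_diameter_mean",
    "f16_pupil_diameter_var",
    "f17_pupil_diameter_skew",
    "f18_pupil_diameter_kurt",
)

ID_COLUMNS = ("participant_id", "movie_id", "class_label")


@dataclass
class FeatureVector:
    participant_id: str
    movie_id: str
    class_label: str
    values: np.ndarray  # length 18, order of FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "movie_id": self.movie_id,
            "class_label": self.class_label,
        }
        d.update(zip(FEATURE_NAMES, self.values))
        return d


def overall_fixation_vector(
    fixations: Sequence[Fixation],
    screen: ScreenGeometry,
    n_samples: int,
) -> float:
    """Norm of the duration-weighted fixation offset sum, per sample.

    Fixations at the screen centre, or symmetric pairs about it, cancel;
    an empty fixation list yields 0.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    xc, yc = screen.center
    sx = sum(f.duration * (f.cx - xc) for f in fixations)
    sy = sum(f.duration * (f.cy - yc) for f in fixations)
    return float(np.hypot(sx, sy)) / n_samples


def moment_features(values: Iterable[float]) -> tuple[float, float, float, float]:
    """(mean, sample variance, skewness, excess kurtosis) of a sample.

    Conventions for degenerate samples, chosen so classifiers never see
    missing values: empty sample -> all zeros; fewer than 2/3/4 values ->
    variance/skewness/kurtosis of 0; constant samples -> skewness and
    kurtosis 0.  Variance uses the n-1 denominator; skewness and kurtosis
    are the standard moment ratios (g1 and g2 = m4/m2^2 - 3).
    """
    a = np.asarray(list(values), dtype=float)
    n = a.size
    if n == 0:
        return (0.0, 0.0, 0.0, 0.0)
    mean = float(a.mean())
    var = float(a.var(ddof=1)) if n >= 2 else 0.0
    constant = var == 0.0
    skew = float(stats.skew(a, bias=True)) if n >= 3 and not constant else 0.0
    kurt = float(stats.kurtosis(a, fisher=True, bias=True)) if n >= 4 and not constant else 0.0
    return (mean, var, skew, kurt)


def extract_features(
    fixations: Sequence[Fixation],
    saccades: Sequence[Saccade],
    pupil_emo: np.ndarray,
    n_samples: int,
    screen: Optional[ScreenGeometry] = None,
    participant_id: str = "",
    movie_id: str = "",
    class_label: str = "none",
) -> FeatureVector:
    """Compute the 18-feature vector for one participant x movie.

    ``pupil_emo`` is the luminance-corrected pupil series of the recording;
    ``n_samples`` the recording length used for duration normalization.
    Only the fixation count and the OFV are divided by length.
    """
    if n_samples <= 0:
        raise ValueError("recording length must be positive")
    screen = screen or ScreenGeometry()
    values = np.empty(len(FEATURE_NAMES))
    values[0] = len(fixations) / n_samples
    values[1] = overall_fixation_vector(fixations, screen, n_samples)
    values[2:6] = moment_features(f.duration for f in fixations)
    values[6:10] = moment_features(s.amplitude for s in saccades)
    values[10:14] = moment_features(s.duration for s in saccades)
    values[14:18] = moment_features(np.asarray(pupil_emo, dtype=float))
    return FeatureVector(participant_id, movie_id, class_label, values)


def features_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table, one row per participant x movie."""
    df = pd.DataFrame([v.as_dict() for v in vectors])
    return df[list(ID_COLUMNS) + list(FEATURE_NAMES)]


def zscore_per_participant(features: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature within participant across that participant's movies.

    Centering and scaling use the participant's own mean and (population)
    standard deviation, so every participant contributes rows with
    per-feature mean 0 and sd 1.  Zero-variance features map to 0.

    Raises
    ------
    ValueError
        If any participant has fewer than two movies (standardization is
        then undefined).
    """
    counts = features.groupby("participant_id").size()
    single = counts[counts < 2]
    if len(single):
        raise ValueError(
            f"standardization undefined for single-movie participants: {list(single.index)}"
        )
    out = features.copy()
    cols = list(FEATURE_NAMES)

    def _z(group: pd.DataFrame) -> pd.DataFrame:
        centred = group - group.mean()
        sd = group.std(ddof=0)
        z = centred.div(sd.replace(0.0, np.nan), axis=1)
        return z.fillna(0.0)

    out[cols] = (
        features.groupby("participant_id", group_keys=False)[cols].apply(_z)
    )
    return out
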