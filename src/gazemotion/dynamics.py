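"""Movie dynamics index and its correlation with eye-tracking features.

Scene motion is summarized per movie by the mean absolute per-pixel
difference between successive grayscale frames,

    D_i = sum_jk |F_{i+1}[j,k] - F_i[j,k]|,

with the movie summary the mean of D_i over transitions divided by the
pixel count, so the index is resolution independent and expressed in the
frames' own intensity units.  The absolute value makes the index strictly
positive for any movie with motion; a signed sum would cancel for
luminance-stable movies.

To relate movie dynamics to oculomotor behaviour, each feature is
correlated with D across movies within participant, and the per-feature
mean correlation over participants is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = ["DynamicsIndex", "movie_dynamics", "dynamics_feature_correlations"]


@dataclass
class DynamicsIndex:
    per_transition: np.ndarray  # summed absolute difference per frame pair
    summary: float  # mean per-transition difference per pixel
    resolution: tuple[int, int]
    movie_id: str = ""


def movie_dynamics(frames: Sequence[np.ndarray] | np.ndarray, movie_id: str = "") -> DynamicsIndex:
    """Dynamics index of a grayscale frame sequence.

    A static movie scores 0; two frames differing by one intensity unit at
    every pixel score 1.0 per pixel.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n_frames, H, W) grayscale stack "
                         "with constant resolution")
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    n, h, w = frames.shape
    per_transition = np.abs(np.diff(frames, axis=0)).sum(axis=(1, 2))
    summary = float(per_transition.mean() / (h * w))
    return DynamicsIndex(per_transition, summary, (h, w), movie_id)


def dynamics_feature_correlations(
    indices: Mapping[str, float],
    features: pd.DataFrame,
) -> pd.Series:
    """Mean over participants of the per-participant feature-vs-D correlation.

    ``indices`` maps movie_id to the movie's dynamics summary; ``features``
    is the per-participant x movie feature table.  For each participant the
    Pearson correlation between D and each feature across movies is
    computed, then averaged over participants.  Participants whose feature
    is constant across movies are excluded from that feature's mean (with a
    warning).
    """
    movies = sorted(indices)
    if len(movies) < 3:
        raise ValueError("need at least 3 movies for meaningful correlations")
    d = np.array([indices[m] for m in movies])
    if np.std(d) == 0:
        raise ValueError("dynamics index constant across movies")
    sums = {name: [] for name in FEATURE_NAMES}
    for pid, group in features.groupby("participant_id"):
        g = group.set_index("movie_id").reindex(movies)
        if g[list(FEATURE_NAMES)].isna().any().any():
            raise ValueError(f"participant {pid} is missing movies with a dynamics index")
        for name in FEATURE_NAMES:
            vals = g[name].to_numpy(dtype=float)
            if np.std(vals) == 0:
                warnings.warn(
                    f"feature {name} constant across movies for {pid}; excluded",
                    stacklevel=2,
                )
                continue
            sums[name].append(float(np.corrcoef(d, vals)[0, 1]))
    return pd.Series(
        {name: (float(np.mean(rs)) if rs else np.nan) for name, rs in sums.items()},
        name="dynamics_correlation",
    )
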