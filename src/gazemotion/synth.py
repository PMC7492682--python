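"""Synthetic eye-tracking experiment generator with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for a cohort of participants who all watch the same set of short
movies:

* gaze alternates fixation plateaus (centroid plus small isotropic jitter,
  durations log-normal with a median near 250 ms) and brief saccadic jumps
  (1-3 samples, amplitudes from a shifted gamma distribution);
* pupil diameter is a participant baseline plus a negative linear response
  to movie luminance, a class-dependent emotional offset, slow drift, and
  white measurement noise, independently for the two eyes;
* blinks knock out runs of samples (80-300 ms) which are flagged invalid;
* movies are grayscale frame sequences whose mean intensity follows a
  smooth luminance series and whose mean absolute inter-frame pixel
  difference is controlled by a dynamics level.

Emotion-class effects are planted at the generating level — pupil offset,
saccade-amplitude scale and fixation-duration scale per class — so that the
class structure is recoverable after feature extraction and per-participant
standardization.  Every planted event and parameter is recorded in a
:class:`GroundTruth` object, which serves as the oracle for event detection
and regression recovery.

All randomness flows from one integer seed; per-recording substreams are
derived deterministically from (seed, participant index, movie index), so a
movie's luminance and frames are identical across participants.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .luminance import LuminanceSeries, align_luminance
from .recording import GazeRecording, ScreenGeometry

__all__ = [
    "MovieSpec",
    "SynthConfig",
    "GroundTruth",
    "Cohort",
    "default_movies",
    "movie_luminance_series",
    "generate_gaze_stream",
    "generate_frames",
    "generate_cohort",
]

CLASSES = ("C1", "C2", "C3")


@dataclass
class MovieSpec:
    """One stimulus movie: emotion label, length, luminance and dynamics."""

    movie_id: str
    class_label: str = "none"  # C1 / C2 / C3 / none
    duration_s: float = 10.0
    frame_rate: float = 25.0
    dynamics_level: float = 0.05  # mean abs inter-frame change per pixel, [0,1] intensity units
    mean_luminance: float = 0.45
    luminance_variability: float = 0.05  # sd of the smooth luminance fluctuation
    frame_shape: tuple[int, int] = (120, 160)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("movie duration must be positive")
        if not 0.0 <= self.mean_luminance <= 1.0:
            raise ValueError("mean_luminance must lie in [0, 1]")
        if self.class_label not in CLASSES + ("none",):
            raise ValueError(f"unknown class label {self.class_label!r}")


def default_movies() -> list[MovieSpec]:
    """The six class movies of the default study design.

    Two movies per class; durations echo the study's clips (5-13 s).  C1
    (pleasant, stimulating) movies are dynamic; C2 (neutral) and C3
    (unpleasant, stimulating) movies are comparatively static.
    """
    return [
        MovieSpec("m01", "C1", duration_s=10, dynamics_level=0.080, mean_luminance=0.45),
        MovieSpec("m02", "C1", duration_s=13, dynamics_level=0.100, mean_luminance=0.55),
        MovieSpec("m03", "C2", duration_s=5, dynamics_level=0.010, mean_luminance=0.50),
        MovieSpec("m04", "C2", duration_s=10, dynamics_level=0.015, mean_luminance=0.40),
        MovieSpec("m05", "C3", duration_s=10, dynamics_level=0.020, mean_luminance=0.35),
        MovieSpec("m06", "C3", duration_s=10, dynamics_level=0.025, mean_luminance=0.42),
    ]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Pupil diameters are in abstract device units (the tracker's unit is not
    physically calibrated); the intercept/slope defaults put baselines near
    30 units with a luminance response near -11 units per luminance unit.
    Class pupil offsets are specified in z-like units and converted to
    device units by ``pupil_offset_scale``; their default pattern
    (C1 > C3 > C2) mirrors the expected ordering of standardized per-class
    pupil means.
    """

    n_participants: int = 30
    movies: list[MovieSpec] = field(default_factory=default_movies)
    sample_rate: float = 60.0
    blink_rate_per_min: float = 15.0
    blink_duration_ms: tuple[float, float] = (80.0, 300.0)
    pupil_noise_sd: float = 0.5
    pupil_drift_sd: float = 0.3
    luminance_slope_range: tuple[float, float] = (-13.0, -9.0)
    luminance_intercept_range: tuple[float, float] = (28.0, 32.0)
    class_pupil_offsets: dict = field(
        default_factory=lambda: {"C1": 0.85, "C2": -0.73, "C3": -0.43}
    )
    class_pupil_offset_sd: float = 0.5  # per-recording emotional variability, z-like units
    pupil_offset_scale: float = 1.0  # device units per z-like unit
    class_saccade_amp_scale: dict = field(
        default_factory=lambda: {"C1": 0.8, "C2": 1.3, "C3": 1.15}
    )
    class_fixation_duration_scale: dict = field(
        default_factory=lambda: {"C1": 1.05, "C2": 0.85, "C3": 1.1}
    )
    fixation_jitter_px: float = 1.5
    fixation_duration_median_ms: float = 250.0
    fixation_duration_sigma: float = 0.4  # log-normal shape
    min_fixation_samples: int = 6
    saccade_amp_floor_px: float = 50.0
    saccade_amp_gamma_shape: float = 2.0
    saccade_amp_gamma_scale: float = 35.0
    saccade_duration_samples: tuple[int, int] = (1, 3)
    high_loss_participants: int = 0  # first k participants get an elevated blink rate
    high_loss_blink_rate_per_min: float = 130.0
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for m in (self.class_pupil_offsets, self.class_saccade_amp_scale,
                  self.class_fixation_duration_scale):
            missing = set(CLASSES) - set(m)
            if missing:
                raise ValueError(f"class map missing entries for {sorted(missing)}")
            if not all(np.isfinite(list(m.values()))):
                raise ValueError("class map values must be finite")


@dataclass
class GroundTruth:
    """Everything planted into one recording, for use as a test oracle."""

    participant_id: str
    movie_id: str
    fixation_intervals: list[tuple[int, int]]  # half-open [start, end)
    fixation_centroids: list[tuple[float, float]]
    saccade_intervals: list[tuple[int, int]]
    saccade_amplitudes: list[float]  # centroid-to-centroid distance, px
    saccade_durations: list[int]  # samples
    b0: float
    b1: float
    class_offset: float  # realized per-recording offset, device units
    aligned_luminance: np.ndarray  # per gaze sample
    emotion_signal: np.ndarray  # offset + drift, per gaze sample
    n_samples: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.fixation_intervals:
            if not (0 <= prev_end <= start < end <= self.n_samples):
                raise ValueError("fixation intervals must be ordered, disjoint, in bounds")
            prev_end = end

    @property
    def n_fixations(self) -> int:
        return len(self.fixation_intervals)


@dataclass
class Cohort:
    """All recordings, movies, labels and ground truth of one experiment."""

    config: SynthConfig
    movies: list[MovieSpec]
    participants: list[str]
    recordings: dict  # (participant_id, movie_id) -> GazeRecording
    ground_truth: dict  # (participant_id, movie_id) -> GroundTruth
    luminance: dict  # movie_id -> LuminanceSeries
    participant_models: dict  # participant_id -> (b0, b1)

    @property
    def labels(self) -> dict:
        return {m.movie_id: m.class_label for m in self.movies}

    @property
    def n_recordings(self) -> int:
        return len(self.recordings)

    def recordings_of(self, participant_id: str) -> list[GazeRecording]:
        return [rec for (pid, _), rec in sorted(self.recordings.items()) if pid == participant_id]


# ---------------------------------------------------------------------------
# low-level helpers


def _smooth_noise(rng: np.random.Generator, n: int, smooth_samples: float) -> np.ndarray:
    """Zero-mean, unit-sd smooth noise (Gaussian-kernel-filtered white noise)."""
    if n <= 1:
        return np.zeros(n)
    white = rng.standard_normal(n + int(6 * smooth_samples))
    half = int(3 * smooth_samples)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / max(smooth_samples, 1e-9)) ** 2)
    k /= k.sum()
    sm = np.convolve(white, k, mode="same")[half: half + n]
    sd = sm.std()
    return (sm - sm.mean()) / sd if sd > 0 else np.zeros(n)


def _movie_seed(seed: int, movie_id: str) -> int:
    """Movie-specific seed, identical for every participant."""
    return int((seed * 1_000_003 + zlib.crc32(movie_id.encode())) % (2**31 - 1))


def movie_luminance_series(spec: MovieSpec, seed: int) -> LuminanceSeries:
    """Smooth per-frame luminance series of a movie, values clipped to [0, 1]."""
    n_frames = int(round(spec.duration_s * spec.frame_rate))
    rng = np.random.default_rng(_movie_seed(seed, spec.movie_id))
    if spec.luminance_variability > 0:
        fluct = _smooth_noise(rng, n_frames, smooth_samples=spec.frame_rate * 0.5)
        values = spec.mean_luminance + spec.luminance_variability * fluct
    else:
        values = np.full(n_frames, spec.mean_luminance)
    values = np.clip(values, 0.0, 1.0)
    return LuminanceSeries(values=values, frame_rate=spec.frame_rate, movie_id=spec.movie_id)


def _plan_events(
    rng: np.random.Generator,
    n_samples: int,
    cfg: SynthConfig,
    fixdur_scale: float,
    amp_scale: float,
) -> tuple[list[tuple[int, int]], list[tuple[float, float]], list[tuple[int, int]]]:
    """Lay out alternating fixation/saccade intervals and fixation centroids."""
    screen = cfg.screen
    margin = 80.0
    lo = np.array([margin, margin])
    hi = np.array([screen.width_px - margin, screen.height_px - margin])
    median_samples = cfg.fixation_duration_median_ms / 1000.0 * cfg.sample_rate * fixdur_scale
    sd_lo, sd_hi = cfg.saccade_duration_samples

    fix_intervals: list[tuple[int, int]] = []
    centroids: list[tuple[float, float]] = []
    sac_intervals: list[tuple[int, int]] = []

    pos = rng.uniform(lo, hi)
    cursor = 0
    while True:
        dur = int(round(rng.lognormal(np.log(max(median_samples, 1.0)), cfg.fixation_duration_sigma)))
        dur = max(dur, cfg.min_fixation_samples)
        sac_dur = int(rng.integers(sd_lo, sd_hi + 1))
        # if the remainder cannot hold another full fixation, absorb it here
        if cursor + dur + sac_dur + cfg.min_fixation_samples >= n_samples:
            fix_intervals.append((cursor, n_samples))
            centroids.append((float(pos[0]), float(pos[1])))
            break
        fix_intervals.append((cursor, cursor + dur))
        centroids.append((float(pos[0]), float(pos[1])))
        cursor += dur
        sac_intervals.append((cursor, cursor + sac_dur))
        cursor += sac_dur
        amp = (cfg.saccade_amp_floor_px + rng.gamma(cfg.saccade_amp_gamma_shape,
                                                   cfg.saccade_amp_gamma_scale)) * amp_scale
        target = None
        for _ in range(100):
            theta = rng.uniform(0, 2 * np.pi)
            cand = pos + amp * np.array([np.cos(theta), np.sin(theta)])
            if np.all(cand >= lo) and np.all(cand <= hi):
                target = cand
                break
        if target is None:  # jump toward the screen centre instead
            direction = np.asarray(screen.center) - pos
            direction /= np.linalg.norm(direction)
            target = np.clip(pos + amp * direction, lo, hi)
        pos = target
    return fix_intervals, centroids, sac_intervals


def generate_gaze_stream(
    spec: MovieSpec,
    behavior: SynthConfig,
    seed: int,
    participant_id: str = "S01",
    b0: Optional[float] = None,
    b1: Optional[float] = None,
    blink_rate_per_min: Optional[float] = None,
    luminance: Optional[LuminanceSeries] = None,
) -> tuple[GazeRecording, GroundTruth]:
    """Generate one participant x movie recording with its ground truth.

    ``b0``/``b1`` (participant pupil baseline and luminance slope) are drawn
    from the configured ranges when not given.  The movie luminance series
    is derived from the movie identity alone so it is shared across
    participants.
    """
    n = int(round(spec.duration_s * behavior.sample_rate))
    if n < 10:
        raise ValueError("recording must span at least 10 samples")
    rng = np.random.default_rng(seed)
    cls = spec.class_label

    if luminance is None:
        luminance = movie_luminance_series(spec, behavior.seed)
    if b0 is None:
        b0 = float(rng.uniform(*behavior.luminance_intercept_range))
    if b1 is None:
        b1 = float(rng.uniform(*behavior.luminance_slope_range))

    fix_intervals, centroids, sac_intervals = _plan_events(
        rng, n, behavior,
        fixdur_scale=behavior.class_fixation_duration_scale.get(cls, 1.0),
        amp_scale=behavior.class_saccade_amp_scale.get(cls, 1.0),
    )

    gx = np.empty(n)
    gy = np.empty(n)
    for (start, end), (cx, cy) in zip(fix_intervals, centroids):
        gx[start:end] = cx
        gy[start:end] = cy
        if behavior.fixation_jitter_px > 0:
            gx[start:end] += rng.normal(0, behavior.fixation_jitter_px, end - start)
            gy[start:end] += rng.normal(0, behavior.fixation_jitter_px, end - start)
    for k, (start, end) in enumerate(sac_intervals):
        (x0, y0), (x1, y1) = centroids[k], centroids[k + 1]
        frac = np.arange(1, end - start + 1) / (end - start + 1)
        gx[start:end] = x0 + frac * (x1 - x0)
        gy[start:end] = y0 + frac * (y1 - y0)

    sac_amps = [
        float(np.hypot(centroids[k + 1][0] - centroids[k][0],
                       centroids[k + 1][1] - centroids[k][1]))
        for k in range(len(sac_intervals))
    ]
    sac_durs = [end - start for start, end in sac_intervals]

    timestamps = np.arange(n) / behavior.sample_rate
    rec_for_alignment = GazeRecording(
        participant_id, spec.movie_id, behavior.sample_rate,
        timestamps, gx, gy, np.zeros(n), np.zeros(n),
    )
    x = align_luminance(luminance, rec_for_alignment)

    offset = 0.0
    if cls in behavior.class_pupil_offsets:
        offset = behavior.class_pupil_offsets[cls]
    if behavior.class_pupil_offset_sd > 0:
        offset += rng.normal(0, behavior.class_pupil_offset_sd)
    offset *= behavior.pupil_offset_scale
    drift = np.zeros(n)
    if behavior.pupil_drift_sd > 0:
        drift = behavior.pupil_drift_sd * _smooth_noise(rng, n, behavior.sample_rate * 1.0)
    emotion = offset + drift
    base = b0 + b1 * x + emotion
    noise_l = rng.normal(0, behavior.pupil_noise_sd, n) if behavior.pupil_noise_sd > 0 else 0.0
    noise_r = rng.normal(0, behavior.pupil_noise_sd, n) if behavior.pupil_noise_sd > 0 else 0.0
    pupil_l = base + noise_l
    pupil_r = base + noise_r

    valid = np.ones(n, dtype=bool)
    rate = behavior.blink_rate_per_min if blink_rate_per_min is None else blink_rate_per_min
    if rate > 0:
        n_blinks = rng.poisson(rate / 60.0 * spec.duration_s)
        lo_ms, hi_ms = behavior.blink_duration_ms
        for _ in range(n_blinks):
            dur = int(round(rng.uniform(lo_ms, hi_ms) / 1000.0 * behavior.sample_rate))
            start = int(rng.integers(0, max(n - dur, 1)))
            valid[start:start + max(dur, 1)] = False
    gx = np.where(valid, gx, np.nan)
    gy = np.where(valid, gy, np.nan)
    pupil_l = np.where(valid, pupil_l, np.nan)
    pupil_r = np.where(valid, pupil_r, np.nan)

    recording = GazeRecording(
        participant_id, spec.movie_id, behavior.sample_rate,
        timestamps, gx, gy, pupil_l, pupil_r, valid,
    )
    truth = GroundTruth(
        participant_id=participant_id,
        movie_id=spec.movie_id,
        fixation_intervals=fix_intervals,
        fixation_centroids=centroids,
        saccade_intervals=sac_intervals,
        saccade_amplitudes=sac_amps,
        saccade_durations=sac_durs,
        b0=b0,
        b1=b1,
        class_offset=offset,
        aligned_luminance=x,
        emotion_signal=emotion,
        n_samples=n,
    )
    return recording, truth


def generate_frames(spec: MovieSpec, seed: int) -> np.ndarray:
    """Grayscale frame sequence (n_frames, H, W), float values in [0, 1].

    Each frame's mean intensity equals the movie's luminance series, and the
    mean absolute per-pixel difference between successive frames equals
    ``dynamics_level`` (realized by a checkerboard texture of alternating
    sign), up to clipping at the intensity bounds and any luminance change
    between frames.
    """
    h, w = spec.frame_shape
    if h <= 0 or w <= 0:
        raise ValueError("frame dimensions must be positive")
    n_frames = int(round(spec.duration_s * spec.frame_rate))
    if n_frames < 2:
        raise ValueError("movie must contain at least 2 frames")
    series = movie_luminance_series(spec, seed)
    yy, xx = np.indices((h, w))
    checker = np.where((yy + xx) % 2 == 0, 1.0, -1.0)
    c = spec.dynamics_level / 2.0
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for i in range(n_frames):
        sign = 1.0 if i % 2 == 0 else -1.0
        frames[i] = np.clip(series.values[i] + sign * c * checker, 0.0, 1.0)
    return frames


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate the full participants x movies experiment.

    Every participant watches every movie.  The first
    ``high_loss_participants`` participants blink at the elevated rate so
    that their sample loss exceeds the rejection threshold downstream.
    """
    if config.n_participants < 2:
        raise ValueError("need at least 2 participants")
    class_counts = {c: sum(1 for m in config.movies if m.class_label == c) for c in CLASSES}
    used = {c: k for c, k in class_counts.items() if k > 0}
    if used and any(k < 2 for k in used.values()):
        raise ValueError(f"each emotion class needs >= 2 movies, got {class_counts}")

    participants = [f"S{i + 1:02d}" for i in range(config.n_participants)]
    lum = {m.movie_id: movie_luminance_series(m, config.seed) for m in config.movies}

    models = {}
    for pi, pid in enumerate(participants):
        prng = np.random.default_rng([config.seed % (2**31), 999_983, pi])
        models[pid] = (
            float(prng.uniform(*config.luminance_intercept_range)),
            float(prng.uniform(*config.luminance_slope_range)),
        )

    recordings, truths = {}, {}
    for pi, pid in enumerate(participants):
        b0, b1 = models[pid]
        blink_rate = (
            config.high_loss_blink_rate_per_min
            if pi < config.high_loss_participants
            else config.blink_rate_per_min
        )
        for mi, spec in enumerate(config.movies):
            sub = np.random.SeedSequence([config.seed % (2**31), pi, mi]).generate_state(1)[0]
            rec, truth = generate_gaze_stream(
                spec, config, int(sub % (2**31)), participant_id=pid,
                b0=b0, b1=b1, blink_rate_per_min=blink_rate,
                luminance=lum[spec.movie_id],
            )
            recordings[(pid, spec.movie_id)] = rec
            truths[(pid, spec.movie_id)] = truth

    return Cohort(
        config=config,
        movies=list(config.movies),
        participants=participants,
        recordings=recordings,
        ground_truth=truths,
        luminance=lum,
        participant_models=models,
    )
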