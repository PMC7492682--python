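"""End-to-end study orchestration.

Runs the stages in their fixed order — synthesize (or load), preprocess,
remove the luminance effect from pupil diameter, detect oculomotor events,
extract and standardize features, classify — and optionally the movie
dynamics analysis and luminance diagnostics.  A :class:`StudyConfig`
captures every knob; identical (config, seed) pairs produce identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation, luminance
from .dynamics import dynamics_feature_correlations, movie_dynamics
from .events import detect_events
from .features import features_table, extract_features, zscore_per_participant
from .preprocess import RejectionReport, preprocess_cohort
from .recording import ScreenGeometry
from .synth import Cohort, SynthConfig, generate_cohort, generate_frames

__all__ = ["StudyConfig", "StudyResult", "run_study", "correct_pupil", "extract_cohort_features"]

TASKS = {
    "C1_vs_C2_vs_C3": ("C1", "C2", "C3"),
    "C1_vs_C2": ("C1", "C2"),
    "C1_vs_C3": ("C1", "C3"),
    "C2_vs_C3": ("C2", "C3"),
}


@dataclass
class StudyConfig:
    """All settings of one end-to-end run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    rejection_threshold: float = 0.25
    filter_cutoff_hz: float = 5.0
    filter_order: int = 4
    detector: str = "idt"  # or "ivt"
    detector_params: dict = field(default_factory=dict)
    luminance_variant: str = "frame"  # or "neighbourhood"
    neighbourhood_diameter_px: float = 68.0
    classifiers: tuple = evaluation.MODELS
    include_dynamics: bool = True
    include_diagnostics: bool = True

    @property
    def screen(self) -> ScreenGeometry:
        return self.synth.screen


@dataclass
class StudyResult:
    config: StudyConfig
    rejection: RejectionReport
    luminance_models: dict  # participant_id -> LuminanceModel
    features: pd.DataFrame  # standardized feature table
    features_raw: pd.DataFrame
    accuracy_table: pd.DataFrame  # rows tasks, columns classifiers
    loso: dict  # (task, model) -> LosoResult
    feature_screen: pd.DataFrame
    dynamics: Optional[pd.Series] = None  # movie_id -> summary
    dynamics_correlations: Optional[pd.Series] = None
    luminance_diagnostics: Optional[dict] = None


def correct_pupil(
    cohort: Cohort,
    variant: str = "frame",
    neighbourhood_diameter_px: float = 68.0,
    frames_by_movie: Optional[dict] = None,
) -> tuple[dict, dict, dict, dict]:
    """Fit per-participant luminance models and form residual pupil traces.

    Returns ``(models, pupil_by_rec, lum_by_rec, resid_by_rec)`` keyed by
    ``(participant_id, movie_id)``.  The ``frame`` variant pairs each gaze
    sample with the active frame's mean luminance; the ``neighbourhood``
    variant uses the gaze-centred circular mean and needs frame stacks.
    """
    pupil_by_rec, lum_by_rec = {}, {}
    for key, rec in cohort.recordings.items():
        pupil_by_rec[key] = rec.pupil_mean()
        series = cohort.luminance[rec.movie_id]
        if variant == "frame":
            lum_by_rec[key] = luminance.align_luminance(series, rec)
        elif variant == "neighbourhood":
            if frames_by_movie is None or rec.movie_id not in frames_by_movie:
                raise ValueError("neighbourhood variant requires frames for every movie")
            lum_by_rec[key] = luminance.neighbourhood_series(
                frames_by_movie[rec.movie_id], rec, series.frame_rate,
                diameter_px=neighbourhood_diameter_px, screen=cohort.config.screen,
            )
        else:
            raise ValueError(f"unknown luminance variant {variant!r}")

    models, resid_by_rec = {}, {}
    for pid in cohort.participants:
        keys = sorted(k for k in cohort.recordings if k[0] == pid)
        y = np.concatenate([pupil_by_rec[k] for k in keys])
        x = np.concatenate([lum_by_rec[k] for k in keys])
        model = luminance.fit_luminance_model(y, x, participant_id=pid)
        models[pid] = model
        for k in keys:
            resid_by_rec[k] = luminance.remove_luminance_effect(
                pupil_by_rec[k], model, lum_by_rec[k]
            )
    return models, pupil_by_rec, lum_by_rec, resid_by_rec


def extract_cohort_features(
    cohort: Cohort,
    resid_by_rec: dict,
    detector: str = "idt",
    detector_params: Optional[dict] = None,
) -> pd.DataFrame:
    """Detect events and build the raw per-recording feature table."""
    detector_params = dict(detector_params or {})
    detector_params.setdefault("screen", cohort.config.screen)
    labels = cohort.labels
    vectors = []
    for (pid, mid), rec in sorted(cohort.recordings.items()):
        fixations, saccades = detect_events(rec, method=detector, **detector_params)
        vectors.append(
            extract_features(
                fixations, saccades, resid_by_rec[(pid, mid)], rec.n_samples,
                screen=cohort.config.screen,
                participant_id=pid, movie_id=mid, class_label=labels.get(mid, "none"),
            )
        )
    return features_table(vectors)


def run_study(config: StudyConfig, cohort: Optional[Cohort] = None) -> StudyResult:
    """Execute the full pipeline and collect every result.

    A pre-generated cohort may be supplied (e.g. one loaded from disk);
    otherwise it is synthesized from ``config.synth``.
    """
    if cohort is None:
        cohort = generate_cohort(config.synth)
    clean, rejection = preprocess_cohort(
        cohort, threshold=config.rejection_threshold,
        cutoff_hz=config.filter_cutoff_hz, order=config.filter_order,
    )

    frames_by_movie = None
    need_frames = config.luminance_variant == "neighbourhood" or config.include_dynamics
    if need_frames:
        frames_by_movie = {
            m.movie_id: generate_frames(m, config.synth.seed) for m in clean.movies
        }

    models, pupil_by_rec, lum_by_rec, resid_by_rec = correct_pupil(
        clean, variant=config.luminance_variant,
        neighbourhood_diameter_px=config.neighbourhood_diameter_px,
        frames_by_movie=frames_by_movie,
    )

    features_raw = extract_cohort_features(
        clean, resid_by_rec, detector=config.detector, detector_params=config.detector_params
    )
    features_z = zscore_per_participant(features_raw)

    loso, acc = {}, {}
    dataset = evaluation.assemble_dataset(features_z)
    for task, classes in TASKS.items():
        ds = dataset if len(classes) == 3 else dataset.subset(classes)
        for model in config.classifiers:
            result = evaluation.evaluate_loso(ds, model=model)
            loso[(task, model)] = result
            acc.setdefault(task, {})[model] = result.accuracy
    accuracy_table = pd.DataFrame(acc).T.reindex(list(TASKS))
    screen_df = evaluation.feature_screen(dataset)

    dyn = dyn_corr = diag = None
    if config.include_dynamics:
        indices = {
            mid: movie_dynamics(frm, movie_id=mid).summary
            for mid, frm in frames_by_movie.items()
        }
        dyn = pd.Series(indices, name="dynamics_index").sort_index()
        dyn_corr = dynamics_feature_correlations(indices, features_z)
    if config.include_diagnostics:
        diag = luminance.luminance_diagnostics(pupil_by_rec, lum_by_rec, resid_by_rec)

    return StudyResult(
        config=config,
        rejection=rejection,
        luminance_models=models,
        features=features_z,
        features_raw=features_raw,
        accuracy_table=accuracy_table,
        loso=loso,
        feature_screen=screen_df,
        dynamics=dyn,
        dynamics_correlations=dyn_corr,
        luminance_diagnostics=diag,
    )
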