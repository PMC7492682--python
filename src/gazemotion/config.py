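"""YAML-backed configuration for the pipeline and CLI."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .pipeline import StudyConfig
from .recording import ScreenGeometry
from .synth import MovieSpec, SynthConfig


def study_from_dict(data: dict) -> StudyConfig:
    data = dict(data or {})
    synth_data = dict(data.pop("synth", {}))
    movies = synth_data.pop("movies", None)
    screen = synth_data.pop("screen", None)
    synth_kwargs = {}
    for f in dataclasses.fields(SynthConfig):
        if f.name in synth_data:
            value = synth_data.pop(f.name)
            if isinstance(value, list):
                value = tuple(value) if f.name not in ("movies",) else value
            synth_kwargs[f.name] = value
    if synth_data:
        raise ValueError(f"unknown synth options: {sorted(synth_data)}")
    if movies is not None:
        synth_kwargs["movies"] = [
            m if isinstance(m, MovieSpec) else MovieSpec(**{
                **m, "frame_shape": tuple(m.get("frame_shape", (120, 160)))
            })
            for m in movies
        ]
    if screen is not None:
        if isinstance(screen, dict) and screen.get("center") is not None:
            screen["center"] = tuple(screen["center"])
        synth_kwargs["screen"] = screen if isinstance(screen, ScreenGeometry) else ScreenGeometry(**screen)
    kwargs = {"synth": SynthConfig(**synth_kwargs)}
    for f in dataclasses.fields(StudyConfig):
        if f.name in data:
            value = data.pop(f.name)
            if f.name == "classifiers":
                value = tuple(value)
            kwargs[f.name] = value
    if data:
        raise ValueError(f"unknown study options: {sorted(data)}")
    return StudyConfig(**kwargs)


def load_config(path) -> StudyConfig:
    """Parse a YAML config file into a validated :class:`StudyConfig`."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return study_from_dict(data)


def dump_config(config: StudyConfig, path) -> None:
    def scrub(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: scrub(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [scrub(v) for v in obj]
        if isinstance(obj, list):
            return [scrub(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(scrub(config), sort_keys=False))
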