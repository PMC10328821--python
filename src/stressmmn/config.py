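"""Run configuration: nested sections mirroring every stage's parameters.

Defaults reproduce the study conditions throughout (paradigm layout,
manipulation sizes, filter design, rejection threshold, analysis settings,
group calibration).  YAML round-trips losslessly; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class ParadigmSection:
    n_blocks: int = 10
    standards_per_block: int = 312
    deviants_per_type_per_block: int = 18
    isi_range_ms: tuple[float, float] = (330.0, 630.0)
    stimulus_duration_ms: float = 458.0


@dataclass
class TemplateSection:
    kappa: float = 0.7
    mmn_peak_lag_ms: float = 195.0
    mmn_width_ms: float = 25.0
    amplitude_mode: str = "window_mean"


@dataclass
class NoiseSection:
    exponent: float = 1.0
    rms_uv: float = 10.0
    artifact_fraction: float = 0.05


@dataclass
class GroupSection:
    label: str = "German"
    n_subjects: int = 16
    syll1_mean_uv: float = -1.62
    syll1_sd_uv: float = 1.81
    syll2_mean_uv: float = -3.53
    syll2_sd_uv: float = 1.80


@dataclass
class PreprocessSection:
    band_hz: tuple[float, float] = (0.1, 45.0)
    filter_order: int = 9056
    kaiser_beta: float = 5.6533
    transition_bw_hz: float = 0.2
    epoch_window_ms: tuple[float, float] = (-100.0, 600.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reject_threshold_uv: float = 100.0


@dataclass
class MmnSection:
    q: float = 0.05
    threshold_fraction: float = 0.7
    search_offset_ms: tuple[float, float] = (100.0, 350.0)


@dataclass
class StatsSection:
    alpha: float = 0.05
    power_target: float = 0.80
    effect_size_d: float = 1.033


@dataclass
class RunConfig:
    rng_seed: int = 0
    outdir: str = "stressmmn_out"
    log_level: str = "INFO"
    sample_rate_hz: float = 500.0
    paradigm: ParadigmSection = field(default_factory=ParadigmSection)
    template: TemplateSection = field(default_factory=TemplateSection)
    noise: NoiseSection = field(default_factory=NoiseSection)
    groups: list[GroupSection] = field(
        default_factory=lambda: [
            GroupSection(),
            GroupSection("Slavic", 16, -2.35, 1.28, -3.30, 1.88),
        ]
    )
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    mmn: MmnSection = field(default_factory=MmnSection)
    stats: StatsSection = field(default_factory=StatsSection)


_TUPLE_FIELDS = {"isi_range_ms", "band_hz", "epoch_window_ms", "baseline_ms",
                 "search_offset_ms"}


def _build(cls, data):
    if not isinstance(data, dict):
        raise ConfigError(f"section for {cls.__name__} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or name in (
            "paradigm", "template", "noise", "preprocess", "mmn", "stats"
        ):
            value = _build(_SECTION_TYPES[name], value)
        elif name == "groups":
            if not isinstance(value, list):
                raise ConfigError("groups must be a list")
            value = [_build(GroupSection, g) for g in value]
        elif name in _TUPLE_FIELDS:
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


_SECTION_TYPES = {
    "paradigm": ParadigmSection,
    "template": TemplateSection,
    "noise": NoiseSection,
    "preprocess": PreprocessSection,
    "mmn": MmnSection,
    "stats": StatsSection,
}


def config_from_dict(data: dict) -> RunConfig:
    return _build(RunConfig, data)


def config_to_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [convert(x) for x in obj]
        return obj

    return convert(config)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
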