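"""Caller configuration: thresholds, presets, and key=value config file I/O.

Three presets are provided:

``wgs-pe``
    Paired-end whole-genome calling. Discordant-pair and clipped evidence,
    support required on both sides of the insertion.
``wes-pe``
    Paired-end whole-exome calling. Same thresholds, but one-sided
    (single-cluster) predictions are allowed so that insertions near capture
    boundaries are not lost.
``wes-se``
    Single-end (clipped-read only) exome calling with shorter clips (20 bp)
    and a 3 bp clip-position scatter tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping


class ConfigError(ValueError):
    """Raised when a configuration value or preset is invalid."""


@dataclass(frozen=True)
class CallerConfig:
    """Every tunable threshold of the caller.

    Distances and lengths are in base pairs; qualities are phred scores.
    """

    #: minimum total supporting reads for a reported prediction
    min_support: int = 5
    #: max start-to-start gap when chaining discordant anchors into a cluster
    neighborhood_distance: int = 200
    #: max gap allowed when joining a 5' and a 3' discordant cluster
    max_cluster_join_distance: int = 600
    #: max overlap allowed when joining 5'/3' clusters (target site duplication)
    max_cluster_overlap: int = 50
    #: max gap between joined clipped clusters (target site deletion)
    max_target_deletion_gap: int = 20
    #: minimum soft-clip length considered as candidate evidence
    min_clip_length: int = 35
    #: minimum mean base quality of the clipped bases
    min_clip_avg_quality: float = 20.0
    #: maximum clip length tolerated at the read's other end
    max_other_end_clip: int = 7
    #: max deviation of a clip position from its cluster's modal position
    clip_position_tolerance: int = 3
    #: flag predictions within this distance of a same-family reference ME
    reference_mei_filter_window: int = 90
    #: merge final predictions of the same family within this distance
    prediction_merge_window: int = 50
    #: a terminal homopolymer must be longer than this to count as polyA/polyT
    min_polyA_length: int = 8
    #: max mismatch fraction for a candidate-vs-mobilome alignment
    mobilome_max_mismatch_frac: float = 0.10
    #: insert sizes beyond median +/- multiplier*sd are discordant
    insert_size_sd_multiplier: float = 4.0
    #: require evidence on both sides of the insertion
    require_double_cluster: bool = True
    #: "paired" or "single"; single mode consumes only clipped evidence
    mode: str = "paired"
    #: MAPQ floor used as the portable proxy for "uniquely mapped"
    min_mapq: int = 20
    #: number of proper pairs sampled for insert-size estimation
    insert_size_sample_size: int = 10000

    def validate(self) -> "CallerConfig":
        for field in (
            "neighborhood_distance",
            "max_cluster_join_distance",
            "max_cluster_overlap",
            "max_target_deletion_gap",
            "min_clip_length",
            "max_other_end_clip",
            "clip_position_tolerance",
            "reference_mei_filter_window",
            "prediction_merge_window",
            "min_polyA_length",
            "min_mapq",
        ):
            value = getattr(self, field)
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"{field} must be a non-negative integer, got {value!r}")
        if not isinstance(self.min_support, int) or self.min_support < 1:
            raise ConfigError(f"min_support must be >= 1, got {self.min_support!r}")
        if not 0.0 < self.mobilome_max_mismatch_frac < 1.0:
            raise ConfigError(
                "mobilome_max_mismatch_frac must be in (0, 1), got "
                f"{self.mobilome_max_mismatch_frac!r}"
            )
        if self.min_clip_avg_quality < 0:
            raise ConfigError(
                f"min_clip_avg_quality must be >= 0, got {self.min_clip_avg_quality!r}"
            )
        if self.insert_size_sd_multiplier <= 0:
            raise ConfigError(
                f"insert_size_sd_multiplier must be > 0, got {self.insert_size_sd_multiplier!r}"
            )
        if self.mode not in ("paired", "single"):
            raise ConfigError(f"mode must be 'paired' or 'single', got {self.mode!r}")
        if self.insert_size_sample_size < 1:
            raise ConfigError("insert_size_sample_size must be >= 1")
        return self

    def replace(self, **kwargs) -> "CallerConfig":
        return dataclasses.replace(self, **kwargs).validate()


PRESETS: Mapping[str, CallerConfig] = {
    "wgs-pe": CallerConfig(),
    "wes-pe": CallerConfig(require_double_cluster=False),
    "wes-se": CallerConfig(
        mode="single",
        min_clip_length=20,
        clip_position_tolerance=3,
        require_double_cluster=True,
    ),
}

_BOOL_FIELDS = {"require_double_cluster"}
_FLOAT_FIELDS = {
    "min_clip_avg_quality",
    "mobilome_max_mismatch_frac",
    "insert_size_sd_multiplier",
}
_STR_FIELDS = {"mode"}
_FIELD_NAMES = {f.name for f in dataclasses.fields(CallerConfig)}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in _BOOL_FIELDS:
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ConfigError(f"{key}: expected a boolean, got {raw!r}")
    if key in _FLOAT_FIELDS:
        try:
            return float(raw)
        except ValueError as exc:
            raise ConfigError(f"{key}: expected a number, got {raw!r}") from exc
    if key in _STR_FIELDS:
        return raw
    try:
        return int(raw)
    except ValueError as exc:
        raise ConfigError(f"{key}: expected an integer, got {raw!r}") from exc


def parse_config_text(text: str) -> dict:
    """Parse flat ``key = value`` text into a typed override dict."""
    overrides: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = line.split("=", 1)
        key = key.strip()
        if key not in _FIELD_NAMES:
            raise ConfigError(f"line {lineno}: unknown configuration key {key!r}")
        overrides[key] = _parse_value(key, raw)
    return overrides


def load_config(
    path: str | None = None,
    preset: str = "wgs-pe",
    overrides: Mapping | None = None,
) -> CallerConfig:
    """Resolve a configuration: preset < config file < explicit overrides."""
    if preset not in PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; choose one of {sorted(PRESETS)}"
        )
    values = dataclasses.asdict(PRESETS[preset])
    if path is not None:
        with open(path, "rt", encoding="utf-8") as handle:
            values.update(parse_config_text(handle.read()))
    if overrides:
        for key in overrides:
            if key not in _FIELD_NAMES:
                raise ConfigError(f"unknown configuration key {key!r}")
        values.update(overrides)
    return CallerConfig(**values).validate()


def dump_config(cfg: CallerConfig) -> str:
    """Serialize a config as flat key=value text; inverse of :func:`load_config`."""
    lines = []
    for field in dataclasses.fields(CallerConfig):
        value = getattr(cfg, field.name)
        if isinstance(value, bool):
            value = "true" if value else "false"
        lines.append(f"{field.name} = {value}")
    return "\n".join(lines) + "\n"
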