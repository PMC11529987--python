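"""Pipeline configuration: a flat, human-editable YAML document.

Every key has a default; unknown keys are reported with a nearest-match
suggestion, and all problems in a file are reported at once rather than
first-failure. CLI flags override file values (file < flag precedence).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

STAGES = ("xscan", "motif", "scan", "filter", "fit", "quant", "kt50")

#: Stage -> (config key of the input consumed when the upstream stage is
#: not part of the run, upstream stage or None).
_STAGE_INPUTS = {
    "xscan": ("xscan_readouts", None),
    "motif": ("activity_matrix", "xscan"),
    "scan": ("pattern_file", "motif"),
    "filter": (None, "scan"),
    "fit": ("dose_response", None),
    "quant": ("prm_table", None),
    "kt50": ("killcurves", None),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    output_dir: str = "out"

    # Normalization / motif
    anchor_mode: str = "cognate"
    cognate: str = "VVVGAVGVGK"
    motif_threshold: float = 50.0

    # Crossreactivity screen
    allele: str = "A*11:01"
    affinity_threshold_nm: float = 500.0
    predictor: str = "builtin"  # "builtin" | "external"

    # Quantitation
    spike_fmol: float = 200.0
    injected_fraction: float = 0.5

    # Stage inputs (paths; only those needed by selected stages are required)
    xscan_readouts: str | None = None
    activity_matrix: str | None = None
    pattern_file: str | None = None
    proteome: str | None = None
    predictions: str | None = None
    dose_response: str | None = None
    prm_table: str | None = None
    killcurves: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


_FIELD_NAMES = {f.name for f in fields(PipelineConfig)}


def _check(config: PipelineConfig) -> list[str]:
    problems = []
    if not isinstance(config.seed, int):
        problems.append(f"seed must be an integer, got {config.seed!r}")
    unknown_stages = [s for s in config.stages if s not in STAGES]
    if unknown_stages:
        problems.append(f"unknown stage(s) {unknown_stages}; valid: {list(STAGES)}")
    if not config.stages:
        problems.append("stages must not be empty")
    if not 0 < config.motif_threshold <= 100:
        problems.append(
            f"motif_threshold must be in (0, 100], got {config.motif_threshold}"
        )
    if config.affinity_threshold_nm <= 0:
        problems.append(
            f"affinity_threshold_nm must be positive, got {config.affinity_threshold_nm}"
        )
    if config.anchor_mode not in ("cognate", "pma_i", "detergent"):
        problems.append(f"anchor_mode must be cognate/pma_i/detergent, got {config.anchor_mode!r}")
    if config.predictor not in ("builtin", "external"):
        problems.append(f"predictor must be 'builtin' or 'external', got {config.predictor!r}")
    if config.spike_fmol <= 0:
        problems.append(f"spike_fmol must be positive, got {config.spike_fmol}")
    if not 0 < config.injected_fraction <= 1:
        problems.append(
            f"injected_fraction must be in (0, 1], got {config.injected_fraction}"
        )
    return problems


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML path, dict, or existing config.

    All problems — unknown keys (with a did-you-mean suggestion), bad
    values — are collected and raised together as one ConfigError.
    """
    if isinstance(source, PipelineConfig):
        data = source.to_dict()
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError([f"config file {source} is not a key-value document"])

    problems = []
    for key in sorted(set(data) - _FIELD_NAMES):
        hint = difflib.get_close_matches(key, _FIELD_NAMES, n=1)
        suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
        problems.append(f"unknown config key {key!r}{suggestion}")
    known = {k: v for k, v in data.items() if k in _FIELD_NAMES}
    try:
        config = PipelineConfig(**known)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError([str(exc)]) from exc
    problems.extend(_check(config))
    if problems:
        raise ConfigError(problems)
    return config


def required_inputs(config: PipelineConfig) -> list[tuple[str, str]]:
    """(config key, path) pairs that must exist for the selected stages."""
    selected = set(config.stages)
    required = []
    for stage in selected:
        key, upstream = _STAGE_INPUTS[stage]
        if key is not None and (upstream is None or upstream not in selected):
            required.append((stage, key))
    if "scan" in selected:
        required.append(("scan", "proteome"))
    if "filter" in selected and config.predictor == "external":
        required.append(("filter", "predictions"))
    out = []
    problems = []
    for stage, key in sorted(set(required)):
        path = getattr(config, key)
        if path is None:
            problems.append(f"stage {stage!r} requires config key {key!r} to be set")
        elif not Path(path).exists():
            problems.append(f"stage {stage!r} input {key}={path!r} does not exist")
        else:
            out.append((key, path))
    if problems:
        raise ConfigError(problems)
    return out
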