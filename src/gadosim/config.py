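"""Study configuration: a single human-editable YAML file.

Four sections — ``compound``, ``cohorts``, ``design``, ``output`` — each
flat key:value.  Every key is optional; the embedded defaults constitute
the canonical replication of the published study, so an empty file (or no
file) runs it unchanged.  Unknown keys are rejected with their full key
path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .compound import CompoundParams
from .errors import ConfigError
from .populations import COHORT_ORDER, CohortSpec, builtin_cohorts
from .trial import TrialDesign

__all__ = ["OutputOptions", "StudyConfig", "load_config", "save_config", "config_hash"]

_TUPLE_FIELDS = {"age_range", "gfr_bounds"}


@dataclass(frozen=True)
class OutputOptions:
    directory: str = "study_out"
    plots: bool = True
    envelope_low: float = 0.05
    envelope_high: float = 0.95


@dataclass(frozen=True)
class StudyConfig:
    """Complete specification of one study run."""

    compound: CompoundParams = field(default_factory=CompoundParams)
    cohorts: dict = field(default_factory=builtin_cohorts)
    design: TrialDesign = field(default_factory=TrialDesign)
    output: OutputOptions = field(default_factory=OutputOptions)

    @property
    def cohort_order(self) -> list[str]:
        known = [c for c in COHORT_ORDER if c in self.cohorts]
        extra = [c for c in self.cohorts if c not in COHORT_ORDER]
        return known + sorted(extra)


def _apply_section(cls, defaults, section: dict, path: str):
    """Overlay a flat key:value section onto a dataclass instance."""
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) under {path}: {', '.join(sorted(unknown))}"
        )
    clean = {}
    for key, value in section.items():
        if key in _TUPLE_FIELDS and value is not None:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError(f"{path}.{key} must be a [lo, hi] pair")
            value = (float(value[0]), float(value[1]))
        clean[key] = value
    try:
        return dataclasses.replace(defaults, **clean)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under {path}: {exc}") from exc


def load_config(path=None) -> StudyConfig:
    """Load a study configuration, overlaying the embedded defaults.

    ``path=None`` returns the default (canonical study) configuration.
    """
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    known_sections = {"compound", "cohorts", "design", "output"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")

    compound = _apply_section(
        CompoundParams, CompoundParams(), raw.get("compound") or {}, "compound"
    )
    design = _apply_section(
        TrialDesign, TrialDesign(), raw.get("design") or {}, "design"
    )
    output = _apply_section(
        OutputOptions, OutputOptions(), raw.get("output") or {}, "output"
    )
    cohorts = dict(builtin_cohorts())
    for label, overrides in (raw.get("cohorts") or {}).items():
        if not isinstance(overrides, dict):
            raise ConfigError(f"cohorts.{label} must be a mapping")
        base = cohorts.get(label)
        if base is None:
            if "weight_mean" not in overrides:
                raise ConfigError(
                    f"new cohort cohorts.{label} requires at least weight_mean"
                )
            base = CohortSpec(label=label, weight_mean=float(overrides["weight_mean"]))
        cohorts[label] = _apply_section(
            CohortSpec, base, {**overrides, "label": label}, f"cohorts.{label}"
        )
    return StudyConfig(compound=compound, cohorts=cohorts, design=design, output=output)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def save_config(config: StudyConfig, path) -> None:
    """Write the fully resolved configuration as YAML."""
    doc = {
        "compound": _as_plain(config.compound),
        "design": _as_plain(config.design),
        "output": _as_plain(config.output),
        "cohorts": {label: _as_plain(spec) for label, spec in config.cohorts.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_hash(config: StudyConfig) -> str:
    """Stable hash of the resolved configuration, for the run manifest."""
    doc = json.dumps(_as_plain(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(doc.encode("utf-8")).hexdigest()[:16]
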