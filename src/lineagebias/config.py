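"""Configuration parsing/validation and reproducibility manifests.

Configs are YAML with five sections (``rates``, ``simulation``,
``extraction``, ``measures``, ``experiments``).  Every key has a default
matching the study design (100-year burn-in, 50-year tail, 10 replicates,
10% genealogist sample of adults 18+, nine generations), so an empty file
is a valid config.  Unknown keys are rejected, all at once, to catch typos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid configuration; message lists every offending key."""


@dataclass
class RatesSection:
    source: str = "synthetic"  # synthetic | files
    preset: str = "sweden_like"
    year_start: int = 1751
    year_end: int = 2022
    seed: int = 0  # preset fluctuation stream (offset by the run seed)
    tfr: float | None = None  # constant-regime overrides (preset='constant')
    e0: float | None = None
    asfr_path: str | None = None
    mortality_path: str | None = None
    mortality_kind: str = "mx"
    allow_missing: bool = False

    def validate(self) -> list[str]:
        errs = []
        if self.source not in ("synthetic", "files"):
            errs.append(f"rates.source: {self.source!r} not in {{synthetic, files}}")
        if self.source == "synthetic" and self.preset not in ("sweden_like", "constant"):
            errs.append(f"rates.preset: unknown preset {self.preset!r}")
        if self.preset == "constant" and (self.tfr is None or self.e0 is None):
            errs.append("rates.tfr and rates.e0 are required for the constant preset")
        if self.source == "files" and not (self.asfr_path and self.mortality_path):
            errs.append("rates.asfr_path and rates.mortality_path are required "
                        "when rates.source = files")
        if self.mortality_kind not in ("mx", "qx"):
            errs.append(f"rates.mortality_kind: {self.mortality_kind!r} not in {{mx, qx}}")
        if self.year_end < self.year_start:
            errs.append("rates.year_end before rates.year_start")
        return errs


@dataclass
class SimulationSection:
    n_initial: int = 2000
    burn_in_years: int = 100
    tail_years: int = 50
    replicates: int = 10
    sex_ratio_at_birth: float = 0.5122
    min_birth_interval_months: int = 9
    match_mean: float = 2.0
    match_sd: float = 3.0
    min_groom_age_years: int = 15
    initial_max_age_years: int = 50

    def validate(self) -> list[str]:
        errs = []
        if self.n_initial <= 0:
            errs.append("simulation.n_initial must be positive")
        if self.replicates < 1:
            errs.append("simulation.replicates must be >= 1")
        if not 0 < self.sex_ratio_at_birth < 1:
            errs.append("simulation.sex_ratio_at_birth must be in (0, 1)")
        if self.burn_in_years < 0 or self.tail_years < 0:
            errs.append("simulation burn-in/tail years must be >= 0")
        return errs


@dataclass
class ExtractionSection:
    sample_fraction: float = 0.10
    min_ego_age_years: int = 18
    max_generations: int = 9
    child_age_threshold_years: int = 5
    childless_min_age_years: int = 15

    def validate(self) -> list[str]:
        errs = []
        if not 0 < self.sample_fraction <= 1:
            errs.append("extraction.sample_fraction must be in (0, 1]")
        if self.max_generations < 1:
            errs.append("extraction.max_generations must be >= 1")
        if self.child_age_threshold_years <= 0 or self.childless_min_age_years <= 0:
            errs.append("extraction age thresholds must be positive")
        return errs


@dataclass
class MeasuresSection:
    ego_birth_quantile: float = 0.10
    fertility_lead_years: int = 15
    min_fertile_exposure: float = 100.0
    min_total_exposure: float = 200.0

    def validate(self) -> list[str]:
        errs = []
        if not 0 <= self.ego_birth_quantile <= 1:
            errs.append("measures.ego_birth_quantile must be in [0, 1]")
        return errs


@dataclass
class ExperimentsSection:
    omission_proportions: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    split_year: int = 1900
    window_years: int = 15

    def validate(self) -> list[str]:
        errs = []
        for p in self.omission_proportions:
            if not 0 <= p <= 1:
                errs.append(f"experiments.omission_proportions: {p} outside [0, 1]")
        if self.window_years < 1:
            errs.append("experiments.window_years must be >= 1")
        return errs


@dataclass
class PipelineConfig:
    rates: RatesSection = field(default_factory=RatesSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    extraction: ExtractionSection = field(default_factory=ExtractionSection)
    measures: MeasuresSection = field(default_factory=MeasuresSection)
    experiments: ExperimentsSection = field(default_factory=ExperimentsSection)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {f.name: f.default_factory for f in dataclasses.fields(PipelineConfig)}


def _build_section(cls, data: dict, section: str, errors: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{section}.{key}: unknown key")
            continue
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        obj = cls()
    errors.extend(obj.validate())
    return obj


def parse_config(path: str | Path | None = None,
                 data: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline config; empty input means all defaults.

    Raises :class:`ConfigError` listing every offending key at once.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            raw = Path(path).read_text(encoding="utf-8")
            data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    sections = {}
    for name, factory in _SECTIONS.items():
        cls = type(factory())
        sections[name] = _build_section(cls, data.get(name) or {}, name, errors)
    for key in data:
        if key not in _SECTIONS:
            errors.append(f"{key}: unknown section")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(sorted(errors)))
    return PipelineConfig(**sections)


# ---------------------------------------------------------------------------
# manifests


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, seeds, file hashes."""

    config: dict
    seed: int
    replicate_seeds: list[int] = field(default_factory=list)
    version: str = ""
    rate_source: str = ""
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    def matches(self, other: "RunManifest") -> bool:
        """True when config, seed and input hashes agree (stage can be skipped)."""
        return (self.config == other.config and self.seed == other.seed
                and self.inputs == other.inputs)
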