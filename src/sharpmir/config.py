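"""Pipeline configuration: every screening threshold in one place.

Two presets are provided.  "default" is the reuse-oriented setting
(general length window, arm-assignment tolerance, criteria calibrated to
the embedded energy model).  "paper" pins every threshold to the
literature-stated value for the source study: exact 22-nt length filter,
two-mismatch conservation allowance, abundance cutoff 10, hairpin rule of
18 matched pairs / one central loop / -18 kcal/mol, and the target-scan
thresholds score >= 145 and energy <= -10 kcal/mol.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .hairpin import HairpinCriteria
from .simulate import DEFAULT_ADAPTER
from .targets import ScoringScheme

PRESETS = ("default", "paper")


@dataclass
class PipelineConfig:
    # read processing
    adapter: str = DEFAULT_ADAPTER
    trim_min_overlap: int = 6
    trim_max_mismatch_rate: float = 0.1
    min_len: int = 18
    max_len: int = 26
    contaminant_max_mismatch: int = 0
    # mapping & conservation
    mapping_max_mismatch: int = 0
    conservation_max_mismatch: int = 2
    # precursor discovery
    hairpin: HairpinCriteria = field(default_factory=HairpinCriteria)
    flank: int = 70
    # quantification
    abundance_cutoff: int = 10
    arm_tolerance: int = 2
    # target scan
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    run_targets: bool = False
    # reproducibility
    seed: int = 0
    # paths (inputs may be None when the simulate stage provides them)
    reads_path: str | None = None
    transcriptome_path: str | None = None
    reference_path: str | None = None
    contaminants_path: str | None = None
    output_dir: str = "sharpmir_out"
    preset: str = "default"


def paper_preset(**overrides) -> PipelineConfig:
    """The literature-stated thresholds, exactly."""
    config = PipelineConfig(
        min_len=22, max_len=22,
        contaminant_max_mismatch=0,
        mapping_max_mismatch=0,
        conservation_max_mismatch=2,
        hairpin=HairpinCriteria(min_matched_pairs=18,
                                max_terminal_loops_on_mature_stem=1,
                                max_energy=-18.0),
        abundance_cutoff=10,
        arm_tolerance=0,
        scoring=ScoringScheme(min_score=145.0, max_energy=-10.0,
                              seed_span=(2, 7), max_seed_gu=1,
                              max_duplex_gaps=1),
        preset="paper",
    )
    for key, value in overrides.items():
        if not hasattr(config, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(config, key, value)
    return config


def make_config(preset: str = "default", **overrides) -> PipelineConfig:
    if preset == "paper":
        return paper_preset(**overrides)
    if preset != "default":
        raise ConfigError(
            f"unknown preset {preset!r}; available presets: {', '.join(PRESETS)}")
    config = PipelineConfig(**{k: v for k, v in overrides.items()})
    return config


def validate_config(config: PipelineConfig,
                    check_paths: bool = True) -> list[str]:
    """Return a list of violations (empty when the config is valid)."""
    errors = []
    if config.min_len > config.max_len:
        errors.append("min_len exceeds max_len")
    for name in ("min_len", "max_len", "trim_min_overlap", "flank",
                 "contaminant_max_mismatch", "mapping_max_mismatch",
                 "conservation_max_mismatch", "arm_tolerance"):
        if getattr(config, name) < 0:
            errors.append(f"{name} must be >= 0")
    if config.abundance_cutoff < 0:
        errors.append("cutoff must be >= 0 (field abundance_cutoff)")
    if not (0 <= config.trim_max_mismatch_rate <= 1):
        errors.append("trim_max_mismatch_rate must be in [0, 1]")
    if len(config.adapter) < config.trim_min_overlap:
        errors.append("adapter shorter than trim_min_overlap")
    if config.scoring.min_score <= 0:
        errors.append("scoring.min_score must be positive")
    if config.preset not in PRESETS:
        errors.append(
            f"unknown preset {config.preset!r}; available: {', '.join(PRESETS)}")
    if config.preset == "paper":
        pinned = {
            "min_len": 22, "max_len": 22, "conservation_max_mismatch": 2,
            "abundance_cutoff": 10,
        }
        for key, value in pinned.items():
            if getattr(config, key) != value:
                errors.append(f"paper preset requires {key} == {value}")
        if config.scoring.min_score != 145.0:
            errors.append("paper preset requires scoring.min_score == 145")
        if config.scoring.max_energy != -10.0:
            errors.append("paper preset requires scoring.max_energy == -10")
        if config.hairpin.min_matched_pairs != 18:
            errors.append("paper preset requires hairpin.min_matched_pairs == 18")
        if config.hairpin.max_energy != -18.0:
            errors.append("paper preset requires hairpin.max_energy == -18")
    if check_paths:
        for name in ("reads_path", "transcriptome_path", "reference_path",
                     "contaminants_path"):
            value = getattr(config, name)
            if value is not None and not Path(value).exists():
                errors.append(f"{name} does not exist: {value}")
    return errors


def to_yaml(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as out:
        yaml.safe_dump(asdict(config), out, sort_keys=True)


def from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    hairpin = HairpinCriteria(**raw.pop("hairpin", {}))
    scoring_raw = raw.pop("scoring", {})
    for key in ("scale_span", "seed_span"):
        if key in scoring_raw and scoring_raw[key] is not None:
            scoring_raw[key] = tuple(scoring_raw[key])
    scoring = ScoringScheme(**scoring_raw)
    return PipelineConfig(hairpin=hairpin, scoring=scoring, **raw)
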