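"""Pipeline configuration: validated defaults for every stage.

Defaults encode the pipeline's canonical constants: 2-kb windows at a 500-bp step
with a 1e-3 per-window threshold; 100-bp TSS-profile bins; 50-kbp SINE
windows at 5-kbp intervals; the 1.24 induction fold threshold; the 225-nm
colocalization threshold; the mean + 1 SD RNAPII-positive rule; the 200-nm
confocal z-step.  Configuration files are JSON or YAML; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields

import yaml

from .context import SineProfileConfig
from .windowscan import ScanConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration schema violation; lists the offending keys."""


@dataclass
class ProfileConfig:
    tss_bin: int = 100
    tss_extent: int = 2000
    promoter_window: tuple[int, int] = (0, 500)

    def __post_init__(self):
        if self.tss_bin <= 0:
            raise ConfigError("profile.tss_bin must be > 0")
        if self.tss_extent % self.tss_bin != 0:
            raise ConfigError("profile.tss_extent must be a multiple of tss_bin")


@dataclass
class GroupingConfig:
    fold_threshold: float = 1.24
    p_threshold: float = 0.05

    def __post_init__(self):
        if self.fold_threshold <= 1.0:
            raise ConfigError("grouping.fold_threshold must be > 1")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("grouping.p_threshold must be in (0, 1)")


@dataclass
class MotifConfig:
    threshold_fraction: float = 0.80  # hit threshold as a fraction of max score
    category_edges: tuple[float, float, float] = (0.80, 0.875, 0.95)
    pseudocount: float = 0.25


@dataclass
class ImagingConfig:
    coloc_threshold_nm: float = 225.0
    positive_k: float = 1.0
    fish_k: float = 2.0
    min_volume: int = 2
    voxel_nm: tuple[float, float, float] = (100.0, 100.0, 200.0)

    def __post_init__(self):
        if self.coloc_threshold_nm <= 0:
            raise ConfigError("imaging.coloc_threshold_nm must be > 0")
        if any(v <= 0 for v in self.voxel_nm):
            raise ConfigError("imaging.voxel_nm entries must be > 0")


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    scan: ScanConfig = field(default_factory=ScanConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    sine_profile: SineProfileConfig = field(default_factory=SineProfileConfig)
    grouping: GroupingConfig = field(default_factory=GroupingConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    def explain(self) -> str:
        """Human-readable provenance of every default."""
        lines = [
            "scan.window = 2000 bp: differential windows slid across the genome",
            "scan.step = 500 bp: scan stride (package choice; region widths quantize at 0.5 kbp)",
            "scan.alpha = 1e-3: per-window one-sided p threshold for calling",
            "profile.tss_bin = 100 bp: TSS metaprofile bin",
            "profile.promoter_window = [0, 500) bp: promoter tag-density summary window",
            "sine_profile.window_width = 50000 bp at step 5000 bp: acetylated-SINE density windows",
            "grouping.fold_threshold = 1.24 (inclusive): induction threshold for NI/NR calls",
            "grouping.p_threshold = 0.05: adjusted-p cut for differential expression",
            "motif.threshold_fraction = 0.80 of max score: PWM hit threshold",
            "imaging.positive_k = 1.0: RNAPII-positive voxels above mean + 1 SD in the nucleus",
            "imaging.coloc_threshold_nm = 225: locus-factory colocalization distance",
            "imaging.voxel_nm dz = 200: confocal z-step",
        ]
        return "\n".join(lines)


def _build(cls, data: dict, prefix: str):
    known = {f.name: f for f in fields(cls)}
    unknown = [f"{prefix}{k}" for k in data if k not in known]
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "scan", "profile", "sine_profile", "grouping", "motif", "imaging"
        ):
            sub_cls = {
                "scan": ScanConfig,
                "profile": ProfileConfig,
                "sine_profile": SineProfileConfig,
                "grouping": GroupingConfig,
                "motif": MotifConfig,
                "imaging": ImagingConfig,
            }[f.name]
            if not isinstance(value, dict):
                raise ConfigError(f"{prefix}{key} must be a mapping")
            kwargs[key] = _build(sub_cls, value, f"{prefix}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid configuration under {prefix or 'root'}: {exc}") from exc


def load_config(path=None) -> PipelineConfig:
    """Load and validate a JSON/YAML configuration; missing keys take the
    defaults above, unknown keys are rejected, and an empty (or absent) file
    yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return PipelineConfig()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _build(PipelineConfig, data, "")
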