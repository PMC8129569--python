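"""Pipeline configuration: defaults, strict validation, YAML loading.

Defaults mirror the analysis conditions of the study design the pipeline
emulates: fold change 2, 40 initial k-means clusters, top-5 clone
frequencies, 0.9/0.1 posterior thresholds.  Unknown keys are rejected with
a close-match suggestion so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PathsConfig:
    mouse_matrix: str | None = None
    mouse_annotations: str | None = None
    human_matrix: str | None = None
    human_annotations: str | None = None
    validation_matrix: str | None = None
    validation_annotations: str | None = None
    airr_table: str | None = None
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    barcode_table: str | None = None
    primer_table: str | None = None
    sample_groups: str | None = None
    outdir: str = "lplpipe_out"


@dataclass
class DiffexprConfig:
    fc_threshold: float = 2.0
    alpha: float = 0.05
    heterogeneity_quantile: float = 0.47
    prior_df: float | str = "auto"
    prior_var: float | str = "auto"
    group_a: str | None = None  # default: first class in annotation order
    group_b: str | None = None  # default: second class

    def validate(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("diffexpr.fc_threshold must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("diffexpr.alpha must lie in (0, 1]")
        if not 0 < self.heterogeneity_quantile <= 1:
            raise ValueError("diffexpr.heterogeneity_quantile must lie in (0, 1]")
        for name in ("prior_df", "prior_var"):
            v = getattr(self, name)
            if v != "auto" and float(v) < 0:
                raise ValueError(f"diffexpr.{name} must be 'auto' or nonnegative")


@dataclass
class AggclustConfig:
    k_init: int = 40
    restarts: int = 10
    reference_mode: str = "hierarchical"

    def validate(self) -> None:
        if self.k_init < 1:
            raise ValueError("aggclust.k_init must be >= 1")
        if self.restarts < 1:
            raise ValueError("aggclust.restarts must be >= 1")
        if self.reference_mode not in ("hierarchical", "direction"):
            raise ValueError("aggclust.reference_mode must be hierarchical or direction")


@dataclass
class LpsConfig:
    p_hi: float = 0.9
    p_lo: float = 0.1
    max_genes: int | None = None  # set to enable predictor refinement
    positive_class: str | None = None  # default: second human class

    def validate(self) -> None:
        if not 0 <= self.p_lo < self.p_hi <= 1:
            raise ValueError("lps thresholds need 0 <= p_lo < p_hi <= 1")
        if self.max_genes is not None and self.max_genes < 1:
            raise ValueError("lps.max_genes must be >= 1 when set")


@dataclass
class ClonalityConfig:
    n_top: int = 5
    min_overlap: int = 10
    max_mismatch_density: float = 0.25

    def validate(self) -> None:
        if self.n_top < 1:
            raise ValueError("clonality.n_top must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("clonality.min_overlap must be >= 1")
        if not 0 <= self.max_mismatch_density <= 1:
            raise ValueError("clonality.max_mismatch_density must lie in [0, 1]")


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    diffexpr: DiffexprConfig = field(default_factory=DiffexprConfig)
    aggclust: AggclustConfig = field(default_factory=AggclustConfig)
    lps: LpsConfig = field(default_factory=LpsConfig)
    clonality: ClonalityConfig = field(default_factory=ClonalityConfig)
    seed: int = 0

    def validate(self) -> None:
        for section in (self.diffexpr, self.aggclust, self.lps, self.clonality):
            section.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, outdir: Path | str) -> Path:
        """Write the fully-resolved configuration into the output directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


# common alternative spellings mapped to their canonical key, so a typo
# like "fold_chnage" still earns a useful suggestion
_ALIASES = {
    "fold_change": "fc_threshold",
    "fdr": "alpha",
    "kmeans_k": "k_init",
    "top_n": "n_top",
    "mismatch_density": "max_mismatch_density",
}


def _suggest(key: str, known) -> str:
    pool = list(known) + list(_ALIASES)
    hint = difflib.get_close_matches(key, pool, n=1, cutoff=0.5)
    if not hint:
        return ""
    canonical = _ALIASES.get(hint[0], hint[0])
    return f"; did you mean {canonical!r}?"


def _fill(cls, data: dict[str, Any], prefix: str):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            raise ValueError(f"unknown config key {prefix}{key!r}{_suggest(key, known)}")
    return cls(**data)


def config_from_dict(data: dict[str, Any] | None) -> PipelineConfig:
    data = dict(data or {})
    sections = {
        "paths": PathsConfig,
        "diffexpr": DiffexprConfig,
        "aggclust": AggclustConfig,
        "lps": LpsConfig,
        "clonality": ClonalityConfig,
    }
    kwargs: dict[str, Any] = {}
    for key in list(data):
        if key in sections:
            sub = data.pop(key) or {}
            if not isinstance(sub, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _fill(sections[key], sub, f"{key}.")
        elif key == "seed":
            kwargs["seed"] = int(data.pop(key))
        else:
            known = list(sections) + ["seed"] + [
                f.name for c in sections.values() for f in dataclasses.fields(c)
            ]
            raise ValueError(f"unknown config key {key!r}{_suggest(key, known)}")
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: Path | str) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(raw)
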