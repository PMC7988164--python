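"""Key-value text configuration for the pipeline.

Configs are flat-ish YAML mappings; unknown keys are rejected so typos in
threshold names fail early.  The config round-trips through its text form.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs besides the data itself."""

    fasta: str | None = None
    library: str | None = None
    transitions: str | None = None
    output_dir: str = "glaquant_out"
    profile: str = "global"
    scheme_start: float = 399.5
    scheme_end: float = 1250.0
    scheme_width: float = 26.0
    scheme_stride: float = 25.0
    fdr_threshold: float = 0.01
    alpha: float = 1e-5
    q: float = 0.01
    rt_tolerance: float = 1.0
    reference: str = "trypsin|VATVSLPR"
    shared_peptides: str = "exclude"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fdr_threshold <= 1.0):
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if self.scheme_end <= self.scheme_start:
            raise ValueError("scheme_end must exceed scheme_start")
        if self.shared_peptides not in ("exclude", "all"):
            raise ValueError("shared_peptides must be 'exclude' or 'all'")


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
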