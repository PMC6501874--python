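"""Run configuration: one YAML file describing a full analysis run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import yaml


@dataclass
class RunConfig:
    """Paths and options for a pipeline run.

    ``alignment`` and ``tree`` are required paths; ``samples`` optionally
    maps gene labels to haplotype FASTA files (the sample manifest);
    ``key_nodes`` lists internal nodes for ancestral reconstruction.
    """

    alignment: str
    tree: str
    samples: dict[str, str] = field(default_factory=dict)
    key_nodes: list[str] = field(default_factory=list)
    frequency_mode: str = "F3x4"
    alpha: float = 0.05
    restarts: int = 3
    seed: int = 0
    out_dir: str = "dupsel_out"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.frequency_mode not in ("equal", "F3x4", "F61"):
            raise ValueError(f"unknown frequency mode {self.frequency_mode!r}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        missing = [p for p in [self.alignment, self.tree, *self.samples.values()]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured paths do not exist: {missing}")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
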