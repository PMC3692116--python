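"""Run configuration: one flat, serializable record of every tunable.

The config is echoed into the commented header of every output file so a
run can be reproduced from its outputs alone. CLI flags override values
loaded from a YAML config file; unset paths stay ``None``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from associnet import __version__


@dataclass
class RunConfig:
    # inputs
    query: str | None = None
    template_net: str | None = None
    template_fasta: str | None = None
    orthologs: str | None = None
    gene_sets: str | None = None
    # ortholog mapping
    score_cutoff: float = 40.0
    overlap_cutoff: float = 0.5
    # transfer
    aggregation: str = "max"
    lls_floor: float = 0.0
    # subnetworks / benchmark
    lls_threshold: float = 0.0
    bin_size: int = 1000
    cumulative: bool = True
    annotation_mode: str = "group"
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.aggregation not in ("max", "sum"):
            raise ValueError(f"aggregation must be 'max' or 'sum', got {self.aggregation!r}")
        if self.lls_floor < 0:
            raise ValueError("lls_floor must be >= 0")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def header_lines(self) -> list[str]:
        """Commented provenance header for output files."""
        lines = [f"associnet version {__version__}"]
        for f in dataclasses.fields(self):
            lines.append(f"config {f.name}={getattr(self, f.name)}")
        return lines
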