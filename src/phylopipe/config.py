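"""Pipeline configuration: every filtering threshold in one audited place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    min_match:        orientation check, minimum locally aligned segment
                      length (strictly exceeded) in nucleotides
    max_templates:    orientation check, templates tried before discarding
    min_species:      smallest retained ortholog-group species count
    overlap:          minimum pairwise aligned overlap (positions) for a
                      clique edge
    alpha:            significance level of the composition chi-square test
    max_gap_fraction: columns with a strictly larger gap fraction are masked
    max_per_genus:    species kept per genus when pruning
    max_per_family:   species re-included per missing family (extended subset)
    """

    min_match: int = 15
    max_templates: int = 4
    min_species: int = 4
    overlap: int = 100
    alpha: float = 0.05
    max_gap_fraction: float = 0.70
    max_per_genus: int = 15
    max_per_family: int = 2
    version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
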