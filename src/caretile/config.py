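"""Pipeline configuration: one YAML-serializable object with every tunable.

Defaults equal the published analysis values where one exists (alpha 0.05,
500 bp merge gap, 400 kb background distance, 25 kb / 5 kb interaction
squares, 250 bp evidence distance, 10x5-fold CV); simulation sizes default
to desk scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # simulated region and screen library
    chrom: str = "chrS"
    region_start: int = 0
    region_end: int = 100_000
    bin_size: int = 100
    guides_per_bin: tuple[int, int] = (2, 3)
    n_controls: int = 200
    days: tuple[float, ...] = (5, 20, 29, 33)
    replicates: int = 2
    depth: float = 2e5
    n_elements: int = 6
    element_bins: int = 3
    planted_slope: float = -0.05
    # single-cell experiment
    n_cells: int = 4000
    n_genes: int = 20
    moi: float = 2.0
    runs: int = 2
    n_links: int = 4
    link_lfc: float = 2.0
    # analysis tunables
    alpha: float = 0.05
    max_gap: int = 500
    window_bins: int = 1
    min_background_distance: int = 400_000
    folds: int = 5
    repeats: int = 10
    capture_half_width: int = 12_500
    catalog_half_width: int = 2_500
    max_dist: int = 250
    seed: int = 0
    # optional external input paths (None -> simulate)
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["guides_per_bin"] = list(self.guides_per_bin)
        d["days"] = list(self.days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "guides_per_bin" in d:
            d["guides_per_bin"] = tuple(d["guides_per_bin"])
        if "days" in d:
            d["days"] = tuple(d["days"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.region_start, self.region_end)
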