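"""Run configuration for the morphometry pipeline.

All tunables that the analysis stages share live here: the physical pixel
size, the P2A class-bin edges, segmentation constants and the NCR
convention. The config round-trips through a flat YAML file so that a run
can be reproduced from its recorded configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Channel names in canonical order: nuclear stain, cytokeratin, leukocyte antigen.
CHANNELS: tuple[str, str, str] = ("dapi", "ck", "cd45")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the pipeline.

    Parameters
    ----------
    pixel_size_um:
        Physical edge length of one pixel in micrometers. Used whenever a
        raster carries no resolution metadata of its own. The default 0.64
        matches CellSearch-style thumbnails where a 6.4 μm scale bar spans
        10 pixels.
    p2a_edges:
        Ascending P2A thresholds ``(t1, t2, t3)`` splitting events into
        single / doublet / small cluster / large cluster.
    min_component_area_um2:
        Smallest connected component (μm²) kept by segmentation; mirrors
        the platform's minimum cytokeratin signal of 4 μm².
    merge_distance_um:
        Components whose distance to the thumbnail center exceeds that of
        the nearest component by more than this margin are treated as
        debris and discarded.
    median_filter_size:
        Edge of the square median filter applied before thresholding.
    ncr_convention:
        ``"area"`` (nucleus/cytoplasm area ratio, the convention that
        reproduces the published cohort values) or ``"diameter"``
        (ratio of equivalent-circle diameters).
    bonferroni:
        Apply a Bonferroni correction to the comparison plan's p-values.
        Off by default; the published analysis used uncorrected pairwise
        tests.
    seed:
        Seed for every stochastic component (synthetic data generation).
    """

    pixel_size_um: float = 0.64
    p2a_edges: tuple[float, float, float] = (1.5, 2.5, 4.0)
    min_component_area_um2: float = 4.0
    merge_distance_um: float = 3.2
    median_filter_size: int = 3
    ncr_convention: str = "area"
    bonferroni: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        t1, t2, t3 = self.p2a_edges
        if not (0 < t1 < t2 < t3):
            raise ValueError(f"p2a_edges must be ascending and positive, got {self.p2a_edges}")
        if self.ncr_convention not in ("area", "diameter"):
            raise ValueError(f"ncr_convention must be 'area' or 'diameter', got {self.ncr_convention!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["p2a_edges"] = list(self.p2a_edges)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "p2a_edges" in data:
            data["p2a_edges"] = tuple(data["p2a_edges"])
        return cls(**data)
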