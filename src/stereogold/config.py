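"""Analysis and plotting configuration.

Every knob of the per-cell analysis is collected here with its conventional
default: volumes are shrunk 4x before geometry, a random tenth of each
tower's border voxels is kept, beads are tied to towers by 10-nearest-
neighbour voting, and a bead farther than 100 um from any surface sample is
excluded (a bound so large it is effectively off at bundle scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "PlotConfig"]


@dataclass
class AnalysisConfig:
    resize_factor: float = 0.25            # volume downsampling before geometry
    border_sampling_factor: float = 0.1    # random fraction of border voxels kept
    association_method: str = "NN"         # 'NN' (k-NN vote) or 'DT' (distance transform)
    n_nearest_neighbors: int = 10          # k for the NN vote
    min_dist_thr_um: float = 100.0         # bead exclusion distance, micrometres
    rng_seed: int = 0                      # border sampling + sign flips
    meanshift_bandwidth_rad: float = 0.3   # angular kernel width on the sphere
    extremity: str = "min"                 # upward rule: std of per-tower min/max projections
    sector_origin: str = "centered"        # sector 1 centered on vs starting at north
    segment_height_um: float = 0.2         # target segment height for density maps

    def __post_init__(self) -> None:
        if not (0 < self.resize_factor <= 1):
            raise ValueError("resize_factor must be in (0, 1]")
        if not (0 < self.border_sampling_factor <= 1):
            raise ValueError("border_sampling_factor must be in (0, 1]")
        if self.association_method not in ("NN", "DT"):
            raise ValueError("association_method must be 'NN' or 'DT'")
        if self.n_nearest_neighbors < 1:
            raise ValueError("n_nearest_neighbors must be >= 1")
        if self.min_dist_thr_um <= 0:
            raise ValueError("min_dist_thr_um must be positive")
        if self.meanshift_bandwidth_rad <= 0:
            raise ValueError("meanshift_bandwidth_rad must be positive")
        if self.extremity not in ("min", "max"):
            raise ValueError("extremity must be 'min' or 'max'")
        if self.sector_origin not in ("centered", "edge"):
            raise ValueError("sector_origin must be 'centered' or 'edge'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlotConfig:
    view_direction: tuple[float, float] = (90.0, 0.0)  # (azimuth, elevation) degrees
    background_color: str = "black"
    gp_marker: str = "*"
    gp_marker_size: float = 1.0
    towers_as_point_clouds: bool = False
    tr_marker_size: float = 1.0
    n_az_bins: int = 4     # radial sectors, counterclockwise from north
    n_ht_bins: int = 5     # height bins incl. the above-tip bin

    def __post_init__(self) -> None:
        if self.n_az_bins < 1:
            raise ValueError("n_az_bins must be >= 1")
        if self.n_ht_bins < 2:
            raise ValueError("n_ht_bins must be >= 2 (incl. the above-tip bin)")
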