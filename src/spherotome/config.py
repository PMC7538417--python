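"""Run configuration: every user-adjustable threshold in one place.

Defaults follow the published pipeline parameters where the source
workflow states them: centroid link distance 2.0 µm, drift limit 3.0 µm,
minimum 5 sections per nucleus, circularity cutoff 0.6, nuclear dilation
0.1 µm, aspect-ratio bounds [0.8, 1.2], watershed separator size 20 px on
the external-import path.  The solidity filter is off by default (curved
cells would be falsely excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # geometry / calibration
    pixel_size_um: float = 0.1071
    nominal_z_spacing_um: float = 0.1
    axial_factor: float = 0.65
    z_shift_per_channel: dict = field(default_factory=dict)
    dark_noise_path: str | None = None
    flatfield_paths: dict = field(default_factory=dict)

    # per-section enhancement
    blur_sigma: float = 1.0
    unsharp_radius: float = 2.0
    unsharp_weight: float = 0.6
    smooth_sigma: float = 1.0

    # nuclear segmentation / grouping
    min_circularity: float = 0.6  # circularity cutoff 4πA/P²
    min_nucleus_area_um2: float = 0.5  # per-section size filter
    dilation_um: float = 0.1  # nuclear ROI dilation
    link_dist: float = 2.0  # µm, centroid linking between sections
    drift_max: float = 3.0  # µm, max centroid drift from chain mean
    min_sections: int = 5  # min 2D ROIs per nucleus
    max_link_gap: int = 1  # missing sections a link may bridge

    # whole-cell segmentation
    sections_above_focus: bool = False
    separator_size: float = 20.0  # px, watershed separator (external path)
    gap_threshold: float = 0.0  # px², smoothing gap fill
    periphery_margin: int = 0  # px
    solidity_filter: bool = False
    min_solidity: float = 0.8
    min_cell_area_px: int = 50
    excluded_region_ids: list = field(default_factory=list)

    # reconstruction
    prune_skeleton: bool = True
    align_midplane_to_nucleus: bool = True

    # downstream filters
    aspect_filter: bool = True
    aspect_bounds: tuple = (0.8, 1.2)
    containment_filter: bool = True

    seed: int = 0

    @property
    def corrected_z_spacing_um(self) -> float:
        return self.nominal_z_spacing_um * self.axial_factor

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.aspect_bounds, list):
            cfg.aspect_bounds = tuple(cfg.aspect_bounds)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["aspect_bounds"] = list(self.aspect_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
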