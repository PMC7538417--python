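"""End-to-end driver: segmentation → reconstruction → pairing → measurement.

The two segmentation tracks run independently — nuclei from the
fluorescence channel (per-section 2D + Z-grouping), whole-cell midplanes
from the brightfield channel (or an imported label mask) — and meet at the
extrusion step: each cell's midplane region is extruded into 3D, by default
re-centered on its paired nucleus's midplane section so nucleus and cell
reconstructions are vertically aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import reassign_midplane, segment_cells
from .config import RunConfig
from .extrusion import RegionStack, extrude_region
from .morphometry import (
    CellRecord,
    measure_pairs,
    pair_nuclei_cells,
    records_to_frame,
)
from .nuclei import NucleusModel, segment_nuclei
from .stack import ImageStack

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    nuclei: list[NucleusModel]
    midplane_regions: list
    focus_index: int
    cell_stacks: list[RegionStack]
    extrusion_failures: list[tuple[int, str]]
    records: list[CellRecord]
    excluded: list[CellRecord]

    @property
    def passing_records(self) -> list[CellRecord]:
        return [r for r in self.records if r.passes_filters]

    def table(self, filtered: bool = False):
        return records_to_frame(self.passing_records if filtered else self.records)


def run_pipeline(
    brightfield: ImageStack,
    nuclear: ImageStack,
    config: RunConfig | None = None,
    external_labels: np.ndarray | None = None,
    signal_channels: dict[str, ImageStack] | None = None,
) -> PipelineResult:
    """Run the full reconstruction and measurement pipeline.

    ``external_labels`` switches the whole-cell track to the imported
    2D-label-mask path (the brightfield stack is then only used for focus
    detection).  ``signal_channels`` are additional corrected fluorescence
    stacks whose intensities are extracted per cell and per nucleus.
    """
    cfg = config or RunConfig()

    nuclei = segment_nuclei(
        nuclear,
        blur_sigma=cfg.blur_sigma,
        unsharp_radius=cfg.unsharp_radius,
        unsharp_weight=cfg.unsharp_weight,
        smooth_sigma=cfg.smooth_sigma,
        min_circularity=cfg.min_circularity,
        min_area_um2=cfg.min_nucleus_area_um2,
        dilation_um=cfg.dilation_um,
        link_dist=cfg.link_dist,
        drift_max=cfg.drift_max,
        min_sections=cfg.min_sections,
        max_link_gap=cfg.max_link_gap,
    )

    regions, focus = segment_cells(
        brightfield,
        blur_sigma=cfg.blur_sigma,
        unsharp_radius=cfg.unsharp_radius,
        unsharp_weight=cfg.unsharp_weight,
        sections_above_focus=cfg.sections_above_focus,
        separator_size=cfg.separator_size if external_labels is not None else -1,
        gap_threshold=cfg.gap_threshold,
        margin=cfg.periphery_margin,
        min_solidity=cfg.min_solidity if cfg.solidity_filter else None,
        min_area=cfg.min_cell_area_px,
        external_labels=external_labels,
    )
    if cfg.excluded_region_ids:
        regions = [
            r for i, r in enumerate(regions) if i not in set(cfg.excluded_region_ids)
        ]
    for i, r in enumerate(regions):
        r.label = i

    # pair midplane regions with nuclei first (on the 2D midplane), so each
    # cell can be extruded from its nucleus's midplane section
    n_z = nuclear.n_sections
    nucleus_by_region: dict[int, NucleusModel] = {}
    counts: dict[int, int] = {i: 0 for i in range(len(regions))}
    for nuc in nuclei:
        x, y = nuc.mean_centroid
        for i, reg in enumerate(regions):
            if reg.contains_point(x, y):
                counts[i] += 1
                nucleus_by_region[i] = nuc
                break

    cell_stacks: list[RegionStack] = []
    failures: list[tuple[int, str]] = []
    for i, reg in enumerate(regions):
        mid = focus
        if cfg.align_midplane_to_nucleus and counts.get(i, 0) == 1:
            mid = reassign_midplane(reg, nucleus_by_region[i].midplane_index, n_z)
        mid = int(np.clip(mid, 0, n_z - 1))
        try:
            stack = extrude_region(
                reg,
                midplane_index=mid,
                n_sections=n_z,
                pixel_size=brightfield.pixel_size,
                z_spacing=brightfield.z_spacing,
                prune=cfg.prune_skeleton,
            )
            stack.cell_id = i
            cell_stacks.append(stack)
        except (ValueError, IndexError) as exc:
            failures.append((i, str(exc)))

    pairs, excluded = pair_nuclei_cells(cell_stacks, nuclei)
    records = measure_pairs(
        pairs,
        channels=signal_channels,
        aspect_bounds=cfg.aspect_bounds,
        apply_aspect_filter=cfg.aspect_filter,
        apply_containment_filter=cfg.containment_filter,
    )
    return PipelineResult(
        nuclei=nuclei,
        midplane_regions=regions,
        focus_index=focus,
        cell_stacks=cell_stacks,
        extrusion_failures=failures,
        records=records,
        excluded=excluded,
    )
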