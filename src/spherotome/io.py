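"""TIFF stack and table I/O plus label-mask rendering."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .extrusion import RegionStack
from .nuclei import NucleusModel
from .stack import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "nuclei_label_stack",
    "cells_label_stack",
    "midplane_label_image",
    "nuclei_table",
    "write_outputs",
]


def read_stack(
    path: str | Path,
    pixel_size: float,
    z_spacing: float,
    channel: int | None = None,
    channel_axis: int | None = None,
) -> ImageStack:
    """Read a TIFF Z-stack (optionally one channel of a multi-channel file).

    Axis order is inferred: 3D arrays are (Z, Y, X); 4D arrays need
    ``channel_axis`` (0 for (C, Z, Y, X), 1 for (Z, C, Y, X)) and a
    ``channel`` index.  Geometry always comes from the caller/config."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        if channel is None or channel_axis is None:
            raise ValueError(
                f"{path}: 4D TIFF needs channel and channel_axis to select one channel"
            )
        if channel >= data.shape[channel_axis]:
            raise ValueError(
                f"{path}: channel {channel} out of range for axis of size "
                f"{data.shape[channel_axis]}"
            )
        data = np.take(data, channel, axis=channel_axis)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a Z-stack, got array of shape {data.shape}")
    return ImageStack(data, pixel_size=pixel_size, z_spacing=z_spacing)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray) -> None:
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    tifffile.imwrite(str(path), np.asarray(data, np.float32))


def nuclei_label_stack(
    nuclei: list[NucleusModel], n_sections: int, frame_shape: tuple[int, int]
) -> np.ndarray:
    """16-bit per-section label masks, one label per nucleus (id + 1)."""
    out = np.zeros((n_sections, *frame_shape), np.uint16)
    for nuc in nuclei:
        for reg in nuc.regions:
            rr, cc = reg.pixels()
            out[reg.section_index][rr, cc] = nuc.nucleus_id + 1
    return out


def cells_label_stack(
    stacks: list[RegionStack], n_sections: int, frame_shape: tuple[int, int]
) -> np.ndarray:
    """16-bit 3D label image of the extruded cells (label = cell_id + 1);
    later cells overwrite earlier ones where reconstructions overlap."""
    out = np.zeros((n_sections, *frame_shape), np.uint16)
    for st in stacks:
        lab = (st.cell_id if st.cell_id is not None else 0) + 1
        for z, reg in st.regions.items():
            rr, cc = reg.pixels()
            out[z][rr, cc] = lab
    return out


def midplane_label_image(regions, frame_shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(frame_shape, np.uint16)
    for i, reg in enumerate(regions):
        rr, cc = reg.pixels()
        out[rr, cc] = (reg.label if reg.label is not None else i) + 1
    return out


def nuclei_table(nuclei: list[NucleusModel]) -> pd.DataFrame:
    rows = []
    for nuc in nuclei:
        x, y = nuc.mean_centroid
        rows.append(
            dict(
                nucleus_id=nuc.nucleus_id,
                midplane_index=nuc.midplane_index,
                centroid_x_px=x,
                centroid_y_px=y,
                n_sections=nuc.n_sections,
                volume_um3=nuc.volume_um3,
                surface_um2=nuc.surface_um2,
                voxel_count=nuc.voxel_count,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id", "midplane_index", "centroid_x_px", "centroid_y_px",
            "n_sections", "volume_um3", "surface_um2", "voxel_count",
        ],
    )


def write_outputs(result, out_dir: str | Path, frame_shape, n_sections, config=None):
    """Write label TIFFs, CSV tables and a JSON run log for a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(out / "midplane_labels.tif"),
        midplane_label_image(result.midplane_regions, frame_shape),
    )
    tifffile.imwrite(
        str(out / "cell_labels.tif"),
        cells_label_stack(result.cell_stacks, n_sections, frame_shape),
    )
    tifffile.imwrite(
        str(out / "nucleus_labels.tif"),
        nuclei_label_stack(result.nuclei, n_sections, frame_shape),
    )
    nuclei_table(result.nuclei).to_csv(out / "nuclei.csv", index=False)
    result.table(filtered=False).to_csv(out / "records.csv", index=False)
    result.table(filtered=True).to_csv(out / "records_filtered.csv", index=False)
    log = {
        "focus_index": result.focus_index,
        "n_nuclei": len(result.nuclei),
        "n_midplane_regions": len(result.midplane_regions),
        "n_cell_stacks": len(result.cell_stacks),
        "n_extrusion_failures": len(result.extrusion_failures),
        "n_records": len(result.records),
        "n_records_passing": len(result.passing_records),
        "exclusions": sorted(
            {flag for rec in result.excluded for flag in rec.filter_flags}
        ),
    }
    if config is not None:
        from dataclasses import asdict

        cfg = asdict(config)
        cfg["aspect_bounds"] = list(cfg["aspect_bounds"])
        log["config"] = cfg
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
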