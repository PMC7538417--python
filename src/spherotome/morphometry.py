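"""Measurements on 3D reconstructions: volumes, surfaces, idealized
geometry, pairing, quality filters, N/C ratio and intensity extraction.

Voxelized quantities come straight from the per-section regions:

    V = Σᵢ Aᵢ · pixel_size² · Z          (Z = axially corrected spacing)
    S = (Σᵢ Pᵢ · Z) + 2·A_midplane       (staircase surface)

Idealized geometry treats a cell as a cylinder with hemispherical caps
(rod) and a nucleus as a prolate ellipsoid, with length L and width W read
from the midplane region either by rotating-calipers Feret diameters or by
the area-preserving moment ellipse:

    V_rod      = hπr² + (4/3)πr³,  r = W/2, h = L − 2r
    S_rod      = 2hπr + 4πr²
    V_ellipsoid = (4/3)πab²,       a = L/2, b = W/2
    S_ellipsoid ≈ 4π((a²ᴾ + 2aᴾbᴾ)/3)^(1/P),  P = 1.6075
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extrusion import RegionStack
from .nuclei import NucleusModel
from .stack import ImageStack

__all__ = [
    "IdealizedRod",
    "IdealizedEllipsoid",
    "CellRecord",
    "stack_volume",
    "stack_surface",
    "feret_dims",
    "ellipse_dims",
    "rod_volume",
    "rod_surface",
    "ellipsoid_volume",
    "ellipsoid_surface",
    "pair_nuclei_cells",
    "aspect_ratio",
    "nucleus_within_cell",
    "stack_intensity",
    "nc_ratio",
    "measure_pairs",
    "records_to_frame",
    "apply_filters",
]

ELLIPSOID_SURFACE_P = 1.6075


# ---------------------------------------------------------------------------
# idealized shapes
# ---------------------------------------------------------------------------


@dataclass
class IdealizedRod:
    """Cylinder of length h = L − W with hemispherical caps of radius W/2."""

    L: float  # µm
    W: float  # µm
    method: str = "feret"  # "feret" | "ellipse-fit"

    def __post_init__(self) -> None:
        if not (self.L >= self.W > 0):
            raise ValueError(f"rod needs L >= W > 0; got L={self.L}, W={self.W}")

    @property
    def r(self) -> float:
        return self.W / 2

    @property
    def h(self) -> float:
        return self.L - self.W


@dataclass
class IdealizedEllipsoid:
    """Prolate spheroid with semi-axes a = L/2 and b = W/2."""

    L: float  # µm
    W: float  # µm
    P: float = ELLIPSOID_SURFACE_P

    def __post_init__(self) -> None:
        if not (self.L >= self.W > 0):
            raise ValueError(f"ellipsoid needs L >= W > 0; got L={self.L}, W={self.W}")

    @property
    def a(self) -> float:
        return self.L / 2

    @property
    def b(self) -> float:
        return self.W / 2


def rod_volume(rod: IdealizedRod) -> float:
    """V = hπr² + (4/3)πr³; reduces to a sphere when L = W."""
    return rod.h * np.pi * rod.r**2 + (4 / 3) * np.pi * rod.r**3


def rod_surface(rod: IdealizedRod) -> float:
    """S = 2hπr + 4πr² (lateral cylinder face + two hemispheric caps)."""
    return 2 * rod.h * np.pi * rod.r + 4 * np.pi * rod.r**2


def ellipsoid_volume(e: IdealizedEllipsoid) -> float:
    """V = (4/3)πab²."""
    return (4 / 3) * np.pi * e.a * e.b**2


def ellipsoid_surface(e: IdealizedEllipsoid) -> float:
    """Thomsen's approximation for a prolate spheroid (semi-axes a, b, b):

        S ≈ 4π((2(ab)ᴾ + b²ᴾ)/3)^(1/P),  P = 1.6075

    Exactly 4πa² at a = b; within ~1.2% of the closed-form prolate surface
    for moderate elongation."""
    a, b, P = e.a, e.b, e.P
    return 4 * np.pi * ((2 * (a * b) ** P + b ** (2 * P)) / 3) ** (1 / P)


# ---------------------------------------------------------------------------
# voxelized measurements
# ---------------------------------------------------------------------------


def stack_volume(stack: RegionStack) -> float:
    """Σ area·pixel_size²·z_spacing over all sections, in µm³."""
    if stack.n_sections == 0:
        raise ValueError("empty region stack")
    return stack.voxel_count * stack.pixel_size**2 * stack.z_spacing


def stack_surface(stack: RegionStack) -> float:
    """Staircase surface S = (Σ Pᵢ·Z) + 2A in µm², with corner-corrected
    perimeters and A the midplane region area."""
    if stack.n_sections == 0:
        raise ValueError("empty region stack")
    px = stack.pixel_size
    perim_sum = sum(r.perimeter for r in stack.regions.values()) * px
    mid_area = stack.midplane_region.area * px**2
    return perim_sum * stack.z_spacing + 2 * mid_area


def feret_dims(region, pixel_size: float = 1.0) -> tuple[float, float]:
    """(L, W) = (max, min) caliper diameter of the region, µm."""
    fmax, fmin = region.feret_diameters()
    return fmax * pixel_size, fmin * pixel_size


def ellipse_dims(region, pixel_size: float = 1.0) -> tuple[float, float]:
    """(L, W) = (major, minor) diameter of the area-preserving moment
    ellipse, µm."""
    L, W = region.ellipse_diameters()
    return L * pixel_size, W * pixel_size


def aspect_ratio(stack: RegionStack, kind: str = "cell") -> float:
    """Z extent over XY reference extent.

    The reference is the minimum Feret diameter (cell width) for cells —
    a radially symmetric cell's Z extent tracks its width — and the
    maximum midplane diameter for nuclei.  Ratios below ~0.8 flag
    reconstructions truncated by the acquisition range; above ~1.2,
    over-segmented ones."""
    if stack.n_sections == 0:
        raise ValueError("empty region stack")
    z_extent = stack.n_sections * stack.z_spacing
    fmax, fmin = stack.midplane_region.feret_diameters()
    ref = (fmin if kind == "cell" else fmax) * stack.pixel_size
    return z_extent / ref


def nucleus_aspect_ratio(nucleus: NucleusModel) -> float:
    z_extent = nucleus.n_sections * nucleus.z_spacing
    return z_extent / nucleus.max_diameter_um


def nucleus_within_cell(cell: RegionStack, nucleus: NucleusModel) -> bool:
    """True iff every nuclear pixel lies inside the cell's 3D ROI
    (shared-boundary pixels count as inside)."""
    frame = cell.midplane_region.frame_shape
    for reg in nucleus.regions:
        z = reg.section_index
        if z not in cell.regions:
            return False
        cell_mask = cell.regions[z].full_mask(frame)
        rr, cc = reg.pixels()
        inside = (
            (rr >= 0)
            & (cc >= 0)
            & (rr < frame[0])
            & (cc < frame[1])
        )
        if not inside.all() or not cell_mask[rr, cc].all():
            return False
    return True


def stack_intensity(
    stack: RegionStack, channel: ImageStack
) -> tuple[float, float]:
    """(integrated density, mean intensity) of a channel inside a 3D ROI.

    Integrated density is the raw sum of voxel intensities over every
    section's region; mean intensity divides it by the ROI volume in µm³
    (the voxel count is available as ``stack.voxel_count`` for the
    per-voxel convention)."""
    if channel.frame_shape != stack.midplane_region.frame_shape:
        raise ValueError("channel frame does not match the region stack frame")
    total = 0.0
    for z, reg in stack.regions.items():
        if not (0 <= z < channel.n_sections):
            raise ValueError(f"stack section {z} outside channel Z range")
        rr, cc = reg.pixels()
        total += float(channel.data[z][rr, cc].sum())
    return total, total / stack_volume(stack)


def nucleus_intensity(
    nucleus: NucleusModel, channel: ImageStack
) -> tuple[float, float]:
    total = 0.0
    for reg in nucleus.regions:
        rr, cc = reg.pixels()
        total += float(channel.data[reg.section_index][rr, cc].sum())
    return total, total / nucleus.volume_um3


# ---------------------------------------------------------------------------
# pairing and records
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """One paired whole-cell + nucleus measurement row."""

    cell_id: int
    nucleus_id: int | None = None
    cell_volume_um3: float = np.nan
    cell_surface_um2: float = np.nan
    cell_voxels: int = 0
    nucleus_volume_um3: float = np.nan
    nucleus_surface_um2: float = np.nan
    nucleus_voxels: int = 0
    length_feret_um: float = np.nan
    width_feret_um: float = np.nan
    length_ellipse_um: float = np.nan
    width_ellipse_um: float = np.nan
    rod_volume_feret_um3: float = np.nan
    rod_volume_ellipse_um3: float = np.nan
    rod_surface_feret_um2: float = np.nan
    nucleus_L_um: float = np.nan
    nucleus_W_um: float = np.nan
    ellipsoid_volume_um3: float = np.nan
    ellipsoid_surface_um2: float = np.nan
    solidity: float = np.nan
    aspect_ratio_cell: float = np.nan
    aspect_ratio_nucleus: float = np.nan
    nc_ratio: float = np.nan
    intensities: dict = field(default_factory=dict)
    filter_flags: list = field(default_factory=list)

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


def nc_ratio(nucleus_volume: float, cell_volume: float) -> float:
    """Nuclear-to-cell volume ratio."""
    if nucleus_volume <= 0 or cell_volume <= 0:
        raise ValueError("N/C ratio needs positive nuclear and cell volumes")
    return nucleus_volume / cell_volume


def pair_nuclei_cells(
    cells: list[RegionStack], nuclei: list[NucleusModel]
) -> tuple[list[tuple[RegionStack, NucleusModel]], list[CellRecord]]:
    """1:1 pairing by nuclear-centroid containment.

    Each nucleus's mean XY centroid is tested against every cell's midplane
    region.  Cells containing zero nuclei (background or failed nuclear
    segmentation) or two and more (septating cells, poor segmentation) are
    excluded, as are nuclei falling in no cell; exclusions come back as
    flagged records."""
    assignments: dict[int, list[int]] = {i: [] for i in range(len(cells))}
    orphan_nuclei: list[int] = []
    for ni, nuc in enumerate(nuclei):
        x, y = nuc.mean_centroid
        hosts = [
            ci for ci, cell in enumerate(cells)
            if cell.midplane_region.contains_point(x, y)
        ]
        if hosts:
            # a nucleus belongs to the (rare) innermost cell if several overlap
            assignments[hosts[0]].append(ni)
        else:
            orphan_nuclei.append(ni)

    pairs: list[tuple[RegionStack, NucleusModel]] = []
    excluded: list[CellRecord] = []
    for ci, cell in enumerate(cells):
        cid = cell.cell_id if cell.cell_id is not None else ci
        hosted = assignments[ci]
        if len(hosted) == 1:
            pairs.append((cell, nuclei[hosted[0]]))
        elif len(hosted) == 0:
            excluded.append(CellRecord(cell_id=cid, filter_flags=["anucleate"]))
        else:
            excluded.append(CellRecord(cell_id=cid, filter_flags=["multinucleate"]))
    for ni in orphan_nuclei:
        excluded.append(
            CellRecord(cell_id=-1, nucleus_id=nuclei[ni].nucleus_id,
                       filter_flags=["nucleus_without_cell"])
        )
    return pairs, excluded


def measure_pairs(
    pairs: list[tuple[RegionStack, NucleusModel]],
    channels: dict[str, ImageStack] | None = None,
    aspect_bounds: tuple[float, float] = (0.8, 1.2),
    apply_aspect_filter: bool = True,
    apply_containment_filter: bool = True,
) -> list[CellRecord]:
    """Compute the full measurement row for each 1:1 cell/nucleus pair.

    Filters only *flag* records (machine-readable reasons in
    ``filter_flags``); :func:`apply_filters` or the record's
    ``passes_filters`` does the exclusion."""
    records: list[CellRecord] = []
    for cell, nuc in pairs:
        px = cell.pixel_size
        mid = cell.midplane_region
        Lf, Wf = feret_dims(mid, px)
        try:
            Le, We = ellipse_dims(mid, px)
        except ValueError:
            Le = We = np.nan
        nmid = nuc.midplane_region
        nLf, nWf = feret_dims(nmid, nuc.pixel_size)
        rec = CellRecord(
            cell_id=cell.cell_id if cell.cell_id is not None else -1,
            nucleus_id=nuc.nucleus_id,
            cell_volume_um3=stack_volume(cell),
            cell_surface_um2=stack_surface(cell),
            cell_voxels=cell.voxel_count,
            nucleus_volume_um3=nuc.volume_um3,
            nucleus_surface_um2=nuc.surface_um2,
            nucleus_voxels=nuc.voxel_count,
            length_feret_um=Lf,
            width_feret_um=Wf,
            length_ellipse_um=Le,
            width_ellipse_um=We,
            nucleus_L_um=nLf,
            nucleus_W_um=nWf,
            solidity=mid.solidity,
            aspect_ratio_cell=aspect_ratio(cell, kind="cell"),
            aspect_ratio_nucleus=nucleus_aspect_ratio(nuc),
        )
        if Lf >= Wf > 0:
            rod_f = IdealizedRod(Lf, Wf, method="feret")
            rec.rod_volume_feret_um3 = rod_volume(rod_f)
            rec.rod_surface_feret_um2 = rod_surface(rod_f)
        if np.isfinite(Le) and Le >= We > 0:
            rec.rod_volume_ellipse_um3 = rod_volume(
                IdealizedRod(Le, We, method="ellipse-fit")
            )
        if nLf >= nWf > 0:
            ell = IdealizedEllipsoid(nLf, nWf)
            rec.ellipsoid_volume_um3 = ellipsoid_volume(ell)
            rec.ellipsoid_surface_um2 = ellipsoid_surface(ell)
        rec.nc_ratio = nc_ratio(rec.nucleus_volume_um3, rec.cell_volume_um3)
        for name, ch in (channels or {}).items():
            ci, cm = stack_intensity(cell, ch)
            nci, ncm = nucleus_intensity(nuc, ch)
            rec.intensities[name] = {
                "cell_integrated": ci,
                "cell_mean_per_um3": cm,
                "nucleus_integrated": nci,
                "nucleus_mean_per_um3": ncm,
            }
        lo, hi = aspect_bounds
        if apply_aspect_filter:
            if not (lo <= rec.aspect_ratio_cell <= hi):
                rec.filter_flags.append("cell_aspect_ratio")
            if not (lo <= rec.aspect_ratio_nucleus <= hi):
                rec.filter_flags.append("nucleus_aspect_ratio")
        if apply_containment_filter and not nucleus_within_cell(cell, nuc):
            rec.filter_flags.append("nucleus_outside_cell")
        records.append(rec)
    return records


def apply_filters(records: list[CellRecord]) -> list[CellRecord]:
    """Records with no filter flags."""
    return [r for r in records if r.passes_filters]


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten records (intensity dicts become per-channel columns)."""
    rows = []
    for r in records:
        row = {
            k: v
            for k, v in r.__dict__.items()
            if k not in ("intensities", "filter_flags")
        }
        for ch, vals in r.intensities.items():
            for key, v in vals.items():
                row[f"{ch}_{key}"] = v
        row["filter_flags"] = ";".join(r.filter_flags)
        rows.append(row)
    cols = None
    if not rows:  # empty-but-valid table with headers
        cols = [f.name for f in CellRecord.__dataclass_fields__.values()
                if f.name not in ("intensities",)]
    return pd.DataFrame(rows, columns=cols)
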