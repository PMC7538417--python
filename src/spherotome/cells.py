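"""Whole-cell 2D midplane segmentation from brightfield Z-stacks.

In defocused brightfield sections every cell is surrounded by a dark
boundary band whose width grows with distance from the focal plane and
vanishes at focus.  The segmentation exploits this: take the sections below
the most in-focus section (the one with minimal intensity standard
deviation), enhance and Otsu-binarize each, and average the binaries.  The
averaged map shows boundary bands as valleys; a second Otsu threshold turns
them into a closed band around each cell.  Components enclosed by bands are
candidate cells; because the band straddles the true outline, each region
is finally enlarged by the measured band half-width.

Externally produced 2D label masks (e.g. from a CNN segmenter) can be
imported instead and run through the same optional post-processing chain
(watershed splitting, gap smoothing, periphery margin, solidity filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max

from .nuclei import binarize_otsu, enhance_sections
from .regions import PlanarRegion, regions_from_binary, regions_from_labels
from .stack import ImageStack

__all__ = [
    "BoundaryMap",
    "find_focus",
    "boundary_map",
    "initial_regions",
    "split_touching",
    "smooth_fill",
    "exclude_periphery",
    "import_external_midplanes",
    "reassign_midplane",
    "segment_cells",
]


@dataclass
class BoundaryMap:
    """Mean of the per-section binaries below focus; bands appear as valleys."""

    grid: np.ndarray  # 2D, values in [0, 1]
    focus_index: int
    band_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("boundary map values must lie in [0, 1]")
        if self.band_halfwidth < 0:
            raise ValueError("band_halfwidth must be non-negative")


def find_focus(stack: ImageStack) -> int:
    """Most in-focus section = argmin of per-section intensity standard
    deviation (the boundary bands vanish at focus, so contrast is minimal).
    Ties break toward the lower index."""
    if stack.n_sections < 2:
        import warnings

        warnings.warn("single-section stack: focus defaults to section 0")
        return 0
    stds = stack.data.reshape(stack.n_sections, -1).std(axis=1)
    return int(np.argmin(stds))


def boundary_map(
    stack: ImageStack,
    focus: int,
    blur_sigma: float = 1.0,
    unsharp_radius: float = 2.0,
    unsharp_weight: float = 0.6,
    sections_above_focus: bool = False,
) -> BoundaryMap:
    """Average the enhanced, Otsu-binarized sections on one side of focus.

    By default the sections strictly *below* the focus index are used
    (acquisition with index increasing upward); ``sections_above_focus``
    flips the direction for the opposite convention.
    """
    if sections_above_focus:
        idx = list(range(focus + 1, stack.n_sections))
    else:
        idx = list(range(0, focus))
    if not idx:
        raise ValueError(
            "no sections on the chosen side of focus; check stack orientation "
            "(sections_above_focus flag) or focus detection"
        )
    sub = stack.with_data(stack.data[idx])
    enhanced = enhance_sections(sub, blur_sigma, unsharp_radius, unsharp_weight)
    acc = np.zeros(stack.frame_shape, float)
    for i in range(enhanced.n_sections):
        acc += binarize_otsu(enhanced.data[i])
    return BoundaryMap(grid=acc / len(idx), focus_index=focus)


def initial_regions(
    bmap: BoundaryMap, min_area: int = 50
) -> tuple[list[PlanarRegion], float]:
    """Candidate cell regions from the boundary map.

    Otsu-binarize the averaged map; pixels below threshold form the band
    mask.  Connected components *enclosed* by bands (not reaching the image
    border through non-band pixels) are candidate cells.  The band
    half-width is the median of the band-mask distance transform sampled on
    the band's medial axis, and every region is dilated by that half-width
    (sub-pixel, not rounded) so the outline lands back on the true cell
    edge.
    """
    grid = bmap.grid
    if grid.min() == grid.max():
        return [], 0.0
    from skimage.filters import threshold_otsu

    band = grid <= threshold_otsu(grid)
    if not band.any() or band.all():
        return [], 0.0
    # components of the non-band area; the one(s) touching the border are
    # background, the enclosed ones are cell interiors
    labels = measure.label(~band, connectivity=1)
    border_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    interior = labels.copy()
    for lab in border_labels:
        interior[interior == lab] = 0
    # band half-width: distance transform of the band, sampled on its skeleton
    edt = ndimage.distance_transform_edt(band)
    skel = morphology.skeletonize(band)
    halfwidth = float(np.median(edt[skel])) if skel.any() else 0.0
    regions = [
        r.dilate(halfwidth)
        for r in regions_from_labels(interior)
        if r.area >= min_area
    ]
    bmap.band_halfwidth = halfwidth
    return regions, halfwidth


def split_touching(mask: np.ndarray, separator_size: float = 20) -> np.ndarray:
    """Distance-transform watershed that cuts necks between touching cells.

    Watershed lines longer than ``separator_size`` pixels are *not*
    applied: a long cut would split a genuinely continuous region rather
    than a narrow neck.  A negative ``separator_size`` disables the step.
    """
    mask = np.asarray(mask, bool)
    if separator_size < 0 or not mask.any():
        return mask
    edt = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        edt, labels=mask, min_distance=3, exclude_border=False
    )
    markers = np.zeros(mask.shape, int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    markers, _ = ndimage.label(
        ndimage.binary_dilation(markers > 0, iterations=2), structure=np.ones((3, 3))
    )
    if markers.max() < 2:
        return mask
    ws = segmentation.watershed(-edt, markers, mask=mask, watershed_line=True)
    lines = mask & (ws == 0)
    if not lines.any():
        return mask
    out = mask.copy()
    line_labels, n = ndimage.label(lines, structure=np.ones((3, 3)))
    for lab in range(1, n + 1):
        seg = line_labels == lab
        if seg.sum() <= separator_size:
            out[seg] = False
    return out


def smooth_fill(region: PlanarRegion, gap_threshold: float) -> PlanarRegion:
    """Fill interior holes and boundary notches smaller than ``gap_threshold``
    (px²); larger gaps are genuine features and stay untouched.
    A threshold of 0 is the identity."""
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be non-negative")
    if gap_threshold == 0:
        return region
    radius = int(np.ceil(np.sqrt(gap_threshold)))
    pad = radius + 1
    mask = np.pad(region.mask, pad)
    closed = morphology.closing(mask, morphology.disk(radius))
    filled = ndimage.binary_fill_holes(closed)
    added_labels, n = ndimage.label(filled & ~mask, structure=np.ones((3, 3)))
    out = mask.copy()
    for lab in range(1, n + 1):
        piece = added_labels == lab
        if piece.sum() < gap_threshold:
            out |= piece
    return PlanarRegion(
        out,
        origin=(region.origin[0] - pad, region.origin[1] - pad),
        section_index=region.section_index,
        frame_shape=region.frame_shape,
        label=region.label,
    )


def exclude_periphery(
    regions: list[PlanarRegion], margin: int, image_shape: tuple[int, int]
) -> list[PlanarRegion]:
    """Drop regions with any pixel within ``margin`` of the image edge."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin == 0:
        return list(regions)
    kept = []
    for r in regions:
        r0, c0, r1, c1 = r.bbox
        if (
            r0 >= margin
            and c0 >= margin
            and r1 <= image_shape[0] - margin
            and c1 <= image_shape[1] - margin
        ):
            kept.append(r)
    return kept


def import_external_midplanes(label_image: np.ndarray) -> list[PlanarRegion]:
    """One region per positive label of an externally produced 2D mask
    (e.g. a CNN segmenter's output); 0 is background."""
    return regions_from_labels(label_image)


def reassign_midplane(region: PlanarRegion, nucleus_mid_z: int, n_sections: int) -> int:
    """Validate and return the extrusion midplane index for a cell region,
    re-assigned to the paired nucleus's midplane section."""
    if not (0 <= nucleus_mid_z < n_sections):
        raise ValueError(
            f"midplane section {nucleus_mid_z} outside stack range [0, {n_sections})"
        )
    return int(nucleus_mid_z)


def segment_cells(
    stack: ImageStack,
    blur_sigma: float = 1.0,
    unsharp_radius: float = 2.0,
    unsharp_weight: float = 0.6,
    sections_above_focus: bool = False,
    separator_size: float = -1,
    gap_threshold: float = 0.0,
    margin: int = 0,
    min_solidity: float | None = None,
    min_area: int = 50,
    external_labels: np.ndarray | None = None,
) -> tuple[list[PlanarRegion], int]:
    """Full whole-cell 2D track; returns (midplane regions, focus index).

    With ``external_labels`` the brightfield track is skipped and the
    label-mask import path is used; the focus index is still estimated from
    the stack so that extrusion has a default midplane.
    """
    focus = find_focus(stack)
    if external_labels is not None:
        regions = import_external_midplanes(external_labels)
    else:
        bmap = boundary_map(
            stack, focus, blur_sigma, unsharp_radius, unsharp_weight,
            sections_above_focus=sections_above_focus,
        )
        regions, _ = initial_regions(bmap, min_area=min_area)
    if separator_size >= 0 and regions:
        frame = stack.frame_shape
        merged = np.zeros(frame, bool)
        for r in regions:
            merged |= r.full_mask(frame)
        regions = regions_from_binary(split_touching(merged, separator_size))
    if gap_threshold > 0:
        regions = [smooth_fill(r, gap_threshold) for r in regions]
    if margin > 0:
        regions = exclude_periphery(regions, margin, stack.frame_shape)
    if min_solidity is not None:
        regions = [r for r in regions if r.area >= 3 and r.solidity >= min_solidity]
    regions = [r for r in regions if r.area >= min_area]
    return regions, focus
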