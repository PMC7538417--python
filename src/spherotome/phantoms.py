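"""Synthetic microscopy phantoms with known ground truth.

Every pipeline stage is testable without real microscopy data: the
generator builds analytic cell bodies (capsules — straight, bent or
tapered — and spheres) with interior ellipsoidal nuclei, renders a
brightfield-like channel and a nuclear-marker channel, and reports the
closed-form volumes alongside.

The brightfield model is geometric, not optical: each optical section
shows a dark boundary band centered on the cell outline whose width grows
linearly with distance from the focal plane and vanishes at focus, over a
bright background with Gaussian camera noise — exactly the feature the
whole-cell segmentation keys on.  The nuclear channel is a bright
ellipsoid with a dimmer interior nucleolar sphere over a dark background.

Default geometry follows a typical high-resolution widefield acquisition
of fission yeast: 0.1071 µm pixels and 0.065 µm corrected section spacing,
cells lying in a flat layer with the focal plane slightly above their
midplane.  Strain presets emulate wild-type rods, short and long size
mutants, and bent-cell shape mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .stack import ImageStack

__all__ = [
    "PhantomSpec",
    "SceneGeometry",
    "truth_voxels",
    "render_brightfield",
    "render_nucleus_channel",
    "make_scene",
    "STRAIN_PRESETS",
]

DEFAULT_PIXEL_SIZE = 0.1071  # µm
DEFAULT_Z_SPACING = 0.065  # µm (axially corrected)

# length and width ranges (µm) emulating wild type and the classic size /
# shape mutants: short ~ temperature-sensitive wee mutants, long ~ cdc
# arrest mutants, bent ~ polarity mutants
STRAIN_PRESETS = {
    "wt": dict(length=(8.0, 13.0), width=(3.9, 4.3), bend=(0.0, 0.0)),
    "short": dict(length=(5.0, 7.5), width=(3.9, 4.3), bend=(0.0, 0.0)),
    "long": dict(length=(18.0, 26.0), width=(4.0, 4.4), bend=(0.0, 0.0)),
    "bent": dict(length=(8.0, 13.0), width=(3.9, 4.3), bend=(25.0, 55.0)),
}


@dataclass
class SceneGeometry:
    """Stack geometry shared by all phantoms of one scene."""

    frame_shape: tuple[int, int] = (640, 640)
    n_sections: int = 48
    pixel_size: float = DEFAULT_PIXEL_SIZE
    z_spacing: float = DEFAULT_Z_SPACING
    midplane_section: int = 24
    focus_section: int = 32


@dataclass
class PhantomSpec:
    """Analytic description of one cell body plus its nucleus.

    The cell axis lies flat in the plane of ``center_um[2]``; a straight
    capsule's axis is a segment of length L − W, a bent capsule's a
    circular arc of the same length turning ``bend_angle_deg`` in total
    (so straight and bent cells of equal L and W have equal volume, by
    Pappus).  A tapered capsule's radius shrinks linearly from W/2 to
    ``taper_ratio``·W/2 along the axis.
    """

    shape: str = "straight-capsule"  # | bent-capsule | tapered-capsule | sphere
    length_um: float = 10.0
    width_um: float = 4.0
    bend_angle_deg: float = 0.0
    taper_ratio: float = 1.0
    orientation_deg: float = 0.0
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)
    nucleus_axes_um: tuple[float, float] | None = None  # (2a, 2b) diameters
    nucleus_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nucleolus_ratio: float = 0.4  # nucleolar radius / nuclear minor semi-axis

    def __post_init__(self) -> None:
        if self.shape == "sphere":
            self.length_um = self.width_um
        if self.width_um > self.length_um:
            raise ValueError("width must not exceed length")

    # -- axis geometry ------------------------------------------------------

    @property
    def axis_length_um(self) -> float:
        """Arc length of the central axis (h = L − W); 0 for spheres."""
        return max(self.length_um - self.width_um, 0.0)

    def axis_points_um(self, step_um: float = 0.02) -> np.ndarray:
        """Dense (x, y) samples of the central axis, µm, scene coordinates."""
        h = self.axis_length_um
        cx, cy = self.center_um[0], self.center_um[1]
        if h == 0:
            return np.array([[cx, cy]])
        n = max(int(np.ceil(h / step_um)), 2)
        s = np.linspace(-h / 2, h / 2, n)
        phi = np.deg2rad(self.bend_angle_deg)
        if self.shape == "bent-capsule" and phi > 0:
            rho = h / phi  # arc radius
            ang = s / rho
            x = rho * np.sin(ang)
            y = rho * (1 - np.cos(ang))
            y -= y.mean()  # re-center the sagitta
        else:
            x, y = s, np.zeros_like(s)
        th = np.deg2rad(self.orientation_deg)
        xr = x * np.cos(th) - y * np.sin(th) + cx
        yr = x * np.sin(th) + y * np.cos(th) + cy
        return np.column_stack([xr, yr])

    def radii_um(self, n: int) -> np.ndarray:
        """Local radius at each of n axis samples (constant unless tapered)."""
        r = self.width_um / 2
        if self.shape == "tapered-capsule" and self.taper_ratio != 1.0:
            return np.linspace(r, r * self.taper_ratio, n)
        return np.full(n, r)

    # -- analytic volumes ---------------------------------------------------

    @property
    def volume_um3(self) -> float:
        """Closed-form cell volume.

        Straight and bent capsules: hπr² + (4/3)πr³ (Pappus for the bent
        arc, exact while the arc radius exceeds r).  Tapered capsules:
        numeric integral of πr(s)² plus the two hemispherical caps."""
        r = self.width_um / 2
        h = self.axis_length_um
        if self.shape == "tapered-capsule" and self.taper_ratio != 1.0:
            s = np.linspace(0, h, 2001)
            rad = np.interp(s, [0, h], [r, r * self.taper_ratio])
            tube = np.trapezoid(np.pi * rad**2, s)
            caps = (2 / 3) * np.pi * (r**3 + (r * self.taper_ratio) ** 3)
            return float(tube + caps)
        return float(h * np.pi * r**2 + (4 / 3) * np.pi * r**3)

    def nucleus_semi_axes_um(self) -> tuple[float, float] | None:
        if self.nucleus_axes_um is None:
            return None
        return self.nucleus_axes_um[0] / 2, self.nucleus_axes_um[1] / 2

    @property
    def nucleus_volume_um3(self) -> float:
        ax = self.nucleus_semi_axes_um()
        if ax is None:
            return 0.0
        a, b = ax
        return float((4 / 3) * np.pi * a * b**2)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _axis_distance_um(
    spec: PhantomSpec, geom: SceneGeometry
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """(distance-to-axis, local radius) per pixel over the spec's XY
    bounding box, in µm; plus the box slices."""
    pts = spec.axis_points_um()
    radii = spec.radii_um(len(pts))
    px = geom.pixel_size
    rmax = spec.width_um / 2 + 2 * px
    x0 = max(int((pts[:, 0].min() - rmax) / px), 0)
    x1 = min(int((pts[:, 0].max() + rmax) / px) + 2, geom.frame_shape[1])
    y0 = max(int((pts[:, 1].min() - rmax) / px), 0)
    y1 = min(int((pts[:, 1].max() + rmax) / px) + 2, geom.frame_shape[0])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    q = np.column_stack([(xx.ravel() + 0.0) * px, (yy.ravel() + 0.0) * px])
    tree = cKDTree(pts)
    dist, idx = tree.query(q)
    return (
        dist.reshape(yy.shape),
        radii[idx].reshape(yy.shape),
        (slice(y0, y1), slice(x0, x1)),
    )


def truth_voxels(
    spec: PhantomSpec, geom: SceneGeometry
) -> tuple[np.ndarray, float]:
    """Voxelize the analytic solid; returns (3D mask, closed-form volume µm³).

    A voxel center (x, y, z) belongs to the body when its XY distance d to
    the central axis and its axial offset dz from the cell plane satisfy
    d² + dz² ≤ r², with r the local axis radius."""
    dist, radius, box = _axis_distance_um(spec, geom)
    if box[0].start >= box[0].stop or box[1].start >= box[1].stop:
        raise ValueError("phantom lies outside the scene frame")
    z0 = spec.center_um[2]
    mask = np.zeros((geom.n_sections,) + geom.frame_shape, bool)
    r2 = radius**2 - dist**2
    touched = False
    for k in range(geom.n_sections):
        dz = k * geom.z_spacing - z0
        sec = r2 >= dz * dz
        if sec.any():
            mask[k][box] = sec
            touched = True
    zmax = z0 + spec.width_um / 2
    zmin = z0 - spec.width_um / 2
    if not touched or zmin < -geom.z_spacing or zmax > geom.n_sections * geom.z_spacing:
        raise ValueError("phantom does not fit the stack Z range")
    return mask, spec.volume_um3


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_brightfield(
    truth: np.ndarray,
    focus_index: int,
    band_width_slope: float = 0.8,
    contrast: float = 600.0,
    noise_sd: float = 15.0,
    seed: int | np.random.Generator = 0,
    background: float = 1000.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    z_spacing: float = DEFAULT_Z_SPACING,
) -> ImageStack:
    """Brightfield-like stack from a 3D truth mask.

    At section k a dark band of width ``band_width_slope·|k − focus_index|``
    pixels is drawn centered on the cells' midplane outline over a bright
    background, plus seeded Gaussian noise; at focus the band width is zero
    and the section is featureless (maximal uniformity, so min-std focus
    detection recovers ``focus_index``)."""
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth, bool)
    n_z = truth.shape[0]
    areas = truth.reshape(n_z, -1).sum(axis=1)
    out = np.empty(truth.shape, float)
    if areas.max() == 0:
        out[:] = background
    else:
        footprint = truth[int(np.argmax(areas))]
        outline = footprint & ~ndimage.binary_erosion(footprint)
        # distance of every pixel to the midplane outline, both sides
        dist = ndimage.distance_transform_edt(~outline)
        for k in range(n_z):
            halfwidth = band_width_slope * abs(k - focus_index) / 2.0
            if halfwidth <= 0:
                out[k] = background  # at focus the band vanishes entirely
                continue
            # sub-pixel-wide bands render as partial-coverage darkening of
            # the outline pixels, so contrast decays smoothly to 0 at focus
            depth = contrast * min(1.0, 2.0 * halfwidth)
            out[k] = background - depth * (dist <= max(halfwidth, 0.5))
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, out.shape)
    return ImageStack(out, pixel_size=pixel_size, z_spacing=z_spacing)


def render_nucleus_channel(
    specs: PhantomSpec | list[PhantomSpec],
    geom: SceneGeometry,
    nucleolar_dim_factor: float = 0.7,
    noise_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
    background: float = 100.0,
    amplitude: float = 1900.0,
) -> ImageStack:
    """Nuclear-marker stack: a bright ellipsoid per nucleus with a dimmer
    interior nucleolar sphere (signal ``amplitude·nucleolar_dim_factor``),
    over a dark background, plus seeded Gaussian noise."""
    if isinstance(specs, PhantomSpec):
        specs = [specs]
    rng = np.random.default_rng(seed)
    out = np.full((geom.n_sections,) + geom.frame_shape, background, float)
    px = geom.pixel_size
    for spec in specs:
        ax = spec.nucleus_semi_axes_um()
        if ax is None:
            continue
        a, b = ax
        ncx = spec.center_um[0] + spec.nucleus_offset_um[0]
        ncy = spec.center_um[1] + spec.nucleus_offset_um[1]
        ncz = spec.center_um[2] + spec.nucleus_offset_um[2]
        th = np.deg2rad(spec.orientation_deg)  # long axis along the cell
        x0 = max(int((ncx - a) / px) - 1, 0)
        x1 = min(int((ncx + a) / px) + 2, geom.frame_shape[1])
        y0 = max(int((ncy - a) / px) - 1, 0)
        y1 = min(int((ncy + a) / px) + 2, geom.frame_shape[0])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = xx * px - ncx
        dy = yy * px - ncy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        rnlo = spec.nucleolus_ratio * b
        for k in range(geom.n_sections):
            dz = k * geom.z_spacing - ncz
            inside = (u / a) ** 2 + (v / b) ** 2 + (dz / b) ** 2 <= 1.0
            if not inside.any():
                continue
            patch = out[k, y0:y1, x0:x1]
            patch[inside] = background + amplitude
            if rnlo > 0:
                nucleolus = dx**2 + dy**2 + dz**2 <= rnlo**2
                patch[nucleolus & inside] = background + amplitude * nucleolar_dim_factor
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, out.shape)
    return ImageStack(out, pixel_size=px, z_spacing=geom.z_spacing)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------


def _capsule_clearance_ok(
    new: PhantomSpec, placed: list[PhantomSpec], clearance_um: float
) -> bool:
    pts_new = new.axis_points_um(step_um=0.25)
    for other in placed:
        pts = other.axis_points_um(step_um=0.25)
        d = cKDTree(pts).query(pts_new)[0].min()
        if d < (new.width_um + other.width_um) / 2 + clearance_um:
            return False
    return True


def make_scene(
    n_cells: int,
    field_shape: tuple[int, int] = (640, 640),
    strain_preset: str = "wt",
    seed: int = 0,
    nc_ratio: float = 0.125,
    clearance_um: float = 1.2,
    margin_um: float = 3.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    z_spacing: float = DEFAULT_Z_SPACING,
    noise_sd_brightfield: float = 15.0,
    noise_sd_nuclear: float = 10.0,
    band_width_slope: float = 0.8,
) -> tuple[ImageStack, ImageStack, pd.DataFrame, SceneGeometry, list[PhantomSpec]]:
    """Assemble a field of non-overlapping phantoms and render both channels.

    Cells lie flat at a common midplane; lengths, orientations and bend
    angles are drawn from the strain preset's ranges with one seeded
    generator, placements by rejection sampling with a surface-to-surface
    clearance.  Each nucleus is a near-spherical prolate ellipsoid sized so
    that nucleus/cell volume equals ``nc_ratio``, its minor axis capped to
    fit inside the cell width.  Returns (brightfield, nuclear channel,
    truth table, geometry, specs)."""
    if strain_preset not in STRAIN_PRESETS:
        raise ValueError(f"unknown strain preset {strain_preset!r}")
    preset = STRAIN_PRESETS[strain_preset]
    rng = np.random.default_rng(seed)
    max_w = preset["width"][1]
    half_sections = int(np.ceil(max_w / 2 / z_spacing))
    midplane = half_sections + 3
    focus = midplane + 8
    n_sections = midplane + half_sections + 4
    geom = SceneGeometry(
        frame_shape=tuple(field_shape),
        n_sections=n_sections,
        pixel_size=pixel_size,
        z_spacing=z_spacing,
        midplane_section=midplane,
        focus_section=focus,
    )
    field_um = (field_shape[1] * pixel_size, field_shape[0] * pixel_size)
    z_mid_um = midplane * z_spacing

    specs: list[PhantomSpec] = []
    attempts = 0
    while len(specs) < n_cells and attempts < 4000 * max(n_cells, 1):
        attempts += 1
        L = rng.uniform(*preset["length"])
        W = rng.uniform(*preset["width"])
        bend = rng.uniform(*preset["bend"])
        shape = "bent-capsule" if bend > 0 else "straight-capsule"
        # nucleus: near-spherical prolate ellipsoid at the target N/C ratio
        v_cell = PhantomSpec(shape=shape, length_um=L, width_um=W,
                             bend_angle_deg=bend).volume_um3
        v_nuc = nc_ratio * v_cell
        b = (3 * v_nuc / (4 * np.pi * 1.05)) ** (1 / 3)
        b = min(b, W / 2 - 0.3)
        a = 3 * v_nuc / (4 * np.pi * b**2)
        pad = margin_um + L / 2
        if field_um[0] <= 2 * pad or field_um[1] <= 2 * pad:
            raise ValueError("field too small for this strain preset")
        cand = PhantomSpec(
            shape=shape,
            length_um=L,
            width_um=W,
            bend_angle_deg=bend,
            orientation_deg=rng.uniform(0, 180),
            center_um=(
                rng.uniform(pad, field_um[0] - pad),
                rng.uniform(pad, field_um[1] - pad),
                z_mid_um,
            ),
            nucleus_axes_um=(2 * a, 2 * b),
        )
        if _capsule_clearance_ok(cand, specs, clearance_um):
            specs.append(cand)
    if len(specs) < n_cells:
        raise ValueError(
            f"could not place {n_cells} non-overlapping cells; "
            f"placed {len(specs)} — enlarge the field or lower the density"
        )

    truth = np.zeros((geom.n_sections,) + geom.frame_shape, bool)
    rows = []
    for i, spec in enumerate(specs):
        mask, vol = truth_voxels(spec, geom)
        truth |= mask
        rows.append(
            dict(
                cell_id=i,
                shape=spec.shape,
                length_um=spec.length_um,
                width_um=spec.width_um,
                bend_angle_deg=spec.bend_angle_deg,
                orientation_deg=spec.orientation_deg,
                x_um=spec.center_um[0],
                y_um=spec.center_um[1],
                z_um=spec.center_um[2],
                volume_um3=vol,
                nucleus_volume_um3=spec.nucleus_volume_um3,
                nc_ratio=spec.nucleus_volume_um3 / vol if vol else np.nan,
            )
        )
    truth_table = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "shape", "length_um", "width_um", "bend_angle_deg",
            "orientation_deg", "x_um", "y_um", "z_um", "volume_um3",
            "nucleus_volume_um3", "nc_ratio",
        ],
    )
    bf = render_brightfield(
        truth,
        focus_index=geom.focus_section,
        band_width_slope=band_width_slope,
        noise_sd=noise_sd_brightfield,
        seed=rng,
        pixel_size=pixel_size,
        z_spacing=z_spacing,
    )
    nuc = render_nucleus_channel(
        specs, geom, noise_sd=noise_sd_nuclear, seed=rng
    )
    return bf, nuc, truth_table, geom, specs
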