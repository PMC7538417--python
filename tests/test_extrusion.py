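import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spherotome.extrusion import (
    RadiusProfile,
    cross_section_radius,
    distance_map,
    extrude,
    extrude_all,
    extrude_region,
    radius_profile,
    skeletonize,
)
from spherotome.morphometry import stack_volume
from spherotome.phantoms import PhantomSpec, SceneGeometry, truth_voxels
from spherotome.regions import PlanarRegion

from conftest import disk_mask


def brute_force_edt(mask):
    """All-pairs distance oracle for small grids."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    for r, c in fg:
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min())
    return out


def flat_capsule(width, length, shape, row_offset=0.4):
    """Axis-aligned capsule whose flat sides fall between pixel rows."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy = shape[0] / 2 + row_offset
    x0, x1 = (shape[1] - length + width) / 2, (shape[1] + length - width) / 2
    t = np.clip((xx - x0) / (x1 - x0), 0, 1)
    return np.hypot(xx - (x0 + t * (x1 - x0)), yy - cy) <= width / 2


class TestDistanceMap:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert distance_map(m)[2, 2] == pytest.approx(1.0)

    def test_disk_matches_brute_force(self):
        m = disk_mask((32, 32), (16, 16), 10)
        np.testing.assert_allclose(distance_map(m), brute_force_edt(m), atol=1e-9)
        assert distance_map(m).max() == pytest.approx(10, abs=0.5)

    def test_capsule_skeleton_values(self):
        m = flat_capsule(30, 50, (48, 64))
        d = distance_map(m)
        np.testing.assert_allclose(d, brute_force_edt(m), atol=1e-9)
        skel = skeletonize(m)
        # along the straight segment (away from the caps) the axis radius
        # equals the half-width
        rr, cc = np.nonzero(skel)
        core = (cc > 24) & (cc < 40)
        assert core.any()
        assert np.all(np.abs(d[rr[core], cc[core]] - 15) <= 0.6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_map(np.zeros((4, 4), bool))


class TestSkeleton:
    def test_straight_capsule_single_path(self):
        skel = skeletonize(flat_capsule(30, 90, (50, 110)))
        # every pixel has at most 2 neighbors: one unbranched path
        from scipy import ndimage

        k = np.ones((3, 3)); k[1, 1] = 0
        ncount = ndimage.convolve(skel.astype(int), k, mode="constant")
        assert (ncount[skel] <= 2).all()
        assert (ncount[skel] == 1).sum() == 2  # exactly two endpoints

    def test_disk_collapses(self):
        # the skeleton of a disk is a short central segment, far shorter
        # than the boundary or diameter-spanning structures
        skel = skeletonize(disk_mask((40, 40), (20, 20), 12))
        assert 1 <= skel.sum() <= 30

    def test_bent_capsule_unbranched(self):
        geom = SceneGeometry(frame_shape=(200, 200), n_sections=3, pixel_size=1.0,
                             z_spacing=100.0, midplane_section=1)
        sp = PhantomSpec(shape="bent-capsule", length_um=100, width_um=30,
                         bend_angle_deg=90, center_um=(100.2, 90.3, 100.0))
        mid = truth_voxels(sp, geom)[0][1]
        skel = skeletonize(mid)
        from scipy import ndimage
        from skimage import measure

        # a branch-free curve: one component with exactly two endpoints
        assert measure.label(skel, connectivity=2).max() == 1
        k = np.ones((3, 3)); k[1, 1] = 0
        ncount = ndimage.convolve(skel.astype(int), k, mode="constant")
        assert (ncount[skel] == 1).sum() == 2

    def test_thin_line_is_its_own_skeleton(self):
        m = np.zeros((10, 30), bool)
        m[5, 5:25] = True
        assert skeletonize(m, prune=False).sum() >= 18


class TestRadiusProfile:
    def test_capsule_constant_radius(self):
        m = flat_capsule(30, 60, (48, 80))
        prof = radius_profile(skeletonize(m), distance_map(m))
        # straight tube spans x in (25, 55); radii in the caps taper off
        xs, rs = prof.points[:, 0], prof.points[:, 2]
        core = rs[(xs > 27) & (xs < 53)]
        assert len(core) > 10
        assert np.all(np.abs(core - 15) <= 0.6)

    def test_tapered_radius_decreases(self):
        geom = SceneGeometry(frame_shape=(90, 200), n_sections=3, pixel_size=1.0,
                             z_spacing=100.0, midplane_section=1)
        sp = PhantomSpec(shape="tapered-capsule", length_um=160, width_um=30,
                         taper_ratio=0.66, center_um=(100.3, 45.2, 100.0))
        mid = truth_voxels(sp, geom)[0][1]
        prof = radius_profile(skeletonize(mid), distance_map(mid))
        xs, rs = prof.points[:, 0], prof.points[:, 2]
        # restrict to the tapering tube, excluding both end caps
        sel = (xs > 50) & (xs < 150)
        order = np.argsort(xs[sel])
        core = rs[sel][order]
        smoothed = np.convolve(core, np.ones(7) / 7, mode="valid")
        # taper from ~14.4 down to ~11.2 px over the selected span
        assert smoothed[0] > smoothed[-1] + 2.5
        assert (np.diff(smoothed) <= 0.5).all()  # monotone within wobble

    def test_single_point_on_disk(self):
        m = disk_mask((40, 40), (20, 20), 10)
        prof = radius_profile(skeletonize(m), distance_map(m))
        assert prof.max_radius == pytest.approx(10, abs=0.7)

    def test_skeleton_outside_region_rejected(self):
        m = disk_mask((20, 20), (10, 10), 5)
        bad = np.zeros((20, 20), bool)
        bad[1, 1] = True
        with pytest.raises(ValueError, match="zero distance"):
            radius_profile(bad, distance_map(m))


class TestCrossSection:
    @pytest.mark.parametrize("R,dz,expected", [(5, 0, 5.0), (5, 3, 4.0)])
    def test_pythagorean(self, R, dz, expected):
        assert cross_section_radius(R, dz) == pytest.approx(expected)

    def test_beyond_pole_none(self):
        assert cross_section_radius(5, 6) is None
        assert cross_section_radius(5, 5) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cross_section_radius(-1, 0)

    @given(R=st.floats(0.5, 50), frac=st.floats(0, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_radius_bounded_by_parent(self, R, frac):
        r = cross_section_radius(R, R * frac)
        assert r is not None and 0 < r <= R


class TestExtrude:
    def test_single_sphere_volume(self):
        prof = RadiusProfile(np.array([[32.0, 32.0, 20.0]]))
        stk = extrude(prof, 32, 64, 1.0, 1.0, (64, 64))
        assert stack_volume(stk) == pytest.approx((4 / 3) * np.pi * 20**3, rel=0.02)

    def test_section_beyond_radius_absent(self):
        prof = RadiusProfile(np.array([[16.0, 16.0, 4.7]]))
        stk = extrude(prof, 10, 30, 1.0, 1.0, (32, 32))
        assert set(stk.sections) == set(range(6, 15))

    def test_oracle_equivalence_union_of_spheres(self):
        # exact set equality against the brute-force voxelizer
        rng = np.random.default_rng(7)
        pts = np.column_stack(
            [rng.uniform(12, 50, 6), rng.uniform(12, 50, 6), rng.uniform(3, 9, 6)]
        )
        frame, nz, zsp = (64, 64), 40, 0.7
        stk = extrude(RadiusProfile(pts), 20, nz, 1.0, zsp, frame)
        got = np.zeros((nz,) + frame, bool)
        for k, reg in stk.regions.items():
            got[k] = reg.full_mask(frame)
        want = np.zeros_like(got)
        yy, xx = np.mgrid[: frame[0], : frame[1]]
        for k in range(nz):
            dz = abs(k - 20) * zsp
            for x, y, R in pts:
                want[k] |= (xx - round(x)) ** 2 + (yy - round(y)) ** 2 <= R * R - dz * dz
        np.testing.assert_array_equal(got, want)

    def test_monotone_sections_single_sphere(self):
        stk = extrude(RadiusProfile(np.array([[30.0, 30.0, 15.0]])), 20, 40,
                      1.0, 0.7, (64, 64))
        secs = sorted(stk.regions)
        areas = [stk.regions[k].area for k in secs]
        mid = secs.index(20)
        assert all(np.diff(areas[: mid + 1]) >= 0)
        assert all(np.diff(areas[mid:]) <= 0)

    def test_capsule_volume_and_midplane_containment(self):
        m = flat_capsule(40, 120, (60, 140))
        reg = PlanarRegion(m, frame_shape=(60, 140))
        stk = extrude_region(reg, 30, 61, 1.0, 1.0)
        analytic = 80 * np.pi * 20**2 + (4 / 3) * np.pi * 20**3
        assert stack_volume(stk) == pytest.approx(analytic, rel=0.02)
        got = stk.midplane_region.full_mask((60, 140))
        assert (got & m).sum() / m.sum() >= 0.99
        assert (got & m).sum() / (got | m).sum() >= 0.97

    def test_midplane_out_of_range_rejected(self):
        prof = RadiusProfile(np.array([[5.0, 5.0, 3.0]]))
        with pytest.raises(ValueError):
            extrude(prof, 30, 20, 1.0, 1.0, (16, 16))
        with pytest.raises(ValueError):
            extrude(prof, 5, 20, 1.0, 0.0, (16, 16))


class TestInvariants:
    def test_bend_invariance(self):
        geom = SceneGeometry(frame_shape=(200, 200), n_sections=60, pixel_size=1.0,
                             z_spacing=1.0, midplane_section=30)
        vols = {}
        for bend in (0, 60, 120):
            sp = PhantomSpec(
                shape="bent-capsule" if bend else "straight-capsule",
                length_um=120, width_um=40, bend_angle_deg=bend,
                orientation_deg=30, center_um=(100.2, 95.7, 30.0),
            )
            mid = truth_voxels(sp, geom)[0][30]
            stk = extrude_region(PlanarRegion(mid, frame_shape=(200, 200)),
                                 30, 60, 1.0, 1.0)
            vols[bend] = stack_volume(stk)
        assert abs(vols[60] - vols[0]) / vols[0] <= 0.03
        assert abs(vols[120] - vols[0]) / vols[0] <= 0.03

    def test_sphere_convergence(self):
        errs = []
        for R in (8, 16, 32):
            n = 2 * R + 12
            m = disk_mask((n, n), (n // 2, n // 2), R)
            stk = extrude_region(PlanarRegion(m, frame_shape=(n, n)),
                                 n // 2, n, 1.0, 1.0)
            v = stack_volume(stk)
            errs.append(abs(v - (4 / 3) * np.pi * R**3) / ((4 / 3) * np.pi * R**3))
        assert errs[0] > errs[1] > errs[2]

    def test_axial_factor_leaves_cell_volume_invariant(self):
        m = disk_mask((64, 64), (32, 32), 15)
        reg = PlanarRegion(m, frame_shape=(64, 64))
        base = extrude_region(reg, 40, 81, 0.5, 0.5)
        doubled = extrude_region(reg, 40, 81, 0.5, 1.0)
        v0, v1 = stack_volume(base), stack_volume(doubled)
        one_section = doubled.midplane_region.area * 0.5**2 * 1.0
        assert abs(v1 - v0) <= one_section
        assert base.voxel_count > 1.8 * doubled.voxel_count


class TestBatch:
    def test_empty_input(self):
        assert extrude_all([], 0, 10, 1.0, 1.0) == ([], [])

    def test_two_phantoms_two_stacks(self):
        regs = [
            PlanarRegion(disk_mask((64, 64), (20, 20), 8), frame_shape=(64, 64)),
            PlanarRegion(disk_mask((64, 64), (45, 45), 8), frame_shape=(64, 64)),
        ]
        stacks, failures = extrude_all(regs, 10, 21, 1.0, 1.0)
        assert len(stacks) == 2 and failures == []

    def test_per_cell_failure_recorded(self):
        good = PlanarRegion(disk_mask((64, 64), (20, 20), 8), frame_shape=(64, 64))
        stacks, failures = extrude_all([good, good], [10, 99], 21, 1.0, 1.0)
        assert len(stacks) == 1 and len(failures) == 1
        assert failures[0][0] == 1
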