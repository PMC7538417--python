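import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spherotome.extrusion import RadiusProfile, RegionStack, extrude, extrude_region
from spherotome.morphometry import (
    IdealizedEllipsoid,
    IdealizedRod,
    aspect_ratio,
    ellipse_dims,
    ellipsoid_surface,
    ellipsoid_volume,
    feret_dims,
    measure_pairs,
    nc_ratio,
    nucleus_within_cell,
    pair_nuclei_cells,
    rod_surface,
    rod_volume,
    stack_intensity,
    stack_surface,
    stack_volume,
)
from spherotome.nuclei import NucleusModel
from spherotome.regions import PlanarRegion
from spherotome.stack import ImageStack

from conftest import disk_mask, disk_region


def single_section_stack(mask, px=0.1, z=0.065, mid=0):
    reg = PlanarRegion(mask, section_index=mid, frame_shape=mask.shape)
    return RegionStack({mid: reg}, midplane_index=mid, pixel_size=px, z_spacing=z)


def sphere_stack(R=20, frame=(64, 64), px=1.0, z=1.0):
    prof = RadiusProfile(np.array([[frame[1] / 2, frame[0] / 2, float(R)]]))
    return extrude(prof, frame[0] // 2, frame[0], px, z, frame)


class TestVoxelizedMeasures:
    def test_single_section_volume_arithmetic(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True  # 100 px
        stk = single_section_stack(m, px=0.1, z=0.065)
        assert stack_volume(stk) == pytest.approx(100 * 0.01 * 0.065)

    def test_sphere_volume(self):
        stk = sphere_stack(R=20)
        assert stack_volume(stk) == pytest.approx(33.51e3, rel=0.02)

    def test_volume_linear_in_z_spacing(self):
        m = disk_mask((40, 40), (20, 20), 10)
        v1 = stack_volume(single_section_stack(m, z=0.065))
        v2 = stack_volume(single_section_stack(m, z=0.13))
        assert v2 == pytest.approx(2 * v1)

    def test_single_section_surface_formula(self):
        m = disk_mask((40, 40), (20, 20), 10)
        stk = single_section_stack(m, px=0.1, z=0.065)
        reg = stk.midplane_region
        expected = reg.perimeter * 0.1 * 0.065 + 2 * reg.area * 0.01
        assert stack_surface(stk) == pytest.approx(expected, rel=1e-12)

    def test_surface_equals_staircase_oracle_on_sphere(self):
        stk = sphere_stack(R=15)
        # independent per-section perimeter/area summation
        oracle = sum(
            r.perimeter * stk.pixel_size * stk.z_spacing for r in stk.regions.values()
        ) + 2 * stk.midplane_region.area * stk.pixel_size**2
        assert stack_surface(stk) == oracle

    def test_cylinder_stack_surface(self):
        m = disk_mask((40, 40), (20, 20), 10)
        regs = {
            k: PlanarRegion(m, section_index=k, frame_shape=(40, 40)) for k in range(5)
        }
        stk = RegionStack(regs, midplane_index=2, pixel_size=0.1, z_spacing=0.065)
        reg = stk.midplane_region
        expected = 5 * reg.perimeter * 0.1 * 0.065 + 2 * reg.area * 0.01
        assert stack_surface(stk) == pytest.approx(expected, rel=1e-12)


class TestDims:
    def test_feret_of_rasterized_capsule(self):
        from test_extrusion import flat_capsule

        m = flat_capsule(40, 120, (60, 140))
        L, W = feret_dims(PlanarRegion(m))
        assert L == pytest.approx(120, abs=1)
        assert W == pytest.approx(40, abs=1)

    def test_circle_dims_agree(self):
        reg = disk_region((60, 60), (30, 30), 20.2)
        Lf, Wf = feret_dims(reg)
        Le, We = ellipse_dims(reg)
        assert Lf == pytest.approx(Wf, abs=1)
        assert Le == pytest.approx(We, rel=0.02)
        assert Le == pytest.approx(Lf, rel=0.05)

    def test_ellipse_length_exceeds_feret_on_capsules(self):
        # the area-preserving elliptical fit overestimates capsule length
        from test_extrusion import flat_capsule

        m = flat_capsule(40, 120, (60, 140))
        reg = PlanarRegion(m)
        assert ellipse_dims(reg)[0] >= feret_dims(reg)[0]


class TestIdealizedFormulas:
    def test_rod_reduces_to_sphere(self):
        r = 1.3
        rod = IdealizedRod(L=2 * r, W=2 * r)
        assert rod_volume(rod) == pytest.approx((4 / 3) * np.pi * r**3, rel=1e-12)
        assert rod_surface(rod) == pytest.approx(4 * np.pi * r**2, rel=1e-12)

    def test_rod_analytic_values(self):
        rod = IdealizedRod(L=4, W=2)
        assert rod_volume(rod) == pytest.approx(10 * np.pi / 3, rel=1e-12)
        assert rod_surface(rod) == pytest.approx(8 * np.pi, rel=1e-12)

    def test_rod_surface_scales_quadratically(self):
        s1 = rod_surface(IdealizedRod(L=5, W=2))
        s2 = rod_surface(IdealizedRod(L=15, W=6))
        assert s2 == pytest.approx(9 * s1, rel=1e-12)

    def test_invalid_rod_rejected(self):
        with pytest.raises(ValueError):
            IdealizedRod(L=1, W=2)

    def test_ellipsoid_volume(self):
        assert ellipsoid_volume(IdealizedEllipsoid(L=2, W=2)) == pytest.approx(
            (4 / 3) * np.pi, rel=1e-12
        )
        assert ellipsoid_volume(IdealizedEllipsoid(L=4, W=2)) == pytest.approx(
            (8 / 3) * np.pi, rel=1e-12
        )

    def test_ellipsoid_surface_sphere_limit_exact(self):
        a = 1.7
        s = ellipsoid_surface(IdealizedEllipsoid(L=2 * a, W=2 * a))
        assert s == pytest.approx(4 * np.pi * a**2, rel=1e-12)

    def test_ellipsoid_surface_vs_prolate_closed_form(self):
        a, b = 2.0, 1.0
        e = np.sqrt(1 - (b / a) ** 2)
        exact = 2 * np.pi * b**2 * (1 + (a / (b * e)) * np.arcsin(e))
        approx = ellipsoid_surface(IdealizedEllipsoid(L=2 * a, W=2 * b))
        assert abs(approx - exact) / exact <= 0.012

    @given(a=st.floats(1.0, 5.0), b=st.floats(0.5, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_ellipsoid_surface_monotone_in_a(self, a, b):
        s1 = ellipsoid_surface(IdealizedEllipsoid(L=2 * a, W=2 * b))
        s2 = ellipsoid_surface(IdealizedEllipsoid(L=2 * (a + 0.5), W=2 * b))
        assert s2 > s1


def _nucleus_at(cx, cy, mid_z, frame=(64, 64), r=5, n=5, px=1.0, z=1.0):
    regs = []
    for i, zidx in enumerate(range(mid_z - n // 2, mid_z + n // 2 + 1)):
        rr = r if zidx == mid_z else r - 1 - abs(zidx - mid_z) // 2
        m = disk_mask(frame, (cy, cx), max(rr, 2))
        regs.append(PlanarRegion(m, section_index=zidx, frame_shape=frame))
    return NucleusModel(regs, pixel_size=px, z_spacing=z)


class TestPairing:
    def test_one_cell_one_nucleus(self):
        cell = sphere_stack(R=20)
        nuc = _nucleus_at(32, 32, 32)
        pairs, excluded = pair_nuclei_cells([cell], [nuc])
        assert len(pairs) == 1 and excluded == []

    def test_two_nuclei_excludes_cell(self):
        cell = sphere_stack(R=20)
        nucs = [_nucleus_at(28, 32, 32), _nucleus_at(38, 32, 32)]
        pairs, excluded = pair_nuclei_cells([cell], nucs)
        assert pairs == []
        assert any("multinucleate" in r.filter_flags for r in excluded)

    def test_orphan_nucleus_dropped(self):
        cell = sphere_stack(R=10)
        nuc = _nucleus_at(60, 60, 32)
        pairs, excluded = pair_nuclei_cells([cell], [nuc])
        assert pairs == []
        flags = {f for r in excluded for f in r.filter_flags}
        assert {"anucleate", "nucleus_without_cell"} <= flags


class TestFilters:
    def test_sphere_aspect_ratio_near_one(self):
        stk = sphere_stack(R=20)
        assert aspect_ratio(stk, kind="cell") == pytest.approx(1.0, abs=0.1)

    def test_truncated_stack_fails_low(self):
        # acquisition cut off below the midplane: keep sections up to it
        full = sphere_stack(R=20)
        secs = [k for k in sorted(full.regions) if k <= full.midplane_index]
        trunc = RegionStack(
            {k: full.regions[k] for k in secs},
            midplane_index=full.midplane_index,
            pixel_size=1.0, z_spacing=1.0,
        )
        assert aspect_ratio(trunc, kind="cell") < 0.8

    def test_nucleus_containment(self):
        cell = sphere_stack(R=20)
        inside = _nucleus_at(32, 32, 32, r=4)
        shifted = _nucleus_at(50, 32, 32, r=6)
        assert nucleus_within_cell(cell, inside)
        assert not nucleus_within_cell(cell, shifted)

    def test_records_failing_filters_are_flagged_and_excluded(self):
        cell = sphere_stack(R=20)
        nuc = _nucleus_at(32, 32, 32)
        pairs, _ = pair_nuclei_cells([cell], [nuc])
        recs = measure_pairs(pairs)
        assert len(recs) == 1
        # this toy nucleus spans 5 sections over a 10-px diameter: aspect fails
        rec = recs[0]
        if rec.filter_flags:
            from spherotome.morphometry import apply_filters

            assert apply_filters(recs) == []


class TestIntensity:
    def test_uniform_image(self):
        stk = sphere_stack(R=10, frame=(32, 32))
        ch = ImageStack(np.full((32, 32, 32), 3.0), 1.0, 1.0)
        integ, mean = stack_intensity(stk, ch)
        assert integ == pytest.approx(3.0 * stk.voxel_count)
        assert mean == pytest.approx(integ / stack_volume(stk))

    def test_zero_image(self):
        stk = sphere_stack(R=10, frame=(32, 32))
        ch = ImageStack(np.zeros((32, 32, 32)), 1.0, 1.0)
        assert stack_intensity(stk, ch) == (0.0, 0.0)

    def test_hand_built_toy_sum(self):
        m = np.zeros((3, 3), bool)
        m[1, :] = True  # 3 px per section
        regs = {
            k: PlanarRegion(m, section_index=k, frame_shape=(3, 3)) for k in range(3)
        }
        stk = RegionStack(regs, midplane_index=1, pixel_size=1.0, z_spacing=1.0)
        data = np.arange(27, dtype=float).reshape(3, 3, 3)
        ch = ImageStack(data, 1.0, 1.0)
        expected = data[:, 1, :].sum()
        assert stack_intensity(stk, ch)[0] == pytest.approx(expected)


class TestNCRatio:
    def test_equal_volumes(self):
        assert nc_ratio(5.0, 5.0) == 1.0

    def test_zero_nucleus_rejected(self):
        with pytest.raises(ValueError):
            nc_ratio(0.0, 5.0)


class TestRodVsExtruded:
    def test_constant_width_capsule_agrees_within_2pct(self):
        from test_extrusion import flat_capsule

        m = flat_capsule(40, 120, (60, 140))
        reg = PlanarRegion(m, frame_shape=(60, 140))
        stk = extrude_region(reg, 30, 61, 1.0, 1.0)
        L, W = feret_dims(reg)
        rv = rod_volume(IdealizedRod(L, W))
        assert abs(rv - stack_volume(stk)) / stack_volume(stk) <= 0.02

    def test_waisted_phantom_rod_overestimates(self):
        geom = __import__("spherotome").SceneGeometry(
            frame_shape=(80, 200), n_sections=80, pixel_size=1.0,
            z_spacing=1.0, midplane_section=40,
        )
        from spherotome.phantoms import PhantomSpec, truth_voxels

        sp = PhantomSpec(shape="tapered-capsule", length_um=140, width_um=36,
                         taper_ratio=0.6, center_um=(100.2, 40.3, 40.0))
        mid = truth_voxels(sp, geom)[0][40]
        reg = PlanarRegion(mid, frame_shape=geom.frame_shape)
        stk = extrude_region(reg, 40, 80, 1.0, 1.0)
        L, W = feret_dims(reg)
        assert rod_volume(IdealizedRod(L, W)) >= stack_volume(stk)

    def test_translation_and_rotation_invariance(self):
        geom = __import__("spherotome").SceneGeometry(
            frame_shape=(160, 160), n_sections=64, pixel_size=1.0,
            z_spacing=1.0, midplane_section=32,
        )
        from spherotome.phantoms import PhantomSpec, truth_voxels

        vols = []
        for (cx, cy, ori) in [(70.2, 80.3, 0), (90.2, 70.3, 90), (80.7, 75.8, 0)]:
            sp = PhantomSpec(length_um=90, width_um=30, orientation_deg=ori,
                             center_um=(cx, cy, 32.0))
            mid = truth_voxels(sp, geom)[0][32]
            stk = extrude_region(PlanarRegion(mid, frame_shape=geom.frame_shape),
                                 32, 64, 1.0, 1.0)
            vols.append(stack_volume(stk))
        assert max(vols) / min(vols) <= 1.03
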