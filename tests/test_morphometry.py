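import numpy as np
import pytest

from airwaymorph import morphometry as mm
from airwaymorph.core import AirwayMask
from airwaymorph.errors import (DataError, EmptyInputError,
                                UndefinedParameterError)
from conftest import make_sphere_mask, make_tube_mask

CYL_SPHERICITY = np.pi ** (1 / 3) * (12 * np.pi) ** (2 / 3) / (6 * np.pi)


# ---------------------------------------------------------------------------
# brute-force oracles (independent per-voxel enumeration)
# ---------------------------------------------------------------------------

def brute_volume(mask):
    count = 0
    nx, ny, nz = mask.data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask.data[i, j, k]:
                    count += 1
    return count * mask.spacing[0] * mask.spacing[1] * mask.spacing[2]


def brute_profile(mask):
    areas = {}
    nx, ny, nz = mask.data.shape
    for k in range(nz):
        n = 0
        for i in range(nx):
            for j in range(ny):
                if mask.data[i, j, k]:
                    n += 1
        areas[k] = n * mask.spacing[0] * mask.spacing[1]
    return areas


def brute_lat_ap(sl, dx, dy, i_mid):
    lat = 0
    for j in range(sl.shape[1]):
        cols = [i for i in range(sl.shape[0]) if sl[i, j]]
        if cols:
            lat = max(lat, (max(cols) - min(cols) + 1) * dx)
    rows = [j for j in range(sl.shape[1]) if sl[i_mid, j]]
    ap = (max(rows) - min(rows) + 1) * dy if rows else None
    return lat, ap


# ---------------------------------------------------------------------------


class TestVolumeLength:
    def test_volume_arithmetic(self):
        data = np.zeros((10, 10, 10), bool)
        data.ravel()[:1000] = True
        mask = AirwayMask(data, (0.5, 0.5, 0.5), (0, 0, 0))
        assert mm.measure_volume(mask) == pytest.approx(125.0)

    def test_volume_empty_raises(self):
        mask = AirwayMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(EmptyInputError):
            mm.measure_volume(mask)

    def test_cylinder_volume(self):
        mask = make_tube_mask(8.0, 60.0, 0.5)
        assert mm.measure_volume(mask) == pytest.approx(
            np.pi * 64 * 60, rel=0.02)

    def test_length_is_plane_distance(self):
        mask = make_tube_mask(4.0, 10.0, 1.0)
        mask.z_top, mask.z_bottom = 66.3, 0.0
        assert mm.measure_length(mask) == pytest.approx(66.3)

    def test_region_additivity(self, measured_phantom):
        records, _, _, _ = measured_phantom
        by_tag = {r.region_tag: r for r in records}
        regions = [v for k, v in by_tag.items() if k != "total"]
        assert sum(r.V for r in regions) == pytest.approx(
            by_tag["total"].V, abs=1e-6)
        assert sum(r.L for r in regions) == pytest.approx(
            by_tag["total"].L, abs=1e-9)

    def test_oropharynx_equals_tongue_base_length(self, measured_phantom):
        # MUE is the exact z-midpoint, so the two segment lengths agree
        records, _, _, _ = measured_phantom
        by_tag = {r.region_tag: r for r in records}
        assert by_tag["oropharynx"].L == pytest.approx(
            by_tag["tongue_base"].L, abs=1e-9)


class TestSurface:
    def test_cylinder_closed_forms(self):
        mask = make_tube_mask(8.0, 60.0, 0.5)
        sa, sac = mm.measure_surface(mask)
        assert sa == pytest.approx(2 * np.pi * 8 * 60, rel=0.04)
        assert sac == pytest.approx(2 * np.pi * 8 * 60 + 2 * np.pi * 64,
                                    rel=0.04)

    def test_open_below_closed(self, measured_phantom):
        records, _, _, _ = measured_phantom
        for rec in records:
            assert rec.SA < rec.SA_closed

    def test_single_voxel_voxel_face(self):
        data = np.zeros((3, 3, 3), bool)
        data[1, 1, 1] = True
        mask = AirwayMask(data, (1, 1, 1), (0, 0, 0))
        sa, sac = mm.measure_surface(mask, method="voxel_face")
        assert sac == pytest.approx(6.0)

    def test_voxel_face_cylinder_caps(self):
        mask = make_tube_mask(8.0, 20.0, 0.5)
        sa, sac = mm.measure_surface(mask, method="voxel_face")
        cap = np.pi * 64
        # caps are flat: exact up to pixelation; lateral overestimates by 4/pi
        assert sac - sa == pytest.approx(2 * cap, rel=0.02)
        assert sa == pytest.approx(2 * np.pi * 8 * 20 * 4 / np.pi, rel=0.05)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            mm.measure_surface(make_tube_mask(4, 10, 1.0), method="nope")

    def test_empty_raises(self):
        mask = AirwayMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(EmptyInputError):
            mm.measure_surface(mask)

    def test_region_additivity_within_tolerance(self, measured_phantom):
        records, _, _, _ = measured_phantom
        by_tag = {r.region_tag: r for r in records}
        total = by_tag.pop("total")
        assert sum(r.SA for r in by_tag.values()) == pytest.approx(
            total.SA, rel=0.01)


class TestProfileAndMca:
    def test_constant_tube_profile(self):
        mask = make_tube_mask(8.0, 30.0, 0.5)
        profile = mm.cross_section_profile(mask)
        assert np.all(np.diff(profile.z) < 0)
        np.testing.assert_allclose(profile.area, profile.area[0])

    def test_phantom_profile_matches_area_function(self, clean_phantom,
                                                   measured_phantom):
        spec, _, _, _ = clean_phantom
        _, mask, _, _ = measured_phantom
        profile = mm.cross_section_profile(mask)
        np.testing.assert_allclose(profile.area,
                                   spec.area_profile(profile.z), rtol=0.03)

    def test_find_mca_simple(self):
        profile = mm.CrossSectionProfile(
            z=[4.0, 3.0, 2.0, 1.0], area=[201.0, 150.0, 80.0, 150.0],
            slice_index=[3, 2, 1, 0])
        mca, z = mm.find_mca(profile)
        assert (mca, z) == (80.0, 2.0)

    def test_tie_breaks_superior(self):
        profile = mm.CrossSectionProfile(
            z=[4.0, 3.0, 2.0, 1.0], area=[100.0, 80.0, 80.0, 100.0],
            slice_index=[3, 2, 1, 0])
        _, z = mm.find_mca(profile)
        assert z == 3.0

    def test_all_zero_raises(self):
        profile = mm.CrossSectionProfile(z=[2.0, 1.0], area=[0.0, 0.0],
                                         slice_index=[1, 0])
        with pytest.raises(EmptyInputError):
            mm.find_mca(profile)

    def test_interior_zero_is_data_error(self):
        profile = mm.CrossSectionProfile(
            z=[3.0, 2.0, 1.0], area=[50.0, 0.0, 60.0], slice_index=[2, 1, 0])
        with pytest.raises(DataError):
            mm.find_mca(profile)

    def test_boundary_zeros_ignored(self):
        profile = mm.CrossSectionProfile(
            z=[4.0, 3.0, 2.0, 1.0], area=[0.0, 90.0, 70.0, 0.0],
            slice_index=[3, 2, 1, 0])
        mca, z = mm.find_mca(profile)
        assert (mca, z) == (70.0, 2.0)

    def test_phantom_constriction_recovered(self, measured_phantom):
        records, _, _, truth = measured_phantom
        assert records[0].MCA == pytest.approx(truth["total"].MCA, rel=0.03)


class TestMcaDimensions:
    def ellipse_slice(self, a, b, sp=0.5):
        n = int(2 * (max(a, b) + 2) / sp)
        c = (np.arange(n) + 0.5) * sp - (max(a, b) + 2)
        X, Y = np.meshgrid(c, c, indexing="ij")
        return (X / a) ** 2 + (Y / b) ** 2 <= 1.0, c

    def test_ellipse(self):
        sl, c = self.ellipse_slice(10.0, 4.0)
        lat, ap = mm.mca_dimensions(sl, (0.5, 0.5), 0.0, c[0])
        assert lat == pytest.approx(20.0, abs=0.5)
        assert ap == pytest.approx(8.0, abs=0.5)

    def test_circle_ratio_one(self):
        sl, c = self.ellipse_slice(5.0, 5.0)
        lat, ap = mm.mca_dimensions(sl, (0.5, 0.5), 0.0, c[0])
        assert lat == pytest.approx(10.0, abs=0.5)
        assert lat / ap == pytest.approx(1.0, abs=0.1)

    def test_crescent_fallback_warns(self):
        sl = np.zeros((20, 20), bool)
        sl[12:18, 5:15] = True          # off to one side of x=0 column
        with pytest.warns(UserWarning, match="centroid"):
            lat, ap = mm.mca_dimensions(sl, (1.0, 1.0), 0.0, 0.0)
        assert lat == 6.0 and ap == 10.0

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            mm.mca_dimensions(np.zeros((5, 5), bool), (1, 1), 0.0)


class TestDeriveParameters:
    def test_mean_csa(self):
        mean_csa, *_ = mm.derive_parameters(100.0, 10.0, 50.0, 5.0, 2.0, 1.0)
        assert mean_csa == pytest.approx(10.0)

    def test_sphere_sphericity_exact(self):
        r = 7.3
        V = 4 / 3 * np.pi * r**3
        SA = 4 * np.pi * r**2
        *_, sph = mm.derive_parameters(V, 2 * r, SA, 1.0, 1.0, 1.0)
        assert sph == pytest.approx(1.0, abs=1e-12)

    def test_cylinder_height_equals_diameter(self):
        r = 1.0
        V = np.pi * r**2 * 2 * r
        SA = 2 * np.pi * r * 2 * r + 2 * np.pi * r**2
        assert mm.sphericity_from(V, SA) == pytest.approx(CYL_SPHERICITY,
                                                          rel=1e-12)
        assert CYL_SPHERICITY == pytest.approx(0.8736, abs=5e-5)

    @pytest.mark.parametrize("L,AP,SA", [(0.0, 1.0, 1.0), (1.0, 0.0, 1.0),
                                         (1.0, 1.0, 0.0)])
    def test_zero_denominators_raise(self, L, AP, SA):
        with pytest.raises(UndefinedParameterError):
            mm.derive_parameters(10.0, L, SA, 5.0, 2.0, AP)


class TestSphericityConvergence:
    def test_monotone_to_one(self):
        devs = []
        for sp in (1.0, 0.5, 0.25):
            mask = make_sphere_mask(6.0, sp)
            V = mm.measure_volume(mask)
            _, sac = mm.measure_surface(mask)
            devs.append(abs(mm.sphericity_from(V, sac) - 1.0))
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.01


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 13, 3))
        data = rng.random(shape) < 0.4
        data[..., [0, -1]] |= True      # keep end slices busy
        spacing = tuple(rng.uniform(0.4, 1.2, 3).round(2))
        z_top = (shape[2] - 1) * spacing[2]
        mask = AirwayMask(data, spacing, (0, 0, 0), z_top=z_top, z_bottom=0.0)

        assert mm.measure_volume(mask) == pytest.approx(brute_volume(mask),
                                                        rel=1e-12)
        profile = mm.cross_section_profile(mask)
        expected = brute_profile(mask)
        for k, area in zip(profile.slice_index, profile.area):
            assert area == pytest.approx(expected[int(k)], rel=1e-12)
        if (profile.area > 0).all():
            mca, _ = mm.find_mca(profile)
            assert mca == pytest.approx(min(expected.values()), rel=1e-12)

        k = int(profile.slice_index[0])
        sl = mask.data[:, :, k]
        if sl.any():
            i_mid = int(np.round(np.nonzero(sl)[0].mean()))
            lat_b, ap_b = brute_lat_ap(sl, spacing[0], spacing[1], i_mid)
            x_mid = i_mid * spacing[0]
            lat, ap = mm.mca_dimensions(sl, spacing[:2], x_mid, 0.0)
            assert lat == pytest.approx(lat_b, rel=1e-12)
            if ap_b is not None:
                assert ap == pytest.approx(ap_b, rel=1e-12)


class TestParameterInvariants:
    def test_uniformity_in_unit_interval(self, measured_phantom):
        records, _, _, _ = measured_phantom
        for rec in records:
            assert 0 < rec.uniformity <= 1.0 + 0.01

    def test_sphericity_bounded(self, measured_phantom):
        records, _, _, _ = measured_phantom
        for rec in records:
            assert 0 < rec.sphericity <= 1.0 + 0.01

    def test_mca_total_is_region_min(self, measured_phantom):
        records, _, _, _ = measured_phantom
        by_tag = {r.region_tag: r for r in records}
        total = by_tag.pop("total")
        assert total.MCA == min(r.MCA for r in by_tag.values())
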