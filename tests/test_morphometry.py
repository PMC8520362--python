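"""Plane extraction, clock geometry and FWHM thickness measurement."""

import numpy as np
import pytest
from scipy import ndimage

from sonokr import (
    DomainError,
    GroundTruth,
    IntensityModel,
    MorphometryConfig,
    PhantomSpec,
    VoxelGrid,
    clock_to_angle,
    extract_plane,
    measure_complex,
    measure_thickness,
    rasterize_truth,
)
from sonokr.morphometry import PlaneSlice, estimate_ring_center


def annulus_slice(inner=5.0, outer=7.0, level=70.0, spacing=0.2, half=10.0,
                  blur_sigma=0.0, center=(0.0, 0.0)):
    """Synthetic axial slice holding one ring of the given radii."""
    n = int(round(2 * half / spacing)) + 1
    origin = np.array([-half + center[0], -half + center[1]])
    xs = origin[0] + spacing * np.arange(n)
    ys = origin[1] + spacing * np.arange(n)
    xx, yy = np.meshgrid(xs - center[0], ys - center[1], indexing="ij")
    r = np.hypot(xx, yy)
    data = np.where((r >= inner) & (r < outer), level, 0.0)
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, blur_sigma / spacing)
    return PlaneSlice(data=data, spacing=np.array([spacing, spacing]),
                      origin=origin, z_mm=0.0, index=0)


MODEL = IntensityModel(levels={"background": 0.0, "EAS": 40.0, "IAS": 70.0, "PRM": 100.0})


class TestExtractPlane:
    def _vol(self, nz):
        data = np.tile(np.arange(nz, dtype=float), (4, 4, 1))
        return VoxelGrid(data=data, spacing=[1, 1, 1], origin=[0, 0, 0])

    def test_mid_plane_of_odd_stack_is_central_slice(self):
        sl = extract_plane(self._vol(11), "mid")
        assert sl.index == 5
        np.testing.assert_array_equal(sl.data, self._vol(11).data[:, :, 5])

    def test_configurable_fraction_floors(self):
        sl = extract_plane(self._vol(100), "mid", fraction=0.25)
        assert sl.index == 24  # floor(0.25 * 99)

    def test_named_fractions(self):
        vol = self._vol(101)
        assert extract_plane(vol, "proximal").index == 80
        assert extract_plane(vol, "mid").index == 50
        assert extract_plane(vol, "distal").index == 20

    def test_unknown_plane_rejected(self):
        with pytest.raises(DomainError):
            extract_plane(self._vol(5), "apex")


class TestClockToAngle:
    @pytest.mark.parametrize("clock,angle", [(12, 90.0), (3, 0.0), (6, -90.0),
                                             (9, 180.0), (4, -30.0), (8, -150.0)])
    def test_convention(self, clock, angle):
        assert clock_to_angle(clock) == pytest.approx(angle)

    @pytest.mark.parametrize("clock", [0, 13, -1])
    def test_out_of_range_rejected(self, clock):
        with pytest.raises(DomainError):
            clock_to_angle(clock)


class TestMeasureThickness:
    def test_ideal_annulus_all_clock_positions(self):
        sl = annulus_slice()
        for clock in range(1, 13):
            prof = measure_thickness(sl, (0.0, 0.0), clock, "IAS", MODEL)
            assert prof.thickness_mm == pytest.approx(2.0, abs=0.1)

    def test_uniform_slice_is_missing_everywhere(self):
        sl = PlaneSlice(data=np.zeros((50, 50)), spacing=np.array([0.2, 0.2]),
                        origin=np.array([-5.0, -5.0]), z_mm=0.0, index=0)
        for clock in (3, 6, 9, 12):
            prof = measure_thickness(sl, (0.0, 0.0), clock, "IAS", MODEL)
            assert prof.missing
            assert prof.reason

    def test_blurred_annulus_matches_1d_fwhm_oracle(self):
        # oracle: dense analytic 1D profile of the blurred ring along +x,
        # FWHM located by direct half-maximum crossings
        inner, outer, level, sigma = 5.0, 7.0, 70.0, 0.3
        sl = annulus_slice(inner, outer, level, spacing=0.2, blur_sigma=sigma)
        step = 0.05
        prof = measure_thickness(sl, (0.0, 0.0), 3, "IAS", MODEL, step=step)

        r = np.arange(0.0, 9.5, 0.001)
        img = sl.sample(np.column_stack([r, np.zeros_like(r)]))
        half = level / 2
        above = img >= half
        idx = np.flatnonzero(np.diff(above.astype(int)))
        assert len(idx) >= 2
        entry = np.interp(half, [img[idx[0]], img[idx[0] + 1]], [r[idx[0]], r[idx[0] + 1]])
        exit_ = np.interp(half, [img[idx[-1] + 1], img[idx[-1]]], [r[idx[-1] + 1], r[idx[-1]]])
        oracle = exit_ - entry
        assert prof.thickness_mm == pytest.approx(oracle, abs=step)

    def test_abutting_rings_measured_separately(self):
        # IAS ring 5-7 mm at level 70 with EAS ring 7-9 mm at level 40:
        # the shared wall must split at the half-way level between tissues
        sl = annulus_slice(5.0, 7.0, 70.0)
        eas = annulus_slice(7.0, 9.0, 40.0)
        merged = PlaneSlice(data=sl.data + eas.data, spacing=sl.spacing,
                            origin=sl.origin, z_mm=0.0, index=0)
        ias = measure_thickness(merged, (0.0, 0.0), 12, "IAS", MODEL)
        eas_m = measure_thickness(merged, (0.0, 0.0), 12, "EAS", MODEL)
        assert ias.thickness_mm == pytest.approx(2.0, abs=0.1)
        assert eas_m.thickness_mm == pytest.approx(2.0, abs=0.1)

    def test_ray_leaving_slice_before_far_edge_is_missing(self):
        sl = annulus_slice(inner=5.0, outer=12.0, half=10.0)  # ring exits the slice
        prof = measure_thickness(sl, (0.0, 0.0), 3, "IAS", MODEL)
        assert prof.missing

    def test_center_outside_slice_rejected(self):
        sl = annulus_slice()
        with pytest.raises(DomainError):
            measure_thickness(sl, (100.0, 0.0), 3, "IAS", MODEL)


class TestRingCenter:
    def test_centroid_recovers_offset_center(self):
        sl = annulus_slice(center=(1.4, -0.8))
        est = estimate_ring_center(sl, MODEL)
        np.testing.assert_allclose(est, [1.4, -0.8], atol=0.05)


@pytest.fixture(scope="module")
def raster_volume():
    spec = PhantomSpec()
    grid = VoxelGrid.from_box(*spec.box, 0.2)
    truth = GroundTruth(spec=spec)
    return rasterize_truth(truth, grid), spec


class TestMeasureComplex:

    def test_noiseless_phantom_gives_18_complete_rows(self, raster_volume):
        vol, spec = raster_volume
        table = measure_complex(vol, MorphometryConfig(intensity_model=MODEL))
        assert len(table) == 18
        assert table["thickness_mm"].notna().all()
        counts = table.groupby("structure").size().to_dict()
        assert counts == {"IAS": 12, "EAS": 4, "PRM": 2}

    def test_ias_rows_within_half_voxel_of_spec(self, raster_volume):
        vol, spec = raster_volume
        table = measure_complex(vol, MorphometryConfig(intensity_model=MODEL))
        ias = table[table["structure"] == "IAS"]
        assert np.allclose(ias["thickness_mm"], spec.ias_thickness, atol=0.1)

    def test_row_count_invariant_under_translation(self, raster_volume):
        vol, _ = raster_volume
        moved = VoxelGrid(data=vol.data, spacing=vol.spacing,
                          origin=vol.origin + [30.0, -12.0, 5.0])
        table = measure_complex(moved, MorphometryConfig(intensity_model=MODEL))
        assert len(table) == 18
        assert table["thickness_mm"].notna().all()

    def test_rotation_maps_clock_positions(self):
        # anatomy rotated clockwise by 3 hours: measurements shift 3 positions
        spec = PhantomSpec()
        base = GroundTruth(spec=spec)

        class Rotated(GroundTruth):
            def field(self, p):
                p = np.atleast_2d(np.asarray(p, float))
                q = np.column_stack([-p[:, 1], p[:, 0], p[:, 2]])
                return GroundTruth.field(self, q)

        grid = VoxelGrid.from_box(*spec.box, 0.25)
        vol_a = rasterize_truth(base, grid)
        vol_b = rasterize_truth(Rotated(spec=spec), grid)
        cfg = MorphometryConfig(intensity_model=MODEL)
        ta = measure_complex(vol_a, cfg).set_index(["structure", "plane", "clock"])
        tb = measure_complex(vol_b, cfg).set_index(["structure", "plane", "clock"])
        for clock_a, clock_b in [(12, 3), (3, 6), (6, 9), (9, 12)]:
            a = ta.loc[("IAS", "mid", clock_a), "thickness_mm"]
            b = tb.loc[("IAS", "mid", clock_b), "thickness_mm"]
            assert b == pytest.approx(a, abs=0.25)  # one voxel

    def test_thickness_tracks_wall_not_radius(self):
        # doubling the radius at fixed wall thickness must not change the
        # measurement; doubling the wall thickness must double it
        cfg = MorphometryConfig(intensity_model=MODEL)
        for spec, expected in [
            (PhantomSpec(ias_inner_radius=10.0), 2.0),
            (PhantomSpec(ias_thickness=4.0), 4.0),
        ]:
            grid = VoxelGrid.from_box(*spec.box, 0.25)
            vol = rasterize_truth(GroundTruth(spec=spec), grid)
            table = measure_complex(vol, cfg)
            ias = table[(table["structure"] == "IAS") & (table["plane"] == "proximal")]
            assert np.allclose(ias["thickness_mm"], expected, atol=0.13)
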