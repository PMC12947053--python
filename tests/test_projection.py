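"""Spherical slice deformation: origin grids, forward/inverse remap."""

import numpy as np
import pytest

from sphereseg import (
    ProjectionOrigin,
    ProjectionParams,
    back_project,
    generate_origin_grid,
    project_ensemble,
    project_slice,
)


def smooth_image(h=64, w=64):
    y, x = np.mgrid[:h, :w]
    return np.exp(-((x - w * 0.55) ** 2 + (y - h * 0.45) ** 2) / (0.05 * h * w))


class TestOriginGrid:
    @pytest.mark.parametrize(
        "h,w,interval,expected",
        [(256, 256, 8, 1024), (8, 8, 8, 1), (16, 16, 8, 4), (64, 64, 16, 16)],
    )
    def test_counts(self, h, w, interval, expected):
        assert len(generate_origin_grid(h, w, interval)) == expected

    def test_positions_match_enumeration(self):
        got = generate_origin_grid(16, 16, 8)
        expected = [
            ProjectionOrigin(r, c) for r in (4, 12) for c in (4, 12)
        ]
        assert got == expected

    def test_roi_filtering_and_empty_error(self):
        roi = np.zeros((16, 16), dtype=np.uint8)
        roi[4, 4] = 1
        assert generate_origin_grid(16, 16, 8, roi) == [ProjectionOrigin(4, 4)]
        with pytest.raises(ValueError, match="denser"):
            generate_origin_grid(16, 16, 8, np.zeros((16, 16), dtype=np.uint8))

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            generate_origin_grid(16, 16, 0)
        with pytest.raises(ValueError):
            generate_origin_grid(16, 16, 32)


class TestForwardMap:
    def test_constant_field_preserved_in_domain(self):
        """Remapping preserves constant fields wherever every bilinear
        support pixel of the source sample is inside the image."""
        img = np.full((32, 32), 0.6)
        radius = 32.0
        params = ProjectionParams(radius=radius, fill=-1.0)
        out = project_slice(img, ProjectionOrigin(16, 16), params).data
        rr, cc = np.meshgrid(np.arange(32.0), np.arange(32.0), indexing="ij")
        rho = np.hypot(rr - 16, cc - 16)
        # source radius stays >= 1 px inside the border around the origin
        in_domain = rho < radius * np.arctan(14.0 / radius)
        assert in_domain.any()
        np.testing.assert_allclose(out[in_domain], 0.6)

    def test_origin_pixel_fixed_point(self):
        img = smooth_image()
        out = project_slice(img, ProjectionOrigin(20, 40), ProjectionParams(radius=24)).data
        assert out[20, 40] == pytest.approx(img[20, 40], abs=1e-12)

    def test_identity_limit_large_radius(self):
        """s(rho) = R tan(rho/R) -> rho as R -> inf, so the map -> identity."""
        img = smooth_image()
        out = project_slice(img, ProjectionOrigin(30, 31), ProjectionParams(radius=1e6)).data
        assert np.abs(out - img).max() < 1e-6
        # analytic displacement bound: max |s - rho| < 0.01 px over the slice
        rho_max = np.hypot(63, 63)
        assert abs(1e6 * np.tan(rho_max / 1e6) - rho_max) < 0.01

    def test_displacement_monotone_in_radius(self):
        img = smooth_image()
        origin = ProjectionOrigin(32, 32)
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        rho = np.hypot(rr - 32, cc - 32)
        prev = None
        for radius in (32.0, 64.0, 128.0, 1024.0):
            valid = rho < np.pi * radius / 2
            s = radius * np.tan(rho[valid] / radius)
            disp = np.max(np.abs(s - rho[valid]))
            if prev is not None:
                assert disp < prev
            prev = disp

    def test_local_scale_magnifies_center(self):
        """ds/drho = sec^2(rho/R): 1 at the origin, strictly increasing."""
        radius = 40.0
        rho = np.linspace(0, np.pi * radius / 2 * 0.95, 200)
        h = 1e-5

        def s(r):
            return radius * np.tan(r / radius)

        ds = (s(rho + h) - s(rho - h)) / (2 * h)
        assert ds[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(ds) > 0)
        np.testing.assert_allclose(ds, 1 / np.cos(rho / radius) ** 2, rtol=1e-6)

    def test_tiny_radius_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            project_slice(smooth_image(), ProjectionOrigin(1, 1), ProjectionParams(radius=0.5))

    def test_channel_equivariance(self, rng):
        stack = rng.random((4, 32, 32))
        params = ProjectionParams(radius=24)
        origin = ProjectionOrigin(10, 12)
        multi = project_slice(stack, origin, params).data
        for c in range(4):
            single = project_slice(stack[c], origin, params).data
            np.testing.assert_array_equal(multi[c], single)


class TestBackProjection:
    def test_round_trip_smooth_image(self):
        img = smooth_image()
        params = ProjectionParams(radius=64)
        origin = ProjectionOrigin(30, 31)
        deformed = project_slice(img, origin, params).data
        back, valid = back_project(np.clip(deformed, 0, 1), origin, params)
        interior = np.zeros_like(valid)
        interior[5:-5, 5:-5] = True
        mae = np.abs(back - img)[valid & interior].mean()
        assert mae < 0.02

    def test_constant_prediction_preserved(self):
        params = ProjectionParams(radius=32)
        pred = np.full((32, 32), 0.7)
        back, valid = back_project(pred, ProjectionOrigin(16, 16), params)
        np.testing.assert_allclose(back[valid], 0.7)

    def test_nearest_preserves_binary_values(self, rng):
        params = ProjectionParams(radius=32, order=0)
        pred = (rng.random((32, 32)) > 0.5).astype(float)
        back, _ = back_project(pred, ProjectionOrigin(11, 21), params)
        assert set(np.unique(back)) <= {0.0, 1.0}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            back_project(np.zeros((8, 9)), ProjectionOrigin(2, 2),
                         ProjectionParams(radius=16, output_shape=(8, 8)))

    def test_output_clamped_to_unit_interval(self):
        pred = np.full((16, 16), 1.0)
        back, valid = back_project(pred, ProjectionOrigin(8, 8), ProjectionParams(radius=16))
        assert back.max() <= 1.0 and back.min() >= 0.0


class TestEnsemble:
    def test_matches_independent_projection(self, rng):
        stack = rng.random((4, 24, 24))
        params = ProjectionParams(radius=20)
        origins = generate_origin_grid(24, 24, 12)
        ensemble = project_ensemble(stack, origins, params)
        assert len(ensemble) == len(origins) == 4
        for ds, origin in zip(ensemble, origins):
            np.testing.assert_array_equal(
                ds.data, project_slice(stack, origin, params).data
            )

    def test_empty_origin_list_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            project_ensemble(rng.random((4, 8, 8)), [], ProjectionParams(radius=8))
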