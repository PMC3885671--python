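"""Plug-in bandwidth, kernel UD surfaces, isopleths, and home-range metrics,
each checked against an independent closed-form or brute-force oracle."""

import numpy as np
import pytest
from shapely.geometry import box

from urbanbear import (Landscape, isopleth, kde_at, kde_surface,
                       normal_scale_bandwidth, plugin_bandwidth)
from urbanbear.homerange import UDSurface, hr_metrics


@pytest.fixture(scope="module")
def gaussian_sample():
    return np.random.default_rng(42).standard_normal((5000, 2))


class TestPluginBandwidth:
    def test_close_to_gaussian_oracle(self, gaussian_sample):
        """On bivariate-normal data the plug-in matrix should land within
        15% (Frobenius) of the closed-form normal-scale optimum
        H = n^(-1/3) Sigma."""
        H = plugin_bandwidth(gaussian_sample)
        H_ns = normal_scale_bandwidth(gaussian_sample)
        rel = np.linalg.norm(H - H_ns) / np.linalg.norm(H_ns)
        assert rel < 0.15

    def test_scaling_equivariance(self, gaussian_sample):
        x = gaussian_sample[:800]
        H1 = plugin_bandwidth(x)
        H2 = plugin_bandwidth(2.0 * x)
        np.testing.assert_allclose(H2, 4.0 * H1, rtol=1e-8)

    def test_shrinks_with_n(self, gaussian_sample):
        H_big = plugin_bandwidth(gaussian_sample[:4000])
        H_small = plugin_bandwidth(gaussian_sample[:250])
        assert np.trace(H_big) < np.trace(H_small)

    def test_spd_output(self, gaussian_sample):
        H = plugin_bandwidth(gaussian_sample[:500])
        assert np.allclose(H, H.T)
        assert (np.linalg.eigvalsh(H) > 0).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10 distinct"):
            plugin_bandwidth(np.random.default_rng(0).normal(size=(9, 2)))

    def test_degenerate_collinear_rejected(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            plugin_bandwidth(np.column_stack([t, 2 * t]))


class TestKDESurface:
    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(400, 2))
        H = np.array([[0.09, 0.02], [0.02, 0.06]])
        surf = kde_surface(x, H, grid_size=100)
        xs, ys = surf.cell_centers()
        ii = rng.integers(0, 100, size=100)
        jj = rng.integers(0, 100, size=100)
        where = np.column_stack([xs[jj], ys[ii]])
        direct = kde_at(x, H, where)
        rel = np.abs(surf.density[ii, jj] - direct) / direct
        assert rel.max() < 1e-6

    def test_integrates_to_one(self):
        x = np.random.default_rng(8).normal(size=(300, 2))
        surf = kde_surface(x, 0.1 * np.eye(2), grid_size=150)
        assert abs(surf.total_mass() - 1.0) < 0.01

    def test_single_point_peak_at_point(self):
        surf = kde_surface(np.array([[1.0, 2.0]]), 0.5 * np.eye(2), grid_size=60)
        iy, ix = np.unravel_index(surf.density.argmax(), surf.density.shape)
        xs, ys = surf.cell_centers()
        assert abs(xs[ix] - 1.0) <= surf.cell
        assert abs(ys[iy] - 2.0) <= surf.cell

    def test_two_clusters_give_two_modes(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 0.3, (200, 2)),
                       rng.normal(6, 0.3, (200, 2))])
        H = 0.2 * np.eye(2)
        # brute-force oracle: density at the cluster centers dwarfs midpoint
        centers = np.array([[0.0, 0.0], [6.0, 6.0], [3.0, 3.0]])
        d = kde_at(x, H, centers)
        assert d[0] > 10 * d[2] and d[1] > 10 * d[2]
        surf = kde_surface(x, H, grid_size=120)
        geom, _ = isopleth(surf, 0.95)
        assert geom.geom_type == "MultiPolygon"

    def test_coarse_grid_warns(self):
        x = np.random.default_rng(1).normal(size=(50, 2))
        with pytest.warns(UserWarning, match="under-resolved"):
            kde_surface(x, 0.0001 * np.eye(2), grid_size=20)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            kde_surface(np.zeros((5, 2)), np.array([[1.0, 2.0], [2.0, 1.0]]))


def analytic_normal_surface(grid_size=220, half_width=5.0):
    """UD surface holding the exact standard bivariate normal density."""
    cell = 2 * half_width / grid_size
    xs = -half_width + (np.arange(grid_size) + 0.5) * cell
    gx, gy = np.meshgrid(xs, xs)
    dens = np.exp(-0.5 * (gx ** 2 + gy ** 2)) / (2 * np.pi)
    return UDSurface(x0=-half_width, y0=-half_width, cell=cell, density=dens,
                     bandwidth=np.eye(2), n_points=1)


class TestIsopleth:
    def test_gaussian_95_area_matches_ellipse(self):
        """The 95% superlevel set of a standard bivariate normal is a disk of
        area pi * chi2_2(0.95) ~ 5.991 pi."""
        surf = analytic_normal_surface()
        geom, _ = isopleth(surf, 0.95)
        oracle = np.pi * 5.991464547107979
        assert abs(geom.area - oracle) / oracle < 0.05

    def test_enclosed_mass_convention(self):
        surf = analytic_normal_surface()
        geom, mask = isopleth(surf, 0.95)
        mass = surf.density[mask].sum() * surf.cell_area
        total = surf.density.sum() * surf.cell_area
        cell_mass = surf.density.max() * surf.cell_area
        assert 0.95 * total <= mass <= 0.95 * total + cell_mass

    def test_two_equal_modes_split_mass(self):
        grid = 200
        cell = 16.0 / grid
        xs = -8.0 + (np.arange(grid) + 0.5) * cell
        gx, gy = np.meshgrid(xs, xs)
        d = (np.exp(-0.5 * ((gx + 4) ** 2 + gy ** 2))
             + np.exp(-0.5 * ((gx - 4) ** 2 + gy ** 2))) / (4 * np.pi)
        surf = UDSurface(x0=-8.0, y0=-8.0, cell=cell, density=d,
                         bandwidth=np.eye(2), n_points=2)
        geom, mask = isopleth(surf, 0.95)
        assert geom.geom_type == "MultiPolygon" and len(geom.geoms) == 2
        mass = surf.density[mask].sum() * surf.cell_area
        assert mass == pytest.approx(0.95, abs=0.01)

    def test_monotone_in_level(self):
        surf = analytic_normal_surface(grid_size=120)
        a95, _ = isopleth(surf, 0.95)
        a50, _ = isopleth(surf, 0.50)
        a9999, _ = isopleth(surf, 0.9999)
        assert a95.area >= a50.area
        # near level 1 the polygon approaches the full support
        assert a9999.area > a95.area

    def test_level_outside_unit_interval_rejected(self):
        surf = analytic_normal_surface(grid_size=50)
        with pytest.raises(ValueError):
            isopleth(surf, 1.5)


def flat_landscape(points, extent=(0, 0, 10_000, 10_000)):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return Landscape(address_points=pts, structure_points=pts,
                     urban_center=(5000, 5000), wildland_center=(8000, 8000),
                     extent=extent)


class TestHRMetrics:
    def test_square_without_structures(self):
        hr = box(4000, 4000, 6000, 6000)  # 2 km x 2 km
        empty = Landscape(address_points=np.empty((0, 2)),
                          structure_points=np.empty((0, 2)),
                          urban_center=(0, 0), wildland_center=(1, 1),
                          extent=(0, 0, 10_000, 10_000))
        with pytest.warns(UserWarning, match="empty landscape"):
            area, overlap, dens = hr_metrics(hr, empty)
        assert (area, overlap, dens) == (4.0, 0.0, 0.0)

    def test_single_structure_buffer_disk_area(self):
        """One structure deep inside a big polygon: the development overlap
        is one 50-m disk, pi * 0.05^2 ~ 0.007854 km^2."""
        hr = box(0, 0, 10_000, 10_000)
        land = flat_landscape([[5000.0, 5000.0]])
        _, overlap, _ = hr_metrics(hr, land)
        assert overlap == pytest.approx(np.pi * 0.05 ** 2, rel=0.01)

    def test_uniform_field_density(self):
        """A uniform 100-address/km^2 field measured through the 1-km^2
        moving window averages ~100 over home-range cells."""
        rng = np.random.default_rng(17)
        side = 8000.0
        n = rng.poisson(100 * (side / 1000) ** 2)
        pts = rng.uniform(0, side, (n, 2))
        land = flat_landscape(pts, extent=(0, 0, side, side))
        hr = box(2000, 2000, 6000, 6000)  # >564 m inside the field edges
        _, _, dens = hr_metrics(hr, land)
        assert dens == pytest.approx(100.0, rel=0.05)
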