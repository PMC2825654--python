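"""Angular acceptance limits, acceptance tables and the forward model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from darkscatter.detection import CollimatorSpec, DetectorGrid
from darkscatter.phantom import BoxRegion, Phantom, build_table1_phantom
from darkscatter.physics import Material
from darkscatter.single_scatter import (
    AcceptanceGeometry,
    GeometryError,
    acceptance_probability,
    angular_limits,
    build_acceptance_table,
    single_scatter_image,
)


class TestAngularLimits:
    def test_cell_on_axis_with_zero_grid_height(self):
        t1, t2, p1, p2 = angular_limits(
            AcceptanceGeometry(H=0.0, D=0.2, R=2.5, r=0.1))
        assert t1 == 0.0
        assert t2 == pytest.approx(math.atan(0.2 / 2.5))

    def test_reference_geometry_values(self):
        # H=1.0, D=0.2, R=2.5, r=0.3: direct arctan evaluation
        t1, t2, p1, p2 = angular_limits(
            AcceptanceGeometry(H=1.0, D=0.2, R=2.5, r=0.3))
        assert t1 == pytest.approx(math.atan((0.3 - 0.1) / (2.5 - 1.0)))
        assert t2 == pytest.approx(math.atan((0.3 + 0.1) / 2.5))
        assert p2 == pytest.approx(math.atan(0.2 / 0.6))

    @pytest.mark.parametrize("r", [0.0, 0.05, 0.1, 0.5, 2.0])
    def test_phi_limits_symmetric(self, r):
        _, _, p1, p2 = angular_limits(
            AcceptanceGeometry(H=1.0, D=0.2, R=2.5, r=r))
        assert p1 == -p2

    def test_axis_overlapping_cell_subtends_full_azimuth(self):
        t1, _, p1, p2 = angular_limits(
            AcceptanceGeometry(H=1.0, D=0.2, R=2.5, r=0.05))
        assert t1 == 0.0
        assert (p2 - p1) == pytest.approx(2 * math.pi)

    def test_scatter_point_below_grid_top_rejected(self):
        with pytest.raises(GeometryError):
            AcceptanceGeometry(H=3.0, D=0.2, R=2.5, r=0.1)


class TestAcceptanceProbability:
    def test_empty_window_is_zero(self, physics50):
        water = Material("water", 0.028, 0.182, 0.0769)
        assert acceptance_probability((0.3, 0.3), (-0.1, 0.1), water,
                                      physics50) == 0.0

    def test_full_sphere_is_one(self, physics50):
        water = Material("water", 0.028, 0.182, 0.0769)
        val = acceptance_probability((0.0, math.pi), (-math.pi, math.pi),
                                     water, physics50)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_inverted_window_warns_and_returns_zero(self, physics50):
        water = Material("water", 0.028, 0.182, 0.0769)
        with pytest.warns(UserWarning, match="unreachable"):
            assert acceptance_probability((0.5, 0.3), (-0.1, 0.1), water,
                                          physics50) == 0.0

    def test_factorized_equals_2d_adaptive_quadrature(self, physics50):
        """The phi integrand is theta-independent, so the factorized form
        equals the full 2-D adaptive quadrature."""
        water = Material("water", 0.028, 0.182, 0.0769)
        rng = np.random.default_rng(7)
        for _ in range(5):
            t1, t2 = np.sort(rng.random(2) * 0.5)
            p2 = rng.random() * math.pi
            got = acceptance_probability((t1, t2), (-p2, p2), water, physics50)
            ref, _ = integrate.dblquad(
                lambda t, p: physics50.mixture_pdf(t, water) / (2 * math.pi),
                -p2, p2, t1, t2, epsabs=1e-12)
            assert got == pytest.approx(ref, abs=1e-8)

    def test_monte_carlo_hit_counting_cross_check(self, physics50, rng):
        """Statistical estimate of the same probability: draw (theta, phi)
        from the mixture density x uniform azimuth and count hits."""
        water = Material("water", 0.028, 0.182, 0.0769)
        geom = AcceptanceGeometry(H=2.0, D=0.2, R=5.0, r=0.2)
        t1, t2, p1, p2 = angular_limits(geom)
        expected = acceptance_probability((t1, t2), (p1, p2), water, physics50)
        n = 400_000
        n_ray = rng.binomial(n, water.beta)
        theta = np.concatenate([
            physics50.sample_rayleigh(rng, n_ray),
            physics50.sample_compton(rng, n - n_ray)])
        phi = rng.random(n) * 2 * math.pi - math.pi
        hits = ((theta >= t1) & (theta <= t2) & (phi >= p1) & (phi <= p2))
        est = hits.mean()
        se = math.sqrt(est * (1 - est) / n)
        assert abs(est - expected) < 4 * se + 1e-9


class TestAcceptanceTable:
    def test_reference_shape_250_by_5(self, table1_phantom, physics50):
        grid = DetectorGrid(60, 60, 0.2, plane_z=5.0)
        table = build_acceptance_table(table1_phantom, grid,
                                       CollimatorSpec(10.0, septa=True),
                                       physics50)
        assert table.shape == (250, 5)
        assert table.on_axis.min() >= 0.0
        assert table.values.max() <= 1.0

    def test_infinite_grid_height_blocks_everything(self, table1_phantom,
                                                    physics50):
        grid = DetectorGrid(60, 60, 0.2, plane_z=5.0)
        tall = CollimatorSpec(1e6, septa=True)   # H >> R for every depth
        table = build_acceptance_table(table1_phantom, grid, tall, physics50)
        assert np.all(table.values == 0.0)

    def test_high_rayleigh_material_accepts_more(self, table1_phantom,
                                                 physics50):
        """The collimator window concentrates where the Rayleigh density
        lives, so the Rayleigh-rich cube4 out-accepts cube1 at every depth
        (summed over reachable cells) -- the dark-field contrast mechanism."""
        grid = DetectorGrid(60, 60, 0.2, plane_z=5.0)
        table = build_acceptance_table(table1_phantom, grid,
                                       CollimatorSpec(10.0, septa=True),
                                       physics50)
        names = table.material_names
        i1, i4 = names.index("cube1"), names.index("cube4")
        summed = table.values.sum(axis=2)
        assert np.all(summed[:, i4] > summed[:, i1])
        # on axis the same holds once the window reaches past ~2 degrees
        # (deepest scattering points, shortest distance to the detector)
        assert table.on_axis[-1, i4] > table.on_axis[-1, i1]

    def test_entries_match_direct_acceptance_probability(self, table1_phantom,
                                                         physics50):
        """Spot-check quadrature table entries against the scalar operation."""
        grid = DetectorGrid(60, 60, 0.2, plane_z=5.0)
        col = CollimatorSpec(10.0, septa=True)
        table = build_acceptance_table(table1_phantom, grid, col, physics50)
        H, D = col.height(grid.pitch), grid.pitch
        water = table1_phantom.materials[0]
        for i in (0, 100, 249):
            R = grid.plane_z - table.depths[i]
            for k, (du, dv) in enumerate(table.offsets[:5]):
                r = D * math.hypot(du, dv)
                t1, t2, p1, p2 = angular_limits(
                    AcceptanceGeometry(H=H, D=D, R=R, r=r))
                if t1 >= t2:
                    expected = 0.0
                else:
                    expected = acceptance_probability((t1, t2), (p1, p2),
                                                      water, physics50)
                assert table.values[i, 0, k] == pytest.approx(
                    expected, abs=2e-6)

    def test_mc_table_probabilities_valid(self, table1_phantom, physics50):
        grid = DetectorGrid(60, 60, 0.2, plane_z=5.0)
        table = build_acceptance_table(table1_phantom, grid,
                                       CollimatorSpec(10.0, septa=True),
                                       physics50, method="mc",
                                       n_samples=2000, seed=9)
        assert table.method == "mc"
        assert table.values.min() >= 0.0
        assert table.values.max() <= 1.0
        # acceptance mass exists and stays below the no-collimator bound
        sums = table.values.sum(axis=2)
        assert sums.max() <= 1.0
        assert sums.min() > 0.0

    def test_indivisible_depth_step_rejected(self, table1_phantom, physics50):
        grid = DetectorGrid(60, 60, 0.2, plane_z=5.0)
        with pytest.raises(ValueError, match="divisible"):
            build_acceptance_table(table1_phantom, grid,
                                   CollimatorSpec(10.0, septa=True),
                                   physics50, depth_step=0.7)


def _small_grid(plane_z=5.0):
    return DetectorGrid(20, 20, 0.5, plane_z=plane_z)


class TestSingleScatterImage:
    def test_zero_scattering_gives_zero_image(self, physics50):
        absorber = Material("absorber", 0.21, 0.0, 0.0)
        ph = Phantom(BoxRegion((-5, -5, -2.5), (5, 5, 2.5), absorber))
        grid = _small_grid()
        col = CollimatorSpec(10.0, septa=True)
        table = build_acceptance_table(ph, grid, col, physics50,
                                       depth_step=0.25)
        img = single_scatter_image(ph, grid, col, physics50, table)
        assert np.all(img == 0.0)

    def test_missing_table_rejected(self, table1_phantom, physics50):
        with pytest.raises(ValueError, match="table"):
            single_scatter_image(table1_phantom, _small_grid(),
                                 CollimatorSpec(10.0, septa=True), physics50,
                                 None)

    def test_mismatched_table_rejected(self, table1_phantom, physics50):
        col = CollimatorSpec(10.0, septa=True)
        table = build_acceptance_table(table1_phantom, _small_grid(), col,
                                       physics50, depth_step=0.25)
        other = DetectorGrid(20, 20, 0.5, plane_z=20.0)
        with pytest.raises(ValueError, match="different grid"):
            single_scatter_image(table1_phantom, other, col, physics50, table)

    def test_monotone_in_grid_height(self, table1_phantom, physics50):
        """Raising the collimator (larger aspect ratio, same aperture) can
        only reduce the predicted image, pixel by pixel."""
        grid = _small_grid()
        imgs = []
        for ratio in (4.0, 6.0, 8.0):
            col = CollimatorSpec(ratio, septa=True)
            table = build_acceptance_table(table1_phantom, grid, col,
                                           physics50, depth_step=0.25)
            imgs.append(single_scatter_image(table1_phantom, grid, col,
                                             physics50, table))
        assert np.all(imgs[1] <= imgs[0] + 1e-15)
        assert np.all(imgs[2] <= imgs[1] + 1e-15)
        assert imgs[0].mean() > imgs[2].mean() > 0.0

    def test_thin_limit_matches_independent_projection(self, physics50):
        """With coefficients scaled by 1e-3 the attenuation factors drop
        out and the image reduces to the acceptance-weighted projection of
        mu_s, accumulated here by an independent brute-force loop."""
        scale = 1e-3
        water = Material("water", 0.028 * scale, 0.182 * scale, 0.0769)
        cube = Material("cube4", 0.028 * scale, 0.182 * scale, 0.2858)
        bg = BoxRegion((-5, -5, -2.5), (5, 5, 2.5), water)
        inc = BoxRegion((-0.5, -0.5, -0.5), (0.5, 0.5, 0.5), cube)
        ph = Phantom(bg, [inc])
        grid = DetectorGrid(12, 12, 0.5, plane_z=5.0)
        col = CollimatorSpec(4.0, septa=True)    # H = 2 cm < every R
        table = build_acceptance_table(ph, grid, col, physics50,
                                       depth_step=0.5)
        img = single_scatter_image(ph, grid, col, physics50, table)

        i0 = 0.5 ** 2 / 100.0
        depths = -2.5 + (np.arange(10) + 0.5) * 0.5
        u, v = grid.pixel_centers()
        H, D = col.height(grid.pitch), grid.pitch
        acc_cache: dict = {}

        def acc_for(mat, R, r):
            key = (mat.name, round(R, 9), round(r, 9))
            if key not in acc_cache:
                t1, t2, p1, p2 = angular_limits(
                    AcceptanceGeometry(H=H, D=D, R=R, r=r))
                acc_cache[key] = 0.0 if t1 >= t2 else acceptance_probability(
                    (t1, t2), (p1, p2), mat, physics50)
            return acc_cache[key]

        ref = np.zeros((12, 12))
        for iz, z in enumerate(depths):
            R = grid.plane_z - z
            for iv, y in enumerate(v):
                for iu, x in enumerate(u):
                    mat = ph.material_at((x, y, z))
                    if mat.mu_s == 0.0:
                        continue
                    for du, dv in table.offsets:
                        ju, jv = iu + du, iv + dv
                        if not (0 <= ju < 12 and 0 <= jv < 12):
                            continue
                        acc = acc_for(mat, R, D * math.hypot(du, dv))
                        if acc:
                            ref[jv, ju] += i0 * mat.mu_s * 0.5 * acc
        np.testing.assert_allclose(img, ref, rtol=2e-3, atol=1e-15)
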