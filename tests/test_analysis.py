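"""Shape descriptors, contact maps, bond correlations and condensation."""

import math

import numpy as np
import pytest

from ringpe import analysis
from ringpe.fixtures import make_loop, make_toroid


def circle(n=200, radius=10.0):
    phi = 2 * math.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                            np.zeros(n)])


class TestRadiusOfGyration:
    def test_coincident_points(self):
        assert analysis.radius_of_gyration(np.ones((5, 3))) == 0.0

    def test_circle_equals_radius(self):
        assert analysis.radius_of_gyration(circle(radius=7.5)) == pytest.approx(7.5)

    def test_matches_direct_sum(self, rng):
        pts = rng.normal(size=(10, 3))
        c = pts.mean(axis=0)
        direct = math.sqrt(np.mean([(p - c) @ (p - c) for p in pts]))
        assert analysis.radius_of_gyration(pts) == pytest.approx(direct)


class TestShapeFactor:
    def test_rod_is_one(self):
        rod = np.zeros((50, 3))
        rod[:, 0] = np.linspace(0, 10, 50)
        assert analysis.shape_factor(rod) == pytest.approx(1.0)

    def test_cube_vertices_are_zero(self):
        cube = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                        dtype=float)
        assert analysis.shape_factor(cube) == pytest.approx(0.0, abs=1e-12)

    def test_planar_circle_is_quarter(self):
        assert analysis.shape_factor(circle()) == pytest.approx(0.25, abs=1e-6)

    def test_rotation_translation_invariant(self, rng):
        pts = rng.normal(size=(30, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=3).as_matrix()
        moved = pts @ R.T + np.array([5.0, -2.0, 1.0])
        assert analysis.shape_factor(moved) == pytest.approx(
            analysis.shape_factor(pts), rel=1e-9)
        assert analysis.radius_of_gyration(moved) == pytest.approx(
            analysis.radius_of_gyration(pts), rel=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            analysis.shape_factor(np.zeros((4, 3)))


class TestContactMap:
    def test_circle_has_no_contacts(self):
        coords, _ = make_loop(200)
        cmap = analysis.contact_map(coords)
        assert not cmap.any()

    def test_symmetric_and_banded(self):
        coords, _ = make_toroid(200, k=3)
        cmap = analysis.contact_map(coords)
        assert np.array_equal(cmap, cmap.T)
        sep = analysis.cyclic_separation(200)
        assert not cmap[sep <= 2].any()

    def test_matches_brute_force_thresholding(self, rng):
        pts = rng.uniform(0, 4, size=(10, 3))
        cmap = analysis.contact_map(pts, cutoff=2.0, min_sep=1)
        for i in range(10):
            for j in range(10):
                sep = min(abs(i - j), 10 - abs(i - j))
                expect = (np.linalg.norm(pts[i] - pts[j]) < 2.0) and sep > 1
                assert cmap[i, j] == expect


class TestBondCorrelation:
    def test_regular_polygon_is_cosine(self):
        n = 120
        curve = analysis.bond_correlation(circle(n=n, radius=n * 1.12 / (2 * math.pi)))
        s = np.arange(1, n // 2 + 1)
        assert np.allclose(curve, np.cos(2 * math.pi * s / n), atol=1e-9)

    def test_polygon_antipodal_bonds_antiparallel(self):
        n = 100
        curve = analysis.bond_correlation(circle(n=n))
        assert curve[n // 2 - 1] == pytest.approx(-1.0, abs=1e-9)

    def test_toroid_periodicity_equals_windings(self):
        for k in (2, 3, 4, 5):
            coords, _ = make_toroid(200, k=k)
            assert analysis.count_torus_rings(coords) == k


class TestTorusRings:
    def test_circle_is_single_period(self):
        assert analysis.count_torus_rings(circle()) == 1

    def test_noisy_toroid_recovered(self):
        coords, _ = make_toroid(200, k=2, noise=0.2, seed=17)
        assert analysis.count_torus_rings(coords) == 2

    def test_winding_number_cross_check(self):
        for k in (2, 3, 5):
            coords, _ = make_toroid(200, k=k)
            assert analysis.winding_number(coords) == k

    def test_aperiodic_signal_flagged(self, rng):
        # white-noise correlation curve has a flat spectrum
        curve = rng.normal(0, 0.05, size=100)
        with pytest.raises(analysis.AperiodicSignalError):
            analysis.count_torus_rings(curve, n=200)


class TestCondensedCations:
    def test_none_within_threshold(self):
        mono = circle(50, radius=9.0) + 20.0
        cations = np.full((5, 3), 2.0)
        assert analysis.count_condensed_cations(cations, mono, 60.0) == 0

    def test_constructed_counts(self):
        mono = circle(50, radius=9.0) + 20.0
        near = mono[0] + np.array([0.5, 0.0, 0.0])
        far = mono[0] + np.array([5.0, 0.0, 0.0])
        cations = np.vstack([near, far])
        assert analysis.count_condensed_cations(cations, mono, 60.0) == 1

    def test_matches_brute_force(self, rng):
        L = 20.0
        mono = rng.uniform(0, L, (30, 3))
        cat = rng.uniform(0, L, (12, 3))
        expected = 0
        for c in cat:
            d = mono - c
            d -= L * np.floor(d / L + 0.5)
            if np.sqrt((d * d).sum(axis=1)).min() < 1.12:
                expected += 1
        assert analysis.count_condensed_cations(cat, mono, L) == expected

    def test_periodic_wrap_respected(self):
        L = 30.0
        mono = np.array([[0.2, 15.0, 15.0]])
        cat = np.array([[29.9, 15.0, 15.0]])  # 0.3 away through the boundary
        assert analysis.count_condensed_cations(cat, mono, L) == 1


class TestPersistenceLength:
    def test_flexible_limit_below_one_bond(self, rng):
        # uncorrelated bond directions: c(1) ~ 0
        u = rng.normal(size=(400, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coords = np.vstack([[0, 0, 0], np.cumsum(1.12 * u, axis=0)])[:-1]
        curve = np.array([np.mean((u[:-s] * u[s:]).sum(axis=1))
                          for s in range(1, 50)])
        lp = analysis.persistence_length(curve, n=400)
        assert 0.0 <= lp < 2.5

    @pytest.mark.parametrize("b", [3.0, 6.0, 10.0])
    def test_matches_discrete_wormlike_closed_form(self, b):
        """Chains sampled from the exact Boltzmann angle distribution.

        For the bending energy b(1 + cos theta) the angle gamma between
        successive bonds has density ~ exp(b cos gamma), giving
        <cos gamma> = coth b - 1/b and l_p = -l / ln<cos gamma>.
        """
        rng = np.random.default_rng(int(b * 100))
        n_chains, n_bonds = 600, 80
        u = np.zeros((n_chains, n_bonds, 3))
        u[:, 0, 2] = 1.0
        for s in range(1, n_bonds):
            prev = u[:, s - 1]
            # inverse-CDF sample of cos(gamma) ~ exp(b cos gamma)
            v = rng.uniform(size=n_chains)
            cosg = 1.0 + np.log(v + (1 - v) * math.exp(-2 * b)) / b
            sing = np.sqrt(np.maximum(1 - cosg**2, 0.0))
            phi = rng.uniform(0, 2 * math.pi, n_chains)
            # orthonormal frame around prev
            ref = np.where(np.abs(prev[:, [0]]) < 0.9,
                           np.tile([1.0, 0, 0], (n_chains, 1)),
                           np.tile([0, 1.0, 0], (n_chains, 1)))
            e1 = np.cross(prev, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(prev, e1)
            u[:, s] = (cosg[:, None] * prev
                       + sing[:, None] * (np.cos(phi)[:, None] * e1
                                          + np.sin(phi)[:, None] * e2))
        smax = 20
        curve = np.array([np.mean((u[:, :-s] * u[:, s:]).sum(axis=2))
                          for s in range(1, smax + 1)])
        lp = analysis.persistence_length(curve, n=8 * smax, bond_length=1.12)
        lp_exact = -1.12 / math.log(1.0 / math.tanh(b) - 1.0 / b)
        assert lp == pytest.approx(lp_exact, rel=0.05)

    def test_rigid_limit_flagged(self):
        curve = np.full(50, 0.99999)
        with pytest.raises(analysis.MeasurementRangeError):
            analysis.persistence_length(curve, n=200)


class TestRadialDensity:
    def test_circle_single_bin(self):
        centres, p = analysis.radial_density(circle(radius=7.3), dr=0.5)
        occupied = np.nonzero(p)[0]
        assert len(occupied) == 1
        assert centres[occupied[0]] == pytest.approx(7.25, abs=0.25)

    def test_normalised(self, rng):
        pts = rng.normal(size=(500, 3)) * 3.0
        _, p = analysis.radial_density(pts, dr=0.5)
        assert p.sum() * 0.5 == pytest.approx(1.0)

    def test_uniform_ball_rises_quadratically(self, rng):
        r = (rng.uniform(size=4000)) ** (1 / 3) * 5.0
        d = rng.normal(size=(4000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts = d * r[:, None]
        centres, p = analysis.radial_density(pts, dr=0.5)
        inside = centres < 4.5
        fit = np.polyfit(np.log(centres[inside][2:]), np.log(p[inside][2:]), 1)
        assert fit[0] == pytest.approx(2.0, abs=0.35)


class TestUnwrap:
    def test_roundtrip_through_boundary(self):
        coords, _ = make_loop(100)
        L = 40.0
        shifted = coords + np.array([L - 2.0, L / 2, L / 2])
        wrapped = np.mod(shifted, L)
        un = analysis.unwrap_ring(wrapped, L)
        d = un - un.mean(axis=0)
        ref = coords - coords.mean(axis=0)
        assert np.allclose(np.sort(np.linalg.norm(d, axis=1)),
                           np.sort(np.linalg.norm(ref, axis=1)), atol=1e-8)

    def test_ring_winding_the_periodic_box_raises(self):
        # a chain spiralling once around the periodic torus cannot close
        L = 7.0
        bad = np.zeros((10, 3))
        bad[:, 0] = np.mod(3.0 * np.arange(10), L)
        with pytest.raises(analysis.RingClosureError):
            analysis.unwrap_ring(bad, L)
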