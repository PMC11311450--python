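"""Pointwise potentials, total energy vs a brute-force oracle, and forces."""

import math

import numpy as np
import pytest

from ringpe import forcefield as ff
from conftest import random_system


class TestPointwisePotentials:
    def test_lj_zero_at_sigma_and_beyond(self, ff_params):
        assert ff.lj_energy(1.0, ff_params) == 0.0
        assert ff.lj_energy(2.0, ff_params) == 0.0

    def test_lj_repulsive_core(self, ff_params):
        val = 4.0 * (0.9**-12 - 0.9**-6)
        assert ff.lj_energy(0.9, ff_params) == pytest.approx(val)
        assert val == pytest.approx(6.636, abs=2e-3)

    def test_lj_overlap_raises(self, ff_params):
        with pytest.raises(ff.OverlapError):
            ff.lj_energy(0.0, ff_params)

    def test_bond_harmonic(self, ff_params):
        assert ff.bond_energy(1.12, ff_params) == 0.0
        assert ff.bond_energy(1.22, ff_params) == pytest.approx(2.5)
        d = 0.07
        assert ff.bond_energy(1.12 + d, ff_params) == pytest.approx(
            ff.bond_energy(1.12 - d, ff_params))

    def test_angle_cosine_limits(self):
        p = ff.ForceFieldParams(bending=10.0)
        assert ff.angle_energy(math.pi, p) == pytest.approx(0.0, abs=1e-12)
        assert ff.angle_energy(math.pi / 2, p) == pytest.approx(10.0)
        assert ff.angle_energy(0.0, p) == pytest.approx(20.0)

    def test_dh_value_and_cutoff(self):
        p = ff.ForceFieldParams(debye=8.637, r_cut_dh=5 * 8.637)
        val = 3.0 * (-4.0) * math.exp(-3.0 / 8.637) / 3.0
        assert ff.dh_energy(-1, 4, 3.0, p) == pytest.approx(val)
        assert val == pytest.approx(-2.827, abs=2e-3)
        assert ff.dh_energy(-1, 4, 5 * 8.637, p) == 0.0
        assert ff.dh_energy(4, 4, 60.0, p) == 0.0

    @pytest.mark.parametrize("qi, qj, sign", [(1, 1, 1), (4, 4, 1),
                                              (-1, 4, -1), (-1, -1, 1)])
    def test_dh_sign_convention(self, qi, qj, sign, ff_params):
        for r in (0.5, 2.0, 10.0):
            e = ff.dh_energy(qi, qj, r, ff_params)
            assert math.copysign(1.0, e) == sign

    def test_dh_truncation_residual_is_small(self, ff_params):
        # worst-case discontinuity at the cutoff: two +4 charges
        resid = abs(ff.dh_energy(4, 4, 5 * ff_params.debye * 0.999999, ff_params))
        bound = ff_params.bjerrum * 16 * math.exp(-5.0) / (5 * ff_params.debye)
        assert resid <= bound * 1.001


def brute_force_energy(system, p):
    """O(n^2) double-loop oracle, independent of the library path."""
    pos = system.wrapped()
    L = system.box_length
    n = len(pos)
    q = system.charges
    e_lj = e_dh = e_b = e_a = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= L * np.floor(d / L + 0.5)
            r = np.linalg.norm(d)
            if r < p.r_cut_lj:
                e_lj += 4 * p.epsilon * ((p.sigma / r)**12 - (p.sigma / r)**6)
            if q[i] * q[j] != 0 and r < p.r_cut_dh:
                e_dh += p.bjerrum * q[i] * q[j] * math.exp(-r / p.debye) / r
    for a, b in system.bonds:
        d = pos[b] - pos[a]
        d -= L * np.floor(d / L + 0.5)
        e_b += 0.5 * p.k_bond * (np.linalg.norm(d) - p.r0)**2
    for i, j, k in system.angles:
        a = pos[i] - pos[j]
        a -= L * np.floor(a / L + 0.5)
        b = pos[k] - pos[j]
        b -= L * np.floor(b / L + 0.5)
        ct = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        e_a += p.bending * (1.0 + ct)
    return e_lj, e_b, e_a, e_dh


class TestTotalEnergy:
    def test_single_neutral_bead_all_zero(self):
        s = ff.ParticleSystem(np.zeros((1, 3)) + 5.0, np.zeros((1, 3)),
                              np.zeros(1), np.array(["X"]), 0, 10.0,
                              np.empty((0, 2), int), np.empty((0, 3), int))
        e = ff.total_energy(s, ff.ForceFieldParams())
        assert e.total == 0.0

    def test_three_bead_chain_at_equilibrium_geometry(self):
        """Straight chain at bond length r0: only the DH term survives."""
        p = ff.ForceFieldParams(bending=10.0, debye=5.0, r_cut_dh=25.0)
        pos = np.array([[5.0, 5.0, 5.0], [6.12, 5.0, 5.0], [7.24, 5.0, 5.0]])
        s = ff.ParticleSystem(pos, np.zeros((3, 3)), -np.ones(3),
                              np.array(["M"] * 3), 0, 50.0,
                              np.array([[0, 1], [1, 2]]), np.array([[0, 1, 2]]))
        e = ff.total_energy(s, p)
        assert e.lj == 0.0
        assert e.bond == pytest.approx(0.0, abs=1e-20)
        assert e.angle == pytest.approx(0.0, abs=1e-12)
        expected_dh = (2 * ff.dh_energy(-1, -1, 1.12, p)
                       + ff.dh_energy(-1, -1, 2.24, p))
        assert e.dh == pytest.approx(expected_dh)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed, ff_params):
        s = random_system(seed, n=12)
        e = ff.total_energy(s, ff_params)
        lj, b, a, dh = brute_force_energy(s, ff_params)
        assert e.lj == pytest.approx(lj, rel=1e-12, abs=1e-12)
        assert e.bond == pytest.approx(b, rel=1e-12, abs=1e-12)
        assert e.angle == pytest.approx(a, rel=1e-12, abs=1e-12)
        assert e.dh == pytest.approx(dh, rel=1e-12, abs=1e-12)

    def test_larger_systems_match_oracle(self, ff_params):
        s = random_system(99, n=50, n_mono=20, box=15.0)
        e = ff.total_energy(s, ff_params)
        lj, b, a, dh = brute_force_energy(s, ff_params)
        assert e.total == pytest.approx(lj + b + a + dh, rel=1e-12)


class TestForces:
    def test_straight_angle_zero_force(self):
        p = ff.ForceFieldParams(bending=50.0, k_bond=0.0)
        pos = np.array([[5.0, 5.0, 5.0], [6.12, 5.0, 5.0], [7.24, 5.0, 5.0]])
        s = ff.ParticleSystem(pos, np.zeros((3, 3)), np.zeros(3),
                              np.array(["X"] * 3), 0, 50.0,
                              np.empty((0, 2), int), np.array([[0, 1, 2]]))
        F = ff.total_forces(s, p)
        assert np.abs(F).max() < 1e-10

    def test_bond_at_rest_length_zero_force(self):
        p = ff.ForceFieldParams()
        pos = np.array([[5.0, 5.0, 5.0], [5.0 + 1.12, 5.0, 5.0]])
        s = ff.ParticleSystem(pos, np.zeros((2, 3)), np.zeros(2),
                              np.array(["X"] * 2), 0, 50.0,
                              np.array([[0, 1]]), np.empty((0, 3), int))
        F = ff.total_forces(s, p)
        assert np.abs(F).max() < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_net_force_vanishes(self, seed, ff_params):
        s = random_system(seed, n=12)
        F = ff.total_forces(s, ff_params)
        assert np.abs(F.sum(axis=0)).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_gradient(self, seed, ff_params):
        s = random_system(seed, n=12)
        F = ff.total_forces(s, ff_params)
        h = 1e-6
        num = np.zeros_like(F)
        base = s.positions.copy()
        for i in range(len(base)):
            for d in range(3):
                for sgn, store in ((1, 0), (-1, 1)):
                    p_ = base.copy()
                    p_[i, d] += sgn * h
                    s.positions = p_
                    if store == 0:
                        ep = ff.total_energy(s, ff_params).total
                    else:
                        em = ff.total_energy(s, ff_params).total
                num[i, d] = -(ep - em) / (2 * h)
        s.positions = base
        assert np.linalg.norm(F - num) / np.linalg.norm(F) < 1e-6

    def test_exclusion_flag_removes_bonded_pairs(self):
        p_in = ff.ForceFieldParams(debye=3.0, r_cut_dh=15.0)
        p_ex = ff.ForceFieldParams(debye=3.0, r_cut_dh=15.0, exclude_bonded=True)
        s = random_system(3, n=8, n_mono=8, box=10.0)
        e_in = ff.total_energy(s, p_in)
        e_ex = ff.total_energy(s, p_ex)
        # bonded neighbours are close, so removing them lowers |pair energy|
        assert e_in.lj >= e_ex.lj
        assert e_in.dh != e_ex.dh
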