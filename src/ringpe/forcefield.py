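"""Energy and force field of the coarse-grained ring-polyelectrolyte model.

Four interactions act in the model, all in reduced Lennard-Jones units
(m = sigma = epsilon = k_B T = 1):

* purely repulsive Lennard-Jones excluded volume among all beads,
  truncated (not shifted) at r_c = sigma;
* harmonic springs between adjacent ring monomers, U = k/2 (r - r0)^2
  with k = 500 and r0 = 1.12 sigma;
* a cosine bending potential U = b (1 + cos theta) on consecutive bonds,
  where theta is the interior angle at the middle bead (theta = pi for a
  straight arrangement, which costs nothing);
* a Debye-Hueckel screened Coulomb potential
  U = lambda_B q_i q_j exp(-r/lambda_D)/r between every pair of charged
  beads, truncated at r_cut = 5 lambda_D (capped at L/2).

Geometry is periodic with the minimum-image convention on a cubic box.
By default no pair is excluded from the LJ/DH sums, bonded neighbours
included; ``exclude_bonded`` flips that for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import DEFAULT_BJERRUM

_OVERLAP_EPS = 1e-10


class OverlapError(ValueError):
    """Two interacting beads sit at (numerically) zero separation."""


@dataclass(frozen=True)
class ForceFieldParams:
    """All force-field constants, in reduced units."""

    epsilon: float = 1.0
    sigma: float = 1.0
    r_cut_lj: float = 1.0
    k_bond: float = 500.0
    r0: float = 1.12
    bending: float = 0.0          # b, in k_B T
    bjerrum: float = DEFAULT_BJERRUM
    debye: float = np.inf         # lambda_D, sigma units
    r_cut_dh: float = np.inf      # min(5 lambda_D, L/2)
    exclude_bonded: bool = False

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma", "r_cut_lj", "k_bond", "r0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.bending < 0:
            raise ValueError("bending energy b must be nonnegative")

    @classmethod
    def for_solution(cls, debye: float, box_length: float, **kwargs) -> "ForceFieldParams":
        """Build parameters with the DH cutoff 5*lambda_D capped at L/2."""
        r_cut = min(5.0 * debye, box_length / 2.0)
        return cls(debye=debye, r_cut_dh=r_cut, **kwargs)

    def with_bending(self, b: float) -> "ForceFieldParams":
        return replace(self, bending=b)


def ring_topology(n_monomer: int) -> tuple[np.ndarray, np.ndarray]:
    """Bond pairs (i, i+1 mod N) and angle triples (i-1, i, i+1) of a closed ring."""
    if n_monomer < 3:
        raise ValueError("a ring needs at least 3 monomers")
    idx = np.arange(n_monomer)
    bonds = np.stack([idx, (idx + 1) % n_monomer], axis=1)
    angles = np.stack([(idx - 1) % n_monomer, idx, (idx + 1) % n_monomer], axis=1)
    return bonds, angles


@dataclass
class ParticleSystem:
    """Positions, velocities, charges and topology of the full system.

    ``positions`` are stored wrapped into [0, L).  Monomers occupy the
    first ``n_monomer`` slots; counterions, salt cations and salt anions
    follow, with species labels 'M', 'CI', 'SC', 'SA'.
    """

    positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray
    species: np.ndarray
    n_monomer: int
    box_length: float
    bonds: np.ndarray = field(default=None)  # type: ignore[assignment]
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.species = np.asarray(self.species)
        if self.bonds is None or self.angles is None:
            b, a = ring_topology(self.n_monomer) if self.n_monomer >= 3 else (
                np.empty((0, 2), int), np.empty((0, 3), int))
            if self.bonds is None:
                self.bonds = b
            if self.angles is None:
                self.angles = a
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        """Check the physical invariants of a ring-PE system."""
        if self.positions.shape != (self.n_particles, 3):
            raise ValueError("positions must be (n, 3)")
        if abs(self.charges.sum()) > 1e-9:
            raise ValueError(f"system is not charge neutral: Q = {self.charges.sum()}")
        if self.n_monomer >= 3:
            if len(self.bonds) != self.n_monomer or len(self.angles) != self.n_monomer:
                raise ValueError("closed ring must have N bonds and N angles")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    def wrapped(self) -> np.ndarray:
        return self.positions - self.box_length * np.floor(self.positions / self.box_length)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(self.positions.copy(), self.velocities.copy(),
                              self.charges.copy(), self.species.copy(),
                              self.n_monomer, self.box_length,
                              self.bonds.copy(), self.angles.copy())


@dataclass(frozen=True)
class EnergyBreakdown:
    lj: float
    bond: float
    angle: float
    dh: float

    @property
    def total(self) -> float:
        return self.lj + self.bond + self.angle + self.dh


# --------------------------------------------------------------------------
# pointwise potentials


def lj_energy(r, params: ForceFieldParams):
    """Truncated repulsive LJ energy; zero at and beyond r_c."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= _OVERLAP_EPS):
        raise OverlapError("LJ energy requested at zero separation")
    sr6 = (params.sigma / r) ** 6
    e = 4.0 * params.epsilon * (sr6 * sr6 - sr6)
    return np.where(r < params.r_cut_lj, e, 0.0)[()]


def bond_energy(r, params: ForceFieldParams):
    r = np.asarray(r, dtype=float)
    return (0.5 * params.k_bond * (r - params.r0) ** 2)[()]


def angle_energy(theta, params: ForceFieldParams):
    """Bending energy b(1 + cos theta); theta = pi (straight) costs nothing."""
    return (params.bending * (1.0 + np.cos(np.asarray(theta, dtype=float))))[()]


def dh_energy(q_i, q_j, r, params: ForceFieldParams):
    """Screened Coulomb energy, truncated at r_cut_dh."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= _OVERLAP_EPS):
        raise OverlapError("DH energy requested at zero separation")
    with np.errstate(over="ignore"):
        e = params.bjerrum * np.asarray(q_i) * np.asarray(q_j) * \
            np.exp(-r / params.debye) / r
    return np.where(r < params.r_cut_dh, e, 0.0)[()]


# --------------------------------------------------------------------------
# geometry helpers


def minimum_image(d: np.ndarray, box_length: float) -> np.ndarray:
    return d - box_length * np.floor(d / box_length + 0.5)


def _pair_table(system: ParticleSystem):
    """Upper-triangle pair separations with minimum image; chunked in i."""
    pos = system.wrapped()
    n = system.n_particles
    L = system.box_length
    for i0 in range(0, n - 1, 512):
        i1 = min(i0 + 512, n - 1)
        for i in range(i0, i1):
            d = minimum_image(pos[i + 1:] - pos[i], L)
            r = np.sqrt((d * d).sum(axis=1))
            yield i, np.arange(i + 1, n), r


def _bonded_mask(system: ParticleSystem, i: int, j: np.ndarray) -> np.ndarray:
    mask = np.zeros(j.shape, dtype=bool)
    for a, b in system.bonds:
        if a == i:
            mask |= j == b
        elif b == i:
            mask |= j == a
    return mask


def total_energy(system: ParticleSystem, params: ForceFieldParams) -> EnergyBreakdown:
    """Energy decomposition over all minimum-image pairs, bonds and angles."""
    pos = system.wrapped()
    L = system.box_length
    e_lj = 0.0
    e_dh = 0.0
    q = system.charges
    for i, j, r in _pair_table(system):
        if np.any(r <= _OVERLAP_EPS):
            raise OverlapError(f"particles overlap (pair involving {i})")
        keep = np.ones(r.shape, dtype=bool)
        if params.exclude_bonded:
            keep = ~_bonded_mask(system, i, j)
        lj_mask = keep & (r < params.r_cut_lj)
        if np.any(lj_mask):
            sr6 = (params.sigma / r[lj_mask]) ** 6
            e_lj += float(np.sum(4.0 * params.epsilon * (sr6 * sr6 - sr6)))
        qq = q[i] * q[j]
        dh_mask = keep & (qq != 0.0) & (r < params.r_cut_dh)
        if np.any(dh_mask):
            e_dh += float(np.sum(params.bjerrum * qq[dh_mask] *
                                 np.exp(-r[dh_mask] / params.debye) / r[dh_mask]))

    e_bond = 0.0
    if len(system.bonds):
        d = minimum_image(pos[system.bonds[:, 1]] - pos[system.bonds[:, 0]], L)
        r = np.linalg.norm(d, axis=1)
        e_bond = float(np.sum(0.5 * params.k_bond * (r - params.r0) ** 2))

    e_angle = 0.0
    if len(system.angles) and params.bending != 0.0:
        ct = _angle_cosines(pos, system.angles, L)
        e_angle = float(np.sum(params.bending * (1.0 + ct)))
    return EnergyBreakdown(e_lj, e_bond, e_angle, e_dh)


def _angle_cosines(pos: np.ndarray, angles: np.ndarray, L: float) -> np.ndarray:
    """cos(theta) of the interior angle at the middle bead of each triple."""
    i, j, k = angles[:, 0], angles[:, 1], angles[:, 2]
    a = minimum_image(pos[i] - pos[j], L)
    b = minimum_image(pos[k] - pos[j], L)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    return np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)


def kinetic_energy(system: ParticleSystem) -> float:
    return 0.5 * float(np.sum(system.velocities**2))


def total_forces(system: ParticleSystem, params: ForceFieldParams) -> np.ndarray:
    """Analytic forces F = -grad U for all four interactions."""
    pos = system.wrapped()
    L = system.box_length
    n = system.n_particles
    q = system.charges
    F = np.zeros((n, 3))

    for i, j, r in _pair_table(system):
        if np.any(r <= _OVERLAP_EPS):
            raise OverlapError(f"particles overlap (pair involving {i})")
        d = minimum_image(pos[j] - pos[i], L)  # vector from i to each j
        keep = np.ones(r.shape, dtype=bool)
        if params.exclude_bonded:
            keep = ~_bonded_mask(system, i, j)
        # f_over_r * d gives the force on j; minus that acts on i
        f_over_r = np.zeros(r.shape)
        lj_mask = keep & (r < params.r_cut_lj)
        if np.any(lj_mask):
            sr6 = (params.sigma / r[lj_mask]) ** 6
            f_over_r[lj_mask] += 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r[lj_mask] ** 2
        qq = q[i] * q[j]
        dh_mask = keep & (qq != 0.0) & (r < params.r_cut_dh)
        if np.any(dh_mask):
            rm = r[dh_mask]
            f_over_r[dh_mask] += params.bjerrum * qq[dh_mask] * \
                np.exp(-rm / params.debye) * (1.0 / rm + 1.0 / params.debye) / rm**2
        fj = f_over_r[:, None] * d
        F[j] += fj
        F[i] -= fj.sum(axis=0)

    if len(system.bonds):
        bi, bj = system.bonds[:, 0], system.bonds[:, 1]
        d = minimum_image(pos[bj] - pos[bi], L)
        r = np.linalg.norm(d, axis=1)
        fmag = -params.k_bond * (r - params.r0) / r  # along d, acting on j
        fj = fmag[:, None] * d
        np.add.at(F, bj, fj)
        np.add.at(F, bi, -fj)

    if len(system.angles) and params.bending != 0.0:
        ai, aj, ak = system.angles[:, 0], system.angles[:, 1], system.angles[:, 2]
        a = minimum_image(pos[ai] - pos[aj], L)
        b = minimum_image(pos[ak] - pos[aj], L)
        na = np.linalg.norm(a, axis=1)[:, None]
        nb = np.linalg.norm(b, axis=1)[:, None]
        ct = np.clip((a * b).sum(axis=1) / (na[:, 0] * nb[:, 0]), -1.0, 1.0)[:, None]
        # U = b_param (1 + ct)  =>  F_x = -b_param * d(ct)/dx
        dct_di = b / (na * nb) - ct * a / na**2
        dct_dk = a / (na * nb) - ct * b / nb**2
        fi = -params.bending * dct_di
        fk = -params.bending * dct_dk
        np.add.at(F, ai, fi)
        np.add.at(F, ak, fk)
        np.add.at(F, aj, -(fi + fk))

    return F
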