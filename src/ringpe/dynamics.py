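"""Langevin dynamics: initialization, integration, and the run protocol.

The production integrator is the BAOAB splitting of Langevin dynamics
(friction xi, temperature T, k_B = m = 1), compiled with numba in
:mod:`ringpe._kernels`; with xi = 0 it reduces exactly to velocity
Verlet.  :func:`langevin_step` exposes a single pure-Python step of the
same scheme for small systems and testing.

A run starts from a planar regular N-gon for the ring (side exactly r0)
with ions scattered uniformly, relaxes for ``n_equil`` steps, then
records ``n_prod / dump_every`` production snapshots.  Everything is
reproducible from one master seed; per-chunk noise seeds are derived
from it with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams, ParticleSystem, total_forces

#: minimum allowed separation when scattering ions at setup; avoids LJ blow-up
ION_OVERLAP_THRESHOLD = 0.8

SPECIES_MONOMER = "M"
SPECIES_COUNTERION = "CI"
SPECIES_SALT_CATION = "SC"
SPECIES_SALT_ANION = "SA"

SPECIES_CHARGE = {
    SPECIES_MONOMER: -1.0,
    SPECIES_COUNTERION: 1.0,
    SPECIES_SALT_CATION: 4.0,
    SPECIES_SALT_ANION: -1.0,
}


class IntegrationBlowUpError(RuntimeError):
    """Coordinates became non-finite during integration."""


@dataclass(frozen=True)
class IntegratorSpec:
    """Timestep, thermostat and run-schedule parameters."""

    dt: float = 0.001
    friction: float = 1.0       # xi, in m/tau
    temperature: float = 1.0
    seed: int = 0
    n_equil: int = 10_000_000
    n_prod: int = 10_000_000
    dump_every: int = 10_000
    n_runs: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0 or self.friction < 0:
            raise ValueError("temperature and friction must be nonnegative")

    @property
    def n_snapshots(self) -> int:
        return self.n_prod // self.dump_every


@dataclass
class Trajectory:
    """Ordered production snapshots of one run."""

    frames: list  # list of (n, 3) wrapped position arrays
    times: list   # production step index of each frame
    charges: np.ndarray
    species: np.ndarray
    n_monomer: int
    box_length: float
    meta: dict = field(default_factory=dict)
    energies: list = field(default_factory=list)  # per-frame dicts

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def initialize_system(n_monomer: int,
                      n_counterion: int,
                      n_salt: int,
                      box_length: float,
                      r0: float = 1.12,
                      temperature: float = 1.0,
                      rng: np.random.Generator | None = None,
                      charged: bool = True) -> ParticleSystem:
    """Ring as a planar regular N-gon plus uniformly scattered ions.

    The polygon side equals r0 exactly (circumradius r0 / (2 sin(pi/N)),
    which approaches N r0 / (2 pi)).  Ions are rejection-sampled so no
    two particles start closer than ``ION_OVERLAP_THRESHOLD``.
    Velocities are Maxwell-Boltzmann at ``temperature`` with the centre
    of mass drift removed.
    """
    if n_monomer < 3:
        raise ValueError("ring needs at least 3 monomers")
    rng = np.random.default_rng() if rng is None else rng
    radius = r0 / (2.0 * math.sin(math.pi / n_monomer))
    if 2.0 * radius >= box_length:
        raise ValueError(
            f"box edge {box_length} too small for ring of circumradius {radius:.2f}")

    centre = box_length / 2.0
    phi = 2.0 * math.pi * np.arange(n_monomer) / n_monomer
    ring = np.column_stack([centre + radius * np.cos(phi),
                            centre + radius * np.sin(phi),
                            np.full(n_monomer, centre)])

    n_sc = n_salt
    n_sa = 4 * n_salt
    n_ions = n_counterion + n_sc + n_sa
    placed = [ring]
    if n_ions:
        from scipy.spatial import cKDTree

        thr = ION_OVERLAP_THRESHOLD
        ions = np.empty((0, 3))
        while len(ions) < n_ions:
            cand = rng.uniform(0.0, box_length, size=(n_ions - len(ions), 3))
            pool = np.vstack([np.mod(ring, box_length), ions])
            tree = cKDTree(pool, boxsize=box_length)
            ok = tree.query(cand)[0] > thr
            cand = cand[ok]
            if len(cand) > 1:
                # drop later members of too-close candidate pairs
                ctree = cKDTree(cand, boxsize=box_length)
                drop = np.zeros(len(cand), dtype=bool)
                for a, b in ctree.query_pairs(thr):
                    drop[max(a, b)] = True
                cand = cand[~drop]
            if len(cand):
                ions = np.vstack([ions, cand])
        placed.append(ions)

    positions = np.vstack(placed)
    species = np.array([SPECIES_MONOMER] * n_monomer
                       + [SPECIES_COUNTERION] * n_counterion
                       + [SPECIES_SALT_CATION] * n_sc
                       + [SPECIES_SALT_ANION] * n_sa)
    charges = np.array([SPECIES_CHARGE[s] for s in species])
    if not charged:  # neutral variant for integrator checks
        charges = np.zeros_like(charges)
    n_total = len(species)
    velocities = rng.normal(0.0, math.sqrt(temperature), size=(n_total, 3))
    velocities -= velocities.mean(axis=0)
    system = ParticleSystem(positions, velocities, charges, species,
                            n_monomer, box_length)
    system.validate()
    return system


def langevin_step(system: ParticleSystem,
                  integrator: IntegratorSpec,
                  params: ForceFieldParams,
                  rng: np.random.Generator,
                  forces: np.ndarray | None = None) -> np.ndarray:
    """One BAOAB step in place; returns forces at the new configuration.

    Pass the previous return value as ``forces`` to avoid recomputing.
    """
    dt = integrator.dt
    xi = integrator.friction
    if forces is None:
        forces = total_forces(system, params)
    v = system.velocities
    x = system.positions
    v += 0.5 * dt * forces
    x += 0.5 * dt * v
    if xi > 0.0:
        c1 = math.exp(-xi * dt)
        c2 = math.sqrt(integrator.temperature * (1.0 - c1 * c1))
        v *= c1
        v += c2 * rng.standard_normal(v.shape)
    x += 0.5 * dt * v
    np.mod(x, system.box_length, out=x)
    if not np.all(np.isfinite(x)):
        raise IntegrationBlowUpError("non-finite coordinates after position update")
    forces = total_forces(system, params)
    v += 0.5 * dt * forces
    return forces


def _chunk_seeds(seed: int, n_chunks: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_chunks) % (2**31 - 1)


def _advance(system: ParticleSystem, params: ForceFieldParams,
             integrator: IntegratorSpec, n_steps: int, seed: int) -> dict:
    """Run ``n_steps`` kernel steps in place; returns energy/temperature stats."""
    lam_d = params.debye if np.isfinite(params.debye) else 1e30
    rc_dh = min(params.r_cut_dh, system.box_length / 2.0)
    sum_ke, e_lj, e_bond, e_angle, e_dh = _kernels.run_langevin(
        system.positions, system.velocities, system.charges,
        system.n_monomer if system.n_monomer >= 3 else 0,
        system.box_length, integrator.dt, integrator.friction,
        integrator.temperature, n_steps, seed,
        params.epsilon, params.sigma, params.r_cut_lj,
        params.k_bond, params.r0, params.bending,
        params.bjerrum, lam_d, rc_dh, _kernels.DEFAULT_SKIN)
    if sum_ke < 0.0 or not np.all(np.isfinite(system.positions)):
        raise IntegrationBlowUpError(
            f"integration blew up within the last {n_steps} steps")
    n_dof = 3 * system.n_particles
    return {
        "e_lj": e_lj, "e_bond": e_bond, "e_angle": e_angle, "e_dh": e_dh,
        "e_pot": e_lj + e_bond + e_angle + e_dh,
        "e_kin": 0.5 * float(np.sum(system.velocities**2)),
        "mean_ke_per_step": sum_ke / max(n_steps, 1),
        "temperature": 2.0 * sum_ke / max(n_steps, 1) / n_dof,
    }


def run_simulation(system: ParticleSystem,
                   params: ForceFieldParams,
                   integrator: IntegratorSpec,
                   meta: dict | None = None) -> Trajectory:
    """Equilibrate, then record production snapshots every ``dump_every`` steps."""
    system = system.copy()
    system.validate()
    n_equil_chunks = max(1, -(-integrator.n_equil // max(integrator.dump_every, 1)))
    n_prod_chunks = integrator.n_snapshots
    seeds = _chunk_seeds(integrator.seed, n_equil_chunks + n_prod_chunks)

    done = 0
    for c in range(n_equil_chunks):
        todo = min(integrator.dump_every, integrator.n_equil - done)
        if todo <= 0:
            break
        _advance(system, params, integrator, todo, int(seeds[c]))
        done += todo

    frames, times, energies = [], [], []
    for c in range(n_prod_chunks):
        stats = _advance(system, params, integrator, integrator.dump_every,
                         int(seeds[n_equil_chunks + c]))
        frames.append(system.positions.copy())
        times.append((c + 1) * integrator.dump_every)
        energies.append(stats)

    return Trajectory(frames, times, system.charges.copy(), system.species.copy(),
                      system.n_monomer, system.box_length,
                      meta=dict(meta or {}), energies=energies)
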