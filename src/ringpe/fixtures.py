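"""Geometric ground-truth conformations for the five phase classes.

These are constructed, not equilibrated, shapes: a planar regular
polygon (loop), a k-wound torus curve (toroid), a two-racquet-head
spindle, a ball-confined closed random walk (globule) and an expanded
persistent closed random walk (coil).  Each generator returns bead
coordinates forming a valid closed ring whose bond lengths stay within
[0.8, 1.4] r0, plus its class label, so every analysis and
classification stage can be exercised without running dynamics.

Positional noise is isotropic Gaussian displacement followed by a few
sweeps of pairwise bond-length re-projection that pull stretched or
compressed bonds back into the valid band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import analysis

DEFAULT_R0 = 1.12
BOND_BAND = (0.8, 1.4)  # in units of r0

LOOP, SPINDLE, TOROID, GLOBULE, COIL = "loop", "spindle", "toroid", "globule", "coil"
CLASS_LABELS = (LOOP, SPINDLE, TOROID, GLOBULE, COIL)


class FixtureGeometryError(ValueError):
    """Requested geometry cannot satisfy the bond-length band."""


@dataclass(frozen=True)
class FixtureSpec:
    class_label: str
    n: int = 200
    noise_sigma: float = 0.0
    seed: int = 0
    k: int = 2                # toroid windings
    head_fraction: float = 0.25
    density: float = 0.35     # globule beads per sigma^3
    r_minor: float = 1.0


def bond_lengths(coords: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.roll(coords, -1, axis=0) - coords, axis=1)


def ring_is_valid(coords: np.ndarray, r0: float = DEFAULT_R0,
                  band: tuple[float, float] = BOND_BAND) -> bool:
    bl = bond_lengths(coords)
    return bool(np.all(bl >= band[0] * r0) and np.all(bl <= band[1] * r0))


def relax_bonds(coords: np.ndarray, r0: float = DEFAULT_R0,
                band: tuple[float, float] = BOND_BAND,
                n_sweeps: int = 60) -> np.ndarray:
    """Pull out-of-band bonds back by moving both endpoints symmetrically."""
    coords = np.array(coords, dtype=float)
    lo, hi = band[0] * r0, band[1] * r0
    n = len(coords)
    for _ in range(n_sweeps):
        bl = bond_lengths(coords)
        if np.all((bl >= lo) & (bl <= hi)):
            break
        for i in np.nonzero((bl < lo) | (bl > hi))[0]:
            j = (i + 1) % n
            d = coords[j] - coords[i]
            length = np.linalg.norm(d)
            target = min(max(length, lo * 1.02), hi * 0.98)
            shift = 0.5 * (length - target) / length * d
            coords[i] += shift
            coords[j] -= shift
    return coords


def add_noise(coords: np.ndarray, noise_sigma: float,
              rng: np.random.Generator, r0: float = DEFAULT_R0) -> np.ndarray:
    if noise_sigma <= 0.0:
        return np.array(coords, dtype=float)
    noisy = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    return relax_bonds(noisy, r0)


def _resample_closed(path: np.ndarray, n: int) -> np.ndarray:
    """Resample a dense closed polyline into n equally spaced beads."""
    closed = np.vstack([path, path[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n) * total / n
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, closed[:, d])
    return out


def make_loop(n: int = 200, radius: float | None = None,
              noise: float = 0.0, seed: int = 0,
              r0: float = DEFAULT_R0) -> tuple[np.ndarray, str]:
    """Planar regular N-gon; side length r0 when the radius is derived."""
    if radius is None:
        radius = r0 / (2.0 * math.sin(math.pi / n))
    side = 2.0 * radius * math.sin(math.pi / n)
    if not (BOND_BAND[0] * r0 <= side <= BOND_BAND[1] * r0):
        raise FixtureGeometryError(
            f"polygon side {side:.3f} violates the bond band for radius {radius}")
    phi = 2.0 * math.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                              np.zeros(n)])
    rng = np.random.default_rng(seed)
    return add_noise(coords, noise, rng, r0), LOOP


def make_toroid(n: int = 200, k: int = 2, r_major: float | None = None,
                r_minor: float = 1.0, noise: float = 0.0, seed: int = 0,
                r0: float = DEFAULT_R0) -> tuple[np.ndarray, str]:
    """Closed torus curve winding the main axis k times, the tube once.

    phi = 2 pi k t about the main axis and psi = 2 pi t about the tube,
    t = i/N, so successive windings precess once around the tube per
    chain circuit and sit an adjacent-winding chord
    2 r_minor sin(pi/k) apart.
    """
    if k < 2:
        raise ValueError("toroid fixtures need k >= 2 windings")
    t_dense = np.linspace(0.0, 1.0, 40 * n, endpoint=False)

    def curve(r_maj: float) -> np.ndarray:
        phi = 2.0 * math.pi * k * t_dense
        psi = 2.0 * math.pi * t_dense
        rad = r_maj + r_minor * np.cos(psi)
        return np.column_stack([rad * np.cos(phi), rad * np.sin(phi),
                                r_minor * np.sin(psi)])

    r_maj = n * r0 / (2.0 * math.pi * k) if r_major is None else r_major
    if r_major is None:
        for _ in range(3):  # fix total arc length to N r0
            path = curve(r_maj)
            closed = np.vstack([path, path[:1]])
            length = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
            r_maj *= 1.0 + (n * r0 - length) / (2.0 * math.pi * k * r_maj)
    coords = _resample_closed(curve(r_maj), n)
    if not ring_is_valid(coords, r0):
        raise FixtureGeometryError(
            f"toroid with k={k}, r_major={r_maj:.2f}, r_minor={r_minor} "
            "violates the bond-length band")
    rng = np.random.default_rng(seed)
    return add_noise(coords, noise, rng, r0), TOROID


def make_spindle(n: int = 200, head_fraction: float = 0.25,
                 noise: float = 0.0, seed: int = 0,
                 r0: float = DEFAULT_R0,
                 strand_gap: float = 1.2) -> tuple[np.ndarray, str]:
    """Two near-circular racquet heads joined by an antiparallel double strand.

    The two straight strands run antiparallel a distance ``strand_gap``
    apart (inside the contact cutoff), each head is a near-full circle
    whose arc carries ``head_fraction`` of the beads.
    """
    if not 0.05 <= head_fraction <= 0.4:
        raise ValueError("head_fraction out of the sensible range [0.05, 0.4]")
    n_head = max(6, int(round(head_fraction * n)))
    n_strand = (n - 2 * n_head) // 2
    if n_strand < 3:
        raise FixtureGeometryError("heads leave no room for strands")
    d = strand_gap
    # head radius from its arc length; two fixed-point sweeps
    r_h = n_head * r0 / (2.0 * math.pi)
    for _ in range(3):
        c_off = math.sqrt(max(r_h**2 - (d / 2.0)**2, 1e-9))
        alpha = math.atan2(d / 2.0, -c_off)  # ~pi - small
        r_h = n_head * r0 / (2.0 * alpha)
    strand_len = n_strand * r0

    dense_arc = np.linspace(alpha, -alpha, 20 * n_head)

    def head(cx: float, sign: float) -> np.ndarray:
        ang = sign * dense_arc
        return np.column_stack([cx + sign * c_off + r_h * sign * np.cos(ang),
                                r_h * np.sin(ang),
                                np.zeros(len(ang))])

    ts = np.linspace(0.0, 1.0, 20 * n_strand, endpoint=False)
    strand1 = np.column_stack([ts * strand_len, np.full(len(ts), d / 2.0),
                               np.zeros(len(ts))])
    head_b = head(strand_len, +1.0)           # from (L, d/2) around to (L, -d/2)
    strand2 = np.column_stack([strand_len * (1.0 - ts),
                               np.full(len(ts), -d / 2.0), np.zeros(len(ts))])
    head_a = head(0.0, -1.0)                  # from (0, -d/2) back to (0, d/2)
    path = np.vstack([strand1, head_b, strand2, head_a])
    coords = _resample_closed(path, n)
    coords = relax_bonds(coords, r0)
    if not ring_is_valid(coords, r0):
        raise FixtureGeometryError("spindle geometry violates the bond band")
    rng = np.random.default_rng(seed)
    return add_noise(coords, noise, rng, r0), SPINDLE


def _close_walk(coords: np.ndarray) -> np.ndarray:
    """Distribute the closure error affinely so the ring closes."""
    n = len(coords)
    gap = coords[0] - coords[-1]
    glen = float(np.linalg.norm(gap))
    if glen < 1e-9:
        return coords
    # leave one bond length between last and first bead
    excess = gap - gap / glen * min(glen, DEFAULT_R0)
    w = (np.arange(n) / n)[:, None]
    return coords + w * excess


def _steered_walk(n: int, r0: float, rng: np.random.Generator,
                  stiffness: float = 0.0,
                  confine_radius: float | None = None) -> np.ndarray:
    """Closed random walk with optional persistence and spherical confinement."""
    coords = np.empty((n, 3))
    coords[0] = 0.0
    u = _random_unit(rng)
    for i in range(1, n):
        remaining = n - i
        target = coords[0] - coords[i - 1]
        dist = np.linalg.norm(target)
        eta = _random_unit(rng)
        step_dir = stiffness * u + (1.0 - stiffness) * eta
        # steer home when the remaining contour barely covers the gap
        slack = remaining * r0 - dist
        if slack < 3.0 * r0:
            w = min(1.0, max(0.0, 1.0 - slack / (3.0 * r0)))
            step_dir = (1.0 - w) * step_dir + w * target / max(dist, 1e-12)
        step_dir /= np.linalg.norm(step_dir)
        cand = coords[i - 1] + r0 * step_dir
        if confine_radius is not None:
            tries = 0
            while np.linalg.norm(cand) > confine_radius and tries < 40:
                eta = _random_unit(rng)
                inward = -coords[i - 1] / max(np.linalg.norm(coords[i - 1]), 1e-12)
                mix = rng.uniform(0.2, 1.0)
                step_dir = mix * inward + (1.0 - mix) * eta
                step_dir /= np.linalg.norm(step_dir)
                cand = coords[i - 1] + r0 * step_dir
                tries += 1
        coords[i] = cand
        u = step_dir
    return _close_walk(coords)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_globule(n: int = 200, density: float = 0.35, seed: int = 0,
                 r0: float = DEFAULT_R0, max_tries: int = 60) -> tuple[np.ndarray, str]:
    """Closed random walk rejected into a ball of the stated bead density.

    Retries until the packed ring is compact and near-spherical
    (delta < 0.08, R_g well under the collapse radius 0.3 N r0 / 2 pi);
    raises :class:`FixtureGeometryError` if packing keeps failing.
    """
    rng = np.random.default_rng(seed)
    r_ball = (3.0 * n / (4.0 * math.pi * density)) ** (1.0 / 3.0)
    r_collapse = 0.3 * n * r0 / (2.0 * math.pi)
    for _ in range(max_tries):
        coords = _steered_walk(n, r0, rng, stiffness=0.0, confine_radius=r_ball)
        coords = relax_bonds(coords, r0)
        if not ring_is_valid(coords, r0):
            continue
        if (analysis.shape_factor(coords) < 0.08
                and analysis.radius_of_gyration(coords) < 0.8 * r_collapse):
            return coords, GLOBULE
    raise FixtureGeometryError(
        f"could not pack a compact globule of {n} beads at density {density}")


def make_coil(n: int = 200, stiffness: float = 0.5, seed: int = 0,
              r0: float = DEFAULT_R0, max_tries: int = 60) -> tuple[np.ndarray, str]:
    """Expanded closed random walk with mild persistence.

    Retries until the walk is clearly aspherical (delta >= 0.15) and its
    bond-direction spectrum is not dominated by the single-loop
    harmonic, so it cannot be mistaken for a clean loop or a sphere.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        coords = _steered_walk(n, r0, rng, stiffness=stiffness)
        coords = relax_bonds(coords, r0)
        if not ring_is_valid(coords, r0):
            continue
        _, dom = analysis.spectral_dominance(coords)
        if analysis.shape_factor(coords) >= 0.15 and dom <= 0.4:
            return coords, COIL
    raise FixtureGeometryError(f"could not generate a valid coil of {n} beads")


def make_fixture(spec: FixtureSpec, r0: float = DEFAULT_R0) -> tuple[np.ndarray, str]:
    """Dispatch on the class label of a :class:`FixtureSpec`."""
    if spec.class_label == LOOP:
        return make_loop(spec.n, noise=spec.noise_sigma, seed=spec.seed, r0=r0)
    if spec.class_label == TOROID:
        return make_toroid(spec.n, k=spec.k, r_minor=spec.r_minor,
                           noise=spec.noise_sigma, seed=spec.seed, r0=r0)
    if spec.class_label == SPINDLE:
        return make_spindle(spec.n, head_fraction=spec.head_fraction,
                            noise=spec.noise_sigma, seed=spec.seed, r0=r0)
    if spec.class_label == GLOBULE:
        coords, label = make_globule(spec.n, density=spec.density, seed=spec.seed, r0=r0)
        rng = np.random.default_rng(spec.seed + 1)
        return add_noise(coords, spec.noise_sigma, rng, r0), label
    if spec.class_label == COIL:
        coords, label = make_coil(spec.n, seed=spec.seed, r0=r0)
        rng = np.random.default_rng(spec.seed + 1)
        return add_noise(coords, spec.noise_sigma, rng, r0), label
    raise ValueError(f"unknown class label {spec.class_label!r}")


def fixture_suite(n_per_class: int = 20, n: int = 200, noise: float = 0.0,
                  seed: int = 0) -> list[tuple[str, np.ndarray]]:
    """Randomised labelled suite: ``n_per_class`` instances of each class."""
    rng = np.random.default_rng(seed)
    suite = []
    for label in CLASS_LABELS:
        for i in range(n_per_class):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = FixtureSpec(
                class_label=label, n=n, noise_sigma=noise, seed=sub,
                k=int(rng.integers(2, 6)),
                head_fraction=float(rng.uniform(0.15, 0.3)),
                density=float(rng.uniform(0.25, 0.45)),
            )
            coords, _ = make_fixture(spec)
            suite.append((label, coords))
    return suite
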