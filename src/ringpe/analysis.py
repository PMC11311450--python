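"""Per-snapshot and per-trajectory conformational statistics of the ring.

Implements the standard descriptors used to tell loop, spindle, toroid,
globule and coil states apart:

* radius of gyration R_g and the asphericity-type shape factor
  delta = 1 - 3 I2 / I1^2 built from the gyration-tensor eigenvalue
  invariants (0 for spherical symmetry, 1 for a rod, 1/4 for a planar
  circle);
* the monomer contact map (pairs closer than 2.5 sigma with cyclic
  index separation > 2);
* the bond-direction correlation <cos theta(s)> along the ring and the
  dominant winding (torus-ring) count read off its harmonic spectrum;
* the condensed tetravalent-cation count (cations within one
  equilibrium bond length of the backbone);
* a persistence-length estimate from the initial decay of the bond
  correlation, and the radial monomer density about the ring centroid.

All routines expect unwrapped monomer coordinates; :func:`unwrap_ring`
rebuilds them from wrapped ones by walking bonds with minimum-image
displacements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_CONTACT_CUTOFF = 2.5
DEFAULT_CONTACT_MIN_SEP = 2
DEFAULT_BOND_LENGTH = 1.12
DEFAULT_RADIAL_DR = 0.5


class RingClosureError(ValueError):
    """Unwrapped ring does not close; coordinates are inconsistent."""


class AperiodicSignalError(ValueError):
    """Bond-correlation spectrum has no dominant harmonic."""


class MeasurementRangeError(ValueError):
    """Correlation does not decay; persistence length exceeds the window."""


def unwrap_ring(coords: np.ndarray, box_length: float,
                tol: float = 0.5) -> np.ndarray:
    """Unwrap ring coordinates by walking bonds with minimum image.

    Raises :class:`RingClosureError` if the closure bond of the
    reconstructed ring misses the first bead by more than ``tol``.
    """
    coords = np.asarray(coords, dtype=float)
    steps = np.diff(coords, axis=0)
    steps -= box_length * np.floor(steps / box_length + 0.5)
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(steps, axis=0)
    # walking the closure bond with minimum image must return to the start;
    # a mismatch (always a box multiple) means the ring wraps the torus
    closing = coords[0] - coords[-1]
    closing -= box_length * np.floor(closing / box_length + 0.5)
    mismatch = float(np.linalg.norm(out[-1] + closing - out[0]))
    if mismatch > tol:
        raise RingClosureError(
            "ring spans the periodic box inconsistently "
            f"(closure mismatch {mismatch:.3f} sigma)")
    return out


def radius_of_gyration(coords: np.ndarray) -> float:
    """sqrt of the mean squared distance of beads from their centroid."""
    coords = np.asarray(coords, dtype=float)
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c * c).sum(axis=1).mean()))


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    c = coords - coords.mean(axis=0)
    return c.T @ c / len(c)


def shape_factor(coords: np.ndarray) -> float:
    """delta = 1 - 3 I2 / I1^2 from gyration-tensor eigenvalues, in [0, 1]."""
    S = gyration_tensor(coords)
    lam = np.linalg.eigvalsh(S)
    i1 = lam.sum()
    if i1 <= 0.0:
        raise ValueError("shape factor undefined for a degenerate (point) snapshot")
    i2 = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    return float(1.0 - 3.0 * i2 / i1**2)


def cyclic_separation(n: int) -> np.ndarray:
    """Matrix of ring index distances min(|i-j|, N-|i-j|)."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d)


def contact_map(coords: np.ndarray,
                cutoff: float = DEFAULT_CONTACT_CUTOFF,
                min_sep: int = DEFAULT_CONTACT_MIN_SEP) -> np.ndarray:
    """Boolean N x N map: distance < cutoff and cyclic separation > min_sep."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d * d).sum(axis=-1))
    cmap = (dist < cutoff) & (cyclic_separation(n) > min_sep)
    return cmap


def bond_vectors(coords: np.ndarray) -> np.ndarray:
    """Unit bond vectors u_i = r_{i+1} - r_i of the closed ring, normalised."""
    coords = np.asarray(coords, dtype=float)
    u = np.roll(coords, -1, axis=0) - coords
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("zero-length bond")
    return u / norms


def bond_correlation(coords: np.ndarray) -> np.ndarray:
    """<cos theta(s)> = mean_i u_i . u_{i+s} for s = 1..N//2."""
    u = bond_vectors(coords)
    n = len(u)
    return np.array([float(np.mean((u * np.roll(u, -s, axis=0)).sum(axis=1)))
                     for s in range(1, n // 2 + 1)])


def _full_correlation(curve: np.ndarray, n: int) -> np.ndarray:
    """Symmetric full-ring correlation c(0..N-1) from the half curve."""
    c = np.empty(n)
    c[0] = 1.0
    half = len(curve)
    for s in range(1, half + 1):
        c[s] = curve[s - 1]
        c[n - s] = curve[s - 1]
    return c


def correlation_spectrum(curve: np.ndarray, n: int) -> np.ndarray:
    """Harmonic power of the bond correlation for k = 1..N//4."""
    c = _full_correlation(np.asarray(curve, dtype=float), n)
    power = np.abs(np.fft.rfft(c))**2
    kmax = max(2, n // 4)
    return power[1:kmax + 1]


def count_torus_rings(coords_or_curve: np.ndarray,
                      n: int | None = None,
                      min_dominance: float = 0.2) -> int:
    """Dominant integer period count of the bond-correlation curve.

    Accepts either monomer coordinates or a precomputed half curve (with
    ``n`` the ring length).  The winding count is the spectral peak
    k = argmax over harmonics 1..N/4; a flat spectrum (peak carrying
    less than ``min_dominance`` of the total harmonic power) raises
    :class:`AperiodicSignalError`.
    """
    arr = np.asarray(coords_or_curve, dtype=float)
    if arr.ndim == 2:
        n = len(arr)
        curve = bond_correlation(arr)
    else:
        if n is None:
            raise ValueError("ring length n is required with a precomputed curve")
        curve = arr
    power = correlation_spectrum(curve, n)
    total = power.sum()
    if total <= 0.0:
        raise AperiodicSignalError("bond correlation carries no harmonic power")
    k = int(np.argmax(power)) + 1
    if power[k - 1] / total < min_dominance:
        raise AperiodicSignalError(
            f"no dominant harmonic (peak fraction {power[k - 1] / total:.2f})")
    return k


def spectral_dominance(coords_or_curve: np.ndarray, n: int | None = None) -> tuple[int, float]:
    """(peak harmonic k, fraction of harmonic power it carries)."""
    arr = np.asarray(coords_or_curve, dtype=float)
    if arr.ndim == 2:
        n = len(arr)
        curve = bond_correlation(arr)
    else:
        if n is None:
            raise ValueError("ring length n is required with a precomputed curve")
        curve = arr
    power = correlation_spectrum(curve, n)
    total = power.sum()
    if total <= 0.0:
        return 0, 0.0
    k = int(np.argmax(power)) + 1
    return k, float(power[k - 1] / total)


def winding_number(coords: np.ndarray) -> int:
    """Windings of the ring about its principal (smallest-eigenvalue) axis."""
    coords = np.asarray(coords, dtype=float)
    S = gyration_tensor(coords)
    lam, vec = np.linalg.eigh(S)
    axis = vec[:, 0]  # symmetry axis of a toroid: least extension
    c = coords - coords.mean(axis=0)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    ang = np.arctan2(c @ e2, c @ e1)
    dang = np.diff(np.concatenate([ang, ang[:1]]))
    dang -= 2.0 * np.pi * np.round(dang / (2.0 * np.pi))
    return int(round(abs(dang.sum()) / (2.0 * np.pi)))


def count_condensed_cations(cation_coords: np.ndarray,
                            monomer_coords: np.ndarray,
                            box_length: float,
                            threshold: float = DEFAULT_BOND_LENGTH) -> int:
    """Tetravalent cations within ``threshold`` of the nearest monomer."""
    cation_coords = np.asarray(cation_coords, dtype=float)
    if len(cation_coords) == 0:
        return 0
    mono = np.mod(np.asarray(monomer_coords, dtype=float), box_length)
    cat = np.mod(cation_coords, box_length)
    tree = cKDTree(mono, boxsize=box_length)
    dist, _ = tree.query(cat)
    return int(np.sum(dist < threshold))


def persistence_length(curve: np.ndarray,
                       n: int,
                       bond_length: float = DEFAULT_BOND_LENGTH,
                       max_frac: float = 0.125,
                       floor: float = 0.05) -> float:
    """Persistence length from the initial exponential decay of <cos theta(s)>.

    Fits -ln c(s) = s * l_bond / l_p through the origin over the
    contiguous run of correlations with s <= N * max_frac, stopping at
    the first value at or below ``floor`` (deep in the decay the curve
    is dominated by sampling noise and ring closure).  Raises
    :class:`MeasurementRangeError` when the correlation does not decay
    within the window (rigid limit, fitted l_p beyond the ring length);
    returns 0.0 when even c(1) is nonpositive (fully flexible limit,
    l_p below one bond).
    """
    curve = np.asarray(curve, dtype=float)
    smax = max(2, int(n * max_frac))
    ss, ys = [], []
    for s in range(1, min(smax, len(curve)) + 1):
        c = curve[s - 1]
        if c <= floor:
            break
        ss.append(float(s))
        ys.append(-math.log(c))
    if not ss:
        return 0.0
    ss_a = np.array(ss)
    ys_a = np.array(ys)
    slope = float((ss_a * ys_a).sum() / (ss_a * ss_a).sum())
    lp = bond_length / slope if slope > 0 else math.inf
    if lp > n * bond_length:
        raise MeasurementRangeError(
            "bond correlation does not decay within the fit window; "
            "persistence length exceeds the measurable range")
    return lp


def radial_density(coords: np.ndarray,
                   dr: float = DEFAULT_RADIAL_DR) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram P(r_m) of monomer distances to the ring centroid.

    Returns (bin centres, P) with sum(P) * dr = 1.
    """
    coords = np.asarray(coords, dtype=float)
    r = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    nbins = max(1, int(math.ceil((r.max() + dr) / dr)))
    hist, edges = np.histogram(r, bins=nbins, range=(0.0, nbins * dr))
    p = hist / (len(r) * dr)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, p


@dataclass
class ConformationMetrics:
    """Everything the phase classifier needs about one snapshot."""

    rg: float
    delta: float
    contact_fraction: float
    n_contacts: int
    spectral_k: int
    spectral_dominance: float
    curve_min: float
    n_condensed: int | None = None
    n_ring: int | None = None
    lp: float | None = None
    contact_map: np.ndarray | None = field(default=None, repr=False)
    cos_curve: np.ndarray | None = field(default=None, repr=False)

    def scalar_dict(self) -> dict:
        return {
            "rg": self.rg, "delta": self.delta,
            "contact_fraction": self.contact_fraction,
            "n_contacts": self.n_contacts,
            "spectral_k": self.spectral_k,
            "spectral_dominance": self.spectral_dominance,
            "curve_min": self.curve_min,
            "n_condensed": self.n_condensed,
            "n_ring": self.n_ring,
        }


def eligible_pairs(n: int, min_sep: int = DEFAULT_CONTACT_MIN_SEP) -> int:
    """Number of (i < j) monomer pairs with cyclic separation > min_sep."""
    sep = cyclic_separation(n)
    return int(np.sum(np.triu(sep > min_sep, k=1)))


def analyze_monomers(coords: np.ndarray,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     min_sep: int = DEFAULT_CONTACT_MIN_SEP,
                     keep_arrays: bool = True) -> ConformationMetrics:
    """All chain-only metrics of one unwrapped monomer snapshot."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    cmap = contact_map(coords, cutoff, min_sep)
    n_contacts = int(np.sum(np.triu(cmap, k=1)))
    curve = bond_correlation(coords)
    k, dom = spectral_dominance(curve, n)
    metrics = ConformationMetrics(
        rg=radius_of_gyration(coords),
        delta=shape_factor(coords),
        contact_fraction=n_contacts / max(eligible_pairs(n, min_sep), 1),
        n_contacts=n_contacts,
        spectral_k=k,
        spectral_dominance=dom,
        curve_min=float(curve.min()),
        contact_map=cmap if keep_arrays else None,
        cos_curve=curve if keep_arrays else None,
    )
    try:
        metrics.n_ring = count_torus_rings(curve, n)
    except AperiodicSignalError:
        metrics.n_ring = None
    return metrics


def analyze_snapshot(positions: np.ndarray,
                     species: np.ndarray,
                     n_monomer: int,
                     box_length: float,
                     condense_threshold: float = DEFAULT_BOND_LENGTH,
                     **kwargs) -> ConformationMetrics:
    """Metrics of a full-system snapshot (wrapped coordinates)."""
    mono = unwrap_ring(positions[:n_monomer], box_length)
    metrics = analyze_monomers(mono, **kwargs)
    cations = positions[np.asarray(species) == "SC"]
    metrics.n_condensed = count_condensed_cations(
        cations, positions[:n_monomer], box_length, condense_threshold)
    return metrics


def analyze_trajectory(traj, **kwargs) -> list[ConformationMetrics]:
    """Per-snapshot metrics for every frame of a trajectory."""
    return [analyze_snapshot(f, traj.species, traj.n_monomer, traj.box_length,
                             keep_arrays=False, **kwargs)
            for f in traj.frames]


def trajectory_summary(metrics: list[ConformationMetrics]) -> dict:
    """Run-level averages: sqrt(<R_g^2>), <delta>, <N_c>, modal N_ring."""
    rg2 = float(np.mean([m.rg**2 for m in metrics]))
    out = {
        "rg": math.sqrt(rg2),
        "delta": float(np.mean([m.delta for m in metrics])),
        "contact_fraction": float(np.mean([m.contact_fraction for m in metrics])),
    }
    cond = [m.n_condensed for m in metrics if m.n_condensed is not None]
    out["n_condensed"] = float(np.mean(cond)) if cond else None
    rings = [m.n_ring for m in metrics if m.n_ring is not None]
    out["n_ring"] = float(np.mean(rings)) if rings else None
    return out
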