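"""Solution bookkeeping: molar salt concentration <-> particle counts, Debye length.

The simulation box is cubic with edge ``L`` expressed in the coarse-grained
bead diameter sigma.  The physical size of sigma is fixed by the Bjerrum
length of water at room temperature, lambda_B = 3 sigma = 7.2 A, i.e.
sigma = 2.4 A.  A tetravalent salt molecule dissociates into one +4e cation
and four -1e anions, so the added salt is always charge neutral.

The Debye screening length of the ionic background (salt cations, salt
anions, monovalent counterions; the ring monomers are *not* part of the
background) is

    lambda_D = [4 pi lambda_B * sum_x n_x z_x^2]^(-1/2)

with number densities n_x = N_x / L^3 in sigma units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AVOGADRO = 6.02214076e23  # 1/mol

#: default box edge in sigma units
DEFAULT_BOX_LENGTH = 150.0
#: physical length of one sigma in Angstrom (lambda_B = 3 sigma = 7.2 A)
DEFAULT_SIGMA_ANGSTROM = 2.4
#: Bjerrum length in sigma units
DEFAULT_BJERRUM = 3.0
#: valences (salt cation, salt anion, counterion)
DEFAULT_VALENCES = (4, -1, 1)


def box_volume_liters(box_length: float = DEFAULT_BOX_LENGTH,
                      sigma_angstrom: float = DEFAULT_SIGMA_ANGSTROM) -> float:
    """Volume of the cubic simulation box in liters."""
    if box_length <= 0 or sigma_angstrom <= 0:
        raise ValueError("box_length and sigma_angstrom must be positive")
    edge_m = box_length * sigma_angstrom * 1e-10
    return edge_m**3 * 1e3  # m^3 -> L


def n_salt_from_concentration(c_s: float,
                              box_length: float = DEFAULT_BOX_LENGTH,
                              sigma_angstrom: float = DEFAULT_SIGMA_ANGSTROM) -> int:
    """Number of tetravalent salt molecules at molar concentration ``c_s``.

    Implements N_salt = C_S * V * N_A with the box volume converted to
    liters, rounded half-up to the nearest integer.

    Parameters
    ----------
    c_s : float
        Molar salt concentration (mol/L); must be >= 0.
    box_length : float
        Box edge in sigma units.
    sigma_angstrom : float
        Physical length of sigma in Angstrom.
    """
    if c_s < 0:
        raise ValueError(f"salt concentration must be nonnegative, got {c_s}")
    exact = c_s * box_volume_liters(box_length, sigma_angstrom) * AVOGADRO
    return int(math.floor(exact + 0.5))


def concentration_from_n_salt(n_salt: int,
                              box_length: float = DEFAULT_BOX_LENGTH,
                              sigma_angstrom: float = DEFAULT_SIGMA_ANGSTROM) -> float:
    """Molar concentration corresponding to ``n_salt`` molecules in the box."""
    if n_salt < 0:
        raise ValueError("n_salt must be nonnegative")
    return n_salt / (box_volume_liters(box_length, sigma_angstrom) * AVOGADRO)


def debye_length(n_salt: int,
                 n_counterion: int,
                 box_length: float = DEFAULT_BOX_LENGTH,
                 bjerrum_length: float = DEFAULT_BJERRUM,
                 valences: tuple[int, int, int] = DEFAULT_VALENCES) -> float:
    """Debye screening length (sigma units) of the full ionic background.

    Each salt molecule contributes one cation of valence ``valences[0]``
    and ``abs(valences[0])`` anions of valence ``valences[1]``, plus the
    ``n_counterion`` monovalent counterions of the ring.

    Returns ``math.inf`` when the total ionic strength is zero
    (unscreened Coulomb limit); callers must handle that sentinel.
    """
    if n_salt < 0 or n_counterion < 0:
        raise ValueError("ion counts must be nonnegative")
    if box_length <= 0 or bjerrum_length <= 0:
        raise ValueError("box_length and bjerrum_length must be positive")
    z_sc, z_sa, z_c = valences
    n_sc = n_salt                    # salt cations
    n_sa = abs(z_sc) * n_salt        # salt anions balance the cation charge
    ionic = (n_sa * z_sa**2 + n_sc * z_sc**2 + n_counterion * z_c**2) / box_length**3
    if ionic == 0.0:
        return math.inf
    return 1.0 / math.sqrt(4.0 * math.pi * bjerrum_length * ionic)


@dataclass(frozen=True)
class SolutionSpec:
    """Ionic composition of one simulation state point."""

    c_s: float
    box_length: float = DEFAULT_BOX_LENGTH
    sigma_angstrom: float = DEFAULT_SIGMA_ANGSTROM
    n_counterion: int = 200
    bjerrum_length: float = DEFAULT_BJERRUM
    valences: tuple[int, int, int] = DEFAULT_VALENCES
    n_salt: int = field(init=False)
    lambda_d: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c_s < 0:
            raise ValueError("c_s must be nonnegative")
        object.__setattr__(
            self, "n_salt",
            n_salt_from_concentration(self.c_s, self.box_length, self.sigma_angstrom))
        object.__setattr__(
            self, "lambda_d",
            debye_length(self.n_salt, self.n_counterion, self.box_length,
                         self.bjerrum_length, self.valences))

    @property
    def n_salt_cation(self) -> int:
        return self.n_salt

    @property
    def n_salt_anion(self) -> int:
        return abs(self.valences[0]) * self.n_salt
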