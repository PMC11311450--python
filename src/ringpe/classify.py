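"""Rule-based assignment of the five conformational phases.

The decision signals mirror how the conformations read off contact maps
and bond-correlation curves:

* **loop** — essentially no contacts and a clean single-period cosine
  curve (the bond direction turns once around the ring);
* **toroid** — contact lines parallel to the main diagonal (pairs with
  j - i constant, adjacent windings) together with an integer
  periodicity k >= 2 of the correlation curve; k is the torus-ring
  count N_ring, and the map shows k - 1 such lines;
* **spindle** — contact lines along anti-diagonals (i + j constant,
  the two antiparallel strands) with a V-shaped correlation curve that
  dips strongly negative at half the ring;
* **globule** — abundant disordered contacts on a compact,
  near-spherical shape (delta below a small threshold, R_g below a
  collapse radius);
* **coil** — anything else: expanded and disordered.

The numeric thresholds are package calibration, exposed in
:class:`ClassifierParams`; the rule order is the cascade above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import ConformationMetrics, analyze_monomers

UNRESOLVED = "unresolved"
PHASES = ("loop", "spindle", "toroid", "globule", "coil")


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the phase-decision cascade."""

    contact_eps: float = 0.005        # loop: contact fraction below this
    loop_dominance: float = 0.5       # loop: single-harmonic power fraction
    delta_globule: float = 0.1
    collapse_factor: float = 0.3      # R_collapse = factor * N r0 / (2 pi)
    r0: float = 1.12
    line_occupancy: float = 0.5       # diagonal lines: fraction of full length
    anti_occupancy: float = 0.35      # anti-diagonal lines are shorter
    vshape_min: float = -0.5          # spindle: curve minimum below this
    ambiguity_ratio: float = 1.2      # diag vs anti contact support tie band
    min_line_fraction: float = 0.05   # contacts per line, as a fraction of N
    toroid_dominance: float = 0.3     # periodicity strength required for toroid

    def collapse_radius(self, n: int) -> float:
        return self.collapse_factor * n * self.r0 / (2.0 * math.pi)


@dataclass(frozen=True)
class PhaseLabel:
    label: str
    confidence: float = 1.0
    diagnostics: dict = field(default_factory=dict)


def count_contact_lines(cmap: np.ndarray,
                        params: ClassifierParams = ClassifierParams()) -> dict:
    """Detect straight contact lines at +-45 degrees in the (i, j) map.

    Diagonal lines collect contacts with constant offset d = j - i
    (adjacent toroid windings); anti-diagonal lines collect constant
    a = i + j (antiparallel spindle strands).  A candidate offset is a
    line when its occupancy (with +-1 smoothing) reaches the stated
    fraction of the full diagonal length; adjacent candidates merge.

    Returns counts and the number of contacts supporting each family.
    """
    n = cmap.shape[0]
    ii, jj = np.nonzero(np.triu(cmap, k=1))
    out = {"n_diag_lines": 0, "n_anti_lines": 0,
           "diag_support": 0, "anti_support": 0}
    if len(ii) == 0:
        return out

    # diagonal family: offsets 1..n-1
    d = jj - ii
    occ = np.bincount(d, minlength=n + 2)
    smooth = occ.copy().astype(float)
    smooth[1:-1] += occ[:-2] + occ[2:]
    expected = np.maximum(n - np.arange(len(smooth)), 1)
    cand = smooth >= params.line_occupancy * expected
    # chain-local contacts (small cyclic |i-j|, e.g. tight turns) are generic
    # in compact states and do not mark toroid windings; adjacent-winding
    # lines sit at cyclic offset N/k, so exclude anything below N/8
    local = max(8, n // 8)
    cand[:local] = False
    cand[len(cand) - local:] = False
    min_support = max(6, int(params.min_line_fraction * n))
    clusters = _clusters(cand, occ, min_support)
    out["n_diag_lines"] = len(clusters)
    out["diag_support"] = int(sum(c[1] for c in clusters))

    # anti-diagonal family: sums 1..2n-3
    a = ii + jj
    occ_a = np.bincount(a, minlength=2 * n + 2)
    smooth_a = occ_a.copy().astype(float)
    smooth_a[1:-1] += occ_a[:-2] + occ_a[2:]
    idx = np.arange(len(smooth_a))
    expected_a = np.maximum(np.minimum(idx, 2 * n - 2 - idx) / 2.0, 1.0)
    cand_a = smooth_a >= params.anti_occupancy * expected_a
    clusters_a = _clusters(cand_a, occ_a, min_support, min_gap=4)
    out["n_anti_lines"] = len(clusters_a)
    out["anti_support"] = int(sum(c[1] for c in clusters_a))
    return out


def _clusters(cand: np.ndarray, occ: np.ndarray, min_support: int,
              min_gap: int = 3) -> list[tuple[np.ndarray, int]]:
    """Group candidate offsets into lines; drop weakly supported clusters."""
    idx = np.nonzero(cand)[0]
    if len(idx) == 0:
        return []
    out = []
    start = 0
    breaks = list(np.nonzero(np.diff(idx) > min_gap)[0] + 1) + [len(idx)]
    for stop in breaks:
        members = idx[start:stop]
        support = int(occ[members].sum())
        if support >= min_support:
            out.append((members, support))
        start = stop
    return out


def classify_metrics(metrics: ConformationMetrics, n: int,
                     params: ClassifierParams = ClassifierParams()) -> PhaseLabel:
    """Apply the decision cascade to precomputed snapshot metrics."""
    if metrics.contact_map is None:
        raise ValueError("classification needs the contact map; "
                         "run the analysis with keep_arrays=True")
    lines = count_contact_lines(metrics.contact_map, params)
    diag = {
        "contact_fraction": metrics.contact_fraction,
        "spectral_k": metrics.spectral_k,
        "spectral_dominance": metrics.spectral_dominance,
        "curve_min": metrics.curve_min,
        "delta": metrics.delta,
        "rg": metrics.rg,
        **lines,
    }

    sparse = metrics.contact_fraction < params.contact_eps
    single_period = (metrics.spectral_k == 1
                     and metrics.spectral_dominance >= params.loop_dominance)
    if sparse and single_period:
        return PhaseLabel("loop", diagnostics=diag)

    diag_sup = lines["diag_support"]
    anti_sup = lines["anti_support"]
    toroid_signal = (lines["n_diag_lines"] >= 1 and metrics.spectral_k >= 2
                     and metrics.spectral_dominance >= params.toroid_dominance
                     and diag_sup >= anti_sup)
    spindle_signal = (lines["n_anti_lines"] >= 1
                      and metrics.curve_min < params.vshape_min
                      and anti_sup >= diag_sup)
    if toroid_signal and spindle_signal:
        hi, lo = max(diag_sup, anti_sup), max(min(diag_sup, anti_sup), 1)
        if hi / lo < params.ambiguity_ratio:
            return PhaseLabel(UNRESOLVED, diagnostics=diag)
    if toroid_signal:
        return PhaseLabel("toroid", diagnostics=diag)
    if spindle_signal:
        return PhaseLabel("spindle", diagnostics=diag)

    compact = (metrics.delta < params.delta_globule
               and metrics.rg < params.collapse_radius(n))
    if (not sparse) and compact:
        return PhaseLabel("globule", diagnostics=diag)
    return PhaseLabel("coil", diagnostics=diag)


def classify_snapshot(coords: np.ndarray,
                      params: ClassifierParams = ClassifierParams()) -> PhaseLabel:
    """Classify one unwrapped monomer snapshot."""
    metrics = analyze_monomers(coords, keep_arrays=True)
    return classify_metrics(metrics, len(coords), params)


def classify_run(labels: list[str]) -> PhaseLabel:
    """Majority vote over snapshot labels; ties are unresolved."""
    if not labels:
        raise ValueError("no snapshot labels to vote over")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    if len(winners) > 1:
        return PhaseLabel(UNRESOLVED, confidence=best / len(labels),
                          diagnostics={"votes": counts})
    return PhaseLabel(winners[0], confidence=best / len(labels),
                      diagnostics={"votes": counts})


@dataclass
class PhaseDiagram:
    """Grid of (b, C_S) state points and their phase labels."""

    b_values: list[float]
    cs_values: list[float]
    grid: dict  # (b, cs) -> PhaseLabel

    def label(self, b: float, cs: float) -> str:
        entry = self.grid.get((b, cs))
        return entry.label if entry is not None else UNRESOLVED

    def boundaries(self) -> list[tuple[float, float, str, str]]:
        """Midpoints in C_S between adjacent differing labels at fixed b."""
        out = []
        for b in self.b_values:
            cs_sorted = sorted(self.cs_values)
            for c0, c1 in zip(cs_sorted, cs_sorted[1:]):
                l0, l1 = self.label(b, c0), self.label(b, c1)
                if l0 != l1:
                    out.append((b, 0.5 * (c0 + c1), l0, l1))
        return out

    def to_records(self) -> list[dict]:
        recs = []
        for (b, cs), lab in sorted(self.grid.items()):
            recs.append({"b": b, "cs": cs, "label": lab.label,
                         "confidence": lab.confidence})
        return recs


def build_phase_diagram(entries: list[tuple[float, float, PhaseLabel]]) -> PhaseDiagram:
    """Assemble labelled (b, C_S) points into a diagram; no smoothing."""
    if not entries:
        raise ValueError("phase diagram needs at least one labelled point")
    grid = {(b, cs): lab for b, cs, lab in entries}
    b_values = sorted({b for b, _, _ in entries})
    cs_values = sorted({cs for _, cs, _ in entries})
    return PhaseDiagram(b_values, cs_values, grid)
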