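# Methods

## System and force field

The system is a single closed bead-spring ring of `N` monomers (default
200), each carrying charge −e, with `N` monovalent counterions and
`N_salt` tetravalent salt molecules (one +4e cation, four −e anions) in
a periodic cubic box of edge `L` (default 150 σ), all species with
diameter σ and mass m = 1.  Reduced LJ units are used throughout
(σ = ε = k_BT = m = 1, time unit τ = σ√(m/ε)).

Four interactions act:

| term | form | parameters |
|---|---|---|
| excluded volume | `4ε[(σ/r)¹² − (σ/r)⁶]`, `r < r_c` | `ε = 1`, `r_c = σ` |
| bond | `k/2 (r − r₀)²` | `k = 500`, `r₀ = 1.12 σ` |
| bending | `b (1 + cos θ)` | `b ∈ [0, 120] k_BT` |
| electrostatics | `λ_B q_i q_j e^{−r/λ_D}/r`, `r < r_cut` | `λ_B = 3 σ`, `r_cut = 5 λ_D` |

Conventions that needed fixing:

- **LJ cutoff at exactly σ**, truncated, unshifted.  The potential is
  zero at the cutoff so the energy is continuous; the force has a
  finite jump of 24 ε/σ there, which is the price of the printed
  convention and is irrelevant for the repulsive-core role the term
  plays.
- **DH truncation** at `5 λ_D` (capped at L/2) is a hard truncation,
  not a shift; the residual discontinuity is of order `e⁻⁵` and is
  tolerated.  The worst case (two +4 charges) is bounded by
  `16 λ_B e⁻⁵ / (5 λ_D)` and a test records that bound.
- **Angle convention**: θ is the interior angle at the middle bead, so
  a straight chain has θ = π and zero bending energy; b penalises
  deviations from straightness.  The cosine form is implemented exactly
  as written, not replaced by a harmonic approximation.
- **No pair exclusions**: LJ acts among all beads and DH between all
  charged pairs, bonded neighbours included.  An `exclude_bonded` flag
  exists for sensitivity checks and is off by default.
- **Ionic strength** in `λ_D` counts salt cations, salt anions and
  counterions only — the ring monomers are not part of the screening
  background.
- Geometry is minimum-image on the periodic cube; coordinates are
  stored wrapped.  Analysis unwraps the ring by walking bonds with
  minimum-image steps; a closure mismatch (necessarily a box multiple)
  raises an error rather than silently producing nonsense shapes.

The length scale is anchored by the Bjerrum length of water at room
temperature: `λ_B = 3 σ = 7.2 Å`, i.e. σ = 2.4 Å; with box edge `L` the
salt count at molarity `C_S` is `N_salt = C_S·(L·2.4 Å)³·N_A`, rounded
half-up.  The conversion reproduces the characteristic printed pairs
(e.g. 1.78×10⁻³ M ↔ 50 molecules); two commonly quoted pairs
(8.90×10⁻² M ↔ 2500 and 1.24×10⁻¹ M ↔ 3600) differ from the direct
conversion (2501 and 3484) and are reported as computed.

## Integration

Langevin dynamics with friction ξ = m/τ and T = 1, integrated with the
BAOAB splitting at dt = 0.001 τ.  BAOAB was chosen over the impulsive
velocity-Verlet Langevin variant because its OU substep is exact (the
free-particle velocity autocorrelation decays as `e^{−ξt/m}` exactly,
which a test verifies) and it degrades gracefully to plain velocity
Verlet at ξ = 0, which is how the NVE-drift check runs.

The thermostat noise is a matched-variance uniform deviate
(√12·(u − ½)) from an inline xorshift64* stream rather than a Gaussian:
the stationary velocity is a geometric average over ~2/(ξ dt) ≈ 2000
consecutive deviates, so its distribution is Gaussian to within an
excess kurtosis of order ξ dt ≈ 10⁻³, while the kinetic temperature is
exact by construction.  Equipartition holds to better than 1% in
practice (tested at 2%).

Neighbour search uses a linked cell list with a Verlet skin of 0.45 σ,
rebuilt when any particle has moved more than half a skin; it falls
back to an all-pairs sweep when fewer than three cells fit per box
edge, which happens at very low salt where `r_cut = 5λ_D` approaches
L/2.  The compiled kernel reproduces the plain all-pairs numpy
reference forces to ~1e-12 relative (they differ only by float
reassociation).  The screened-Coulomb `e^{−t}` on `t ∈ [0, 5]` is
evaluated from a 4096-node table with a third-order Taylor correction
(relative error < 1e-13).

Runs start from a planar regular N-gon (side exactly r₀) centred in the
box with ions placed uniformly at random, rejection-sampled against a
0.8 σ overlap threshold (a numerical guard, not physics), and
Maxwell–Boltzmann velocities with the centre-of-mass drift removed.
The full-scale protocol (10⁷ equilibration + 10⁷ production steps,
snapshots every 10⁴, 10 replicas) is available as a config preset; the
desk-scale preset used by the tests and the acceptance script runs an
N = 50 ring in a 75 σ box for a few 10⁵ steps with 3 replicas, which
one CPU completes in minutes per state point.  One master seed
drives everything; per-replica and per-chunk noise seeds are derived
from it via `numpy.random.SeedSequence`, so runs are bit-reproducible.

## Analysis

- **R_g** — root mean squared distance from the monomer centroid;
  trajectory values are reported as √⟨R_g²⟩.
- **Shape factor** δ = 1 − 3I₂/I₁² from the gyration-tensor eigenvalue
  invariants, averaged over snapshots.  Exact anchors: rod 1, any
  spherically symmetric arrangement 0, planar circle ¼.
- **Contact map** — monomer pairs closer than 2.5 σ with cyclic index
  separation > 2.  Index separation is always cyclic
  (min(|i−j|, N−|i−j|)): the ring has no ends.
- **Bond correlation** ⟨cos θ(s)⟩ = mean_i û_i·û_{i+s}, s = 1..N/2.
  Both the per-snapshot curve and snapshot-averaged curves are
  available.
- **Torus winding count N_ring** — the dominant harmonic k of the
  (symmetrised) correlation curve over k = 1..N/4; a flat spectrum
  raises an "aperiodic" signal.  A geometric cross-check computes the
  winding number of the chain about the principal (smallest-eigenvalue)
  gyration axis; on constructed toroids both agree with the ground
  truth.
- **Condensed cations** — tetravalent cations whose minimum-image
  distance to the nearest monomer bead centre is below r₀ = 1.12 σ
  (threshold exposed as a parameter).
- **Persistence length** — through-origin fit of −ln⟨cos θ(s)⟩ against
  s over the initial decay (s ≤ N/8, stopping where the curve falls
  below 0.05, where ring closure and sampling noise dominate);
  l_p = l_bond/slope.  On open chains sampled from the exact
  single-angle Boltzmann distribution of the bending potential this
  reproduces the discrete worm-like-chain closed form
  `l_p = −l/ln(coth b − 1/b)` within 5%.  A non-decaying curve (fitted
  l_p beyond the ring contour) raises a range error.  Literature
  l_p-vs-b tables extracted with unspecified estimators are treated as
  qualitative only: the monotone trend is tested, not the numbers.
- **Radial density** P(r_m) — histogram of monomer distances to the
  ring centroid, Δr = 0.5 σ, normalised to ∫P dr = 1.

## Phase classification

The visual reading of contact maps and correlation curves that the
field uses to tell these states apart is made explicit as a
deterministic cascade (thresholds in
`ClassifierParams`, calibrated once on the fixture suite):

1. **loop** — contact fraction < 0.5% of eligible pairs *and* a clean
   single-period cosine (k = 1 carrying ≥ 50% of harmonic power);
2. **toroid** — ≥ 1 contact line parallel to the main diagonal
   (constant j − i ⇒ adjacent windings), periodicity k ≥ 2 with ≥ 30%
   dominance, diagonal support ≥ anti-diagonal support;
3. **spindle** — ≥ 1 anti-diagonal line (constant i + j ⇒ antiparallel
   strands) with a V-shaped curve dipping below −0.5;
4. **globule** — abundant disordered contacts with δ < 0.1 and
   R_g < 0.3·N r₀/2π;
5. **coil** — everything else.

Line detection is a ±45° Hough-style scan: occupancy per offset with
±1 smoothing must reach 50% of the full diagonal length (35% for the
shorter anti-diagonals), clusters of adjacent offsets merge into one
line, and clusters supported by fewer than max(6, 0.05 N) contacts are
discarded.  Offsets at cyclic separation below N/8 are excluded:
chain-local contacts (tight turns) occur in any compact or crumpled
state and do not mark toroid windings, whose smallest offset is N/k
with k ≤ 8 in practice.  When toroid and spindle signals tie within a
factor 1.2 of contact support the snapshot is labelled `unresolved`
with diagnostics attached.  Run-level labels are majority votes over
production snapshots; ties are unresolved.  "Bended spindle" shapes are
mapped onto the spindle class, which is how the original five-phase
nomenclature treats them.  The loop/coil boundary at high salt for
stiff chains has no standard quantitative criterion; requiring the
loop label to carry both near-zero contacts *and* a clean single-period
curve is this package's disambiguation.

## Synthetic fixtures

Geometric (not Boltzmann) ring conformations with ground-truth labels
drive all analysis and classifier tests without any simulation:

- **loop**: regular N-gon, side r₀;
- **toroid**: closed curve with azimuth 2πk·t about the main axis and
  one tube revolution 2π·t per circuit (t = i/N), major radius set so
  the arc length is N r₀.  The tube radius defaults to 1.0 σ so that
  the adjacent-winding chord `2 r sin(π/k)` stays inside the 2.5 σ
  contact cutoff for every k ≥ 2, which is what produces the k − 1
  diagonal contact lines;
- **spindle**: two near-full circular heads joined by an antiparallel
  straight double strand 1.2 σ apart, sampled uniformly by arc length;
- **globule**: closed random walk rejected into a ball of the stated
  bead density (0.35 σ⁻³ default), steered and affinely corrected to
  close, retried until compact and near-spherical;
- **coil**: expanded closed random walk with mild direction
  persistence, retried until clearly aspherical and free of a dominant
  single-loop harmonic.

Positional noise is isotropic Gaussian displacement followed by a few
symmetric bond re-projection sweeps keeping all bonds within
[0.8, 1.4] r₀.  Fixtures are seed-deterministic.  Because they are
geometric, passing the classifier suite demonstrates that the decision
rules read the intended geometric signatures correctly — not that the
simulator visits these states; that link is made separately by the
desk-scale simulation checks.

## Desk-scale simulation study

The full-scale protocol (N = 200, 2×10⁷ steps × 10 replicas × ~100
state points) is far beyond a single-CPU test budget.  The package's
own study conditions, used by the test suite and the acceptance script,
are: N = 50 ring, box 75 σ (same monomer concentration as the full
system), snapshots every 2×10⁴ steps, 3 replicas per state point, with
per-point run lengths set from pilot relaxation traces — dilute points
(few cations diffusing towards the chain) get the longest
equilibration, 3×10⁵ steps, while salt-rich points collapse and reach
their condensation plateau within ~1×10⁵ steps and get 1.5–2×10⁵-step
windows on both sides.

Two phenomenology checks run at this scale:

- **Flexible-ring re-entrance** (b = 0): √⟨R_g²⟩ at
  C_S ∈ {3.56×10⁻⁴, 5.7×10⁻², 2.49×10⁻¹} M is non-monotonic — the
  ring contracts upon first salt addition (cation bridging) and
  re-expands in excess salt.  The scaled-down collapse valley sits at
  higher C_S than in the full system: at ~1.2×10⁻¹ M the N = 50 ring
  is still a neutralised globule, and the re-expansion emerges at the
  top of the studied concentration range, where the condensed charge
  overshoots neutrality (overcharging).  The swelling leg is the
  smallest margin in the suite (the N = 50 coil and globule sizes are
  only ~1 σ apart).
- **Condensation-regime neutralisation**: at moderate stiffness (b = 8
  for the N = 50 ring, chosen so l_p is the same fraction of the loop
  radius as in the full-size toroid regime) and C_S = 5.7×10⁻² M, the
  condensed tetravalent charge 4·N_c balances the ring charge within
  15% (independent-seed pilots gave ratios 0.94 and 1.04).

At salt-poor points the statement does not hold for kinetic reasons:
with only tens of cations in the box the condensation count has not
converged within a desk-scale run, so the neutralisation check is
asserted in the salt-rich part of the condensed regime.

## Known limitations

- Electrostatics is Debye–Hückel at the pair level; ion-ion
  correlations beyond screening enter only through the explicit ions.
  No twisting interaction is included, so torsionally driven effects
  are out of scope by construction.
- The desk-scale system (N = 50) compresses the phase diagram: globule
  and coil sizes are closer together than at N = 200, and winding
  numbers in the toroid regime are small.  Quantities tied to the full
  problem size (e.g. mean N_ring ≈ 5.8 at b = 10) require the
  full-scale preset on cluster hardware.
- The classifier thresholds are calibrated on geometric fixtures; on
  simulation snapshots near phase boundaries labels fluctuate and the
  majority vote with its confidence fraction is the meaningful output.
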