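# Methods

This note documents the models, parameters and design choices behind the
pipeline, in the order the stages run.

## The folded criterion (dRMS)

Native backbone contacts are all pairs of backbone atoms (CA, C, N, O)
from residues more than two positions apart whose native distance is at
most 4.5 Å.  The distance-RMSD of a conformation over that set,

dRMS = sqrt( Σ (r_ij − r_ij⁰)² / N_bb ),

is rigid-motion invariant, and a conformation is *folded* when dRMS is
strictly below a threshold.  The threshold default is **1.5 Å**.  The
criterion is quoted in the folding literature as 0.15 Å; that value is
implausibly strict for a distance-RMSD over backbone contacts (thermal
fluctuation alone exceeds it) and is most plausibly a nm/Å units slip for
0.15 nm.  The package therefore defaults to 1.5 Å and leaves the literal
0.15 Å reachable through the `threshold` argument / `--drms-cutoff` flag.

For coarse-grained (CA-only) trajectories the same machinery runs on a
CA–CA contact set built with the Gō model's cutoff, so the sampler and its
analysis see one consistent definition of the native basin.

## Synthetic fixtures

All tests and examples run on constructions with known ground truth:

- **Ideal β-hairpin** — built residue-by-residue from internal coordinates
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, trans peptides).
  Strands use ideal antiparallel-β dihedrals (φ, ψ) = (−139°, 135°); the
  two central turn residues form a tight positive-φ turn, with two
  flanking residues bridging turn and strand.  The five turn-region
  dihedral pairs were refined once — against the Kabsch–Sander energies of
  the ideal antiparallel H-bond register, with a steric penalty — and
  frozen as construction constants.  The 16-residue hairpin forms 7
  reciprocal inter-strand H-bonds (the eighth is impossible: the
  N-terminus has no amide H) with no heavy-atom clash, and the same
  constants propagate the ladder to other even lengths.
- **GB1 stand-in** — the same generator applied to the real GB1
  C-terminal sequence (GEWTYDDATKTFTVTE) with native numbering 41–56.  It
  is explicitly synthetic, not the experimental 2GB1 coordinates, and is
  used wherever a GB1-like native is needed without a structure file.
- **Extended chain** (φ = −180°, ψ = 180°; forms no H-bonds) and **ideal
  α-helix** (−57°, −47°; forms the i+4→i ladder) as negative/positive
  controls, plus a Gaussian decoy generator (independent per-atom noise,
  deterministic per seed).
- **Two-level model** — folded level e_f with degeneracy g_f, unfolded
  level e_u > e_f with degeneracy g_u.  Its folded fraction
  g_f e^(−e_f/kT) / (g_f e^(−e_f/kT) + g_u e^(−e_u/kT)) is the analytic
  oracle for every thermodynamic test of the samplers
  (k = 0.0019872 kcal/(mol·K)).

## The coarse-grained Gō model

A CA-bead, structure-based potential in reduced units (well depth ε = 1,
k_B = 1):

| term | form | default |
| --- | --- | --- |
| native contacts (\|i−j\| ≥ 3, d⁰ ≤ cutoff) | ε(5(r⁰/r)¹² − 6(r⁰/r)¹⁰) | cutoff 8 Å (pipeline), 7 Å (constructor) |
| virtual bonds (i, i+1) | k_b(r − r⁰)² with native r⁰ | k_b = 100 ε/Ų |
| other pairs | ε_rep((σ/r)¹² − 1) for r < σ, σ capped at the native distance | σ = 4 Å, ε_rep = 1 |
| virtual dihedrals | k_dih(1 − cos(φ − φ⁰)) | k_dih = 1 |

Native bond lengths (not a flat 3.8 Å) are the bond equilibria and the
repulsion is truncated/shifted and per-pair capped, so the native pose has
exactly zero strain and energy −ε·N_contacts.  The dihedral term exists
because a purely distance-based CA potential is achiral: the mirror image
of the native fold satisfies every distance term exactly, which would
defeat any CRMSD-based diagnostic.  Encoding the native virtual dihedrals
is the standard cure in off-lattice CA Gō models; `dihedral_k=0` restores
the distance-only variant.

**Moves and temperature.** Metropolis MC with single-bead Gaussian
displacements (σ = 0.3 Å) and two-bead crankshaft rotations (σ = 0.8 rad),
50/50, N moves per sweep.  The displacement move is strongly suppressed by
the stiff virtual bonds at low temperature, so the effective dynamics are
crankshaft-dominated — acceptable for sampling (the Metropolis chain stays
exact) if not for kinetics.  The inner loop is a numba-compiled kernel
with locally evaluated energy deltas; all randomness is pre-drawn from the
caller's numpy Generator, so runs are bit-reproducible per seed and
independent of chunking.  The default CG sampling temperature T* = 0.5 was
calibrated once as the folding midpoint of the 16-residue hairpin at the
7 Å constructor cutoff (the 8 Å pipeline model melts near T* ≈ 0.6, so 0.5
sits just below its midpoint and a CG run crosses the transition many
times); at that temperature an isothermal run from the extended chain
shows the multiple folding/unfolding transitions the seeding stage needs.

## Reconstruction (three steps)

1. **Backbone from the CA trace.**  The trans peptide unit is rigid, so
   C_i and N_{i+1} occupy fixed in-plane positions between consecutive
   CAs; the only freedom is each peptide plane's orientation about the
   CA–CA axis.  That orientation is taken from the local three-CA plane
   rotated by a constant tilt (70.3°) calibrated once on ideal
   antiparallel-β geometry.  Strand peptides come out essentially right
   (0.61 Å heavy-atom deviation on the ideal hairpin, 6 of 7 native
   H-bonds recovered); turn and helix peptides are approximate and rely on
   the minimization.  Terminal N and C are placed from internal
   coordinates with β-region dihedral conventions.  CA coordinates are
   never touched.
2. **Side chains.**  A single CB stub at the ideal tetrahedral position
   (1.53 Å, N–CA–CB = C–CA–CB = 110.5°, L chirality: det[N−CA, C−CA,
   CB−CA] > 0); glycine gets none.  Full rotamer building is deliberately
   out of scope — downstream stages need geometric plausibility and an
   energy ranking, not chemistry.
3. **Minimization with frozen CA.**  Steepest descent with backtracking
   line search on a minimal pairwise potential: harmonic bonds
   (300 kcal/(mol·Ų)) at ideal lengths, 1-3 distance harmonics
   (80 kcal/(mol·Ų)) standing in for bond-angle terms (same strain
   penalty, trivial analytic gradients), and truncated soft-sphere
   repulsion (σ = 2.8 Å, pairs more than four bonds apart — the 1-5
   exclusion keeps ideal β geometry strain-free, e.g. the 2.3 Å
   O_i···CB_{i+1} approach).  The ideal-geometry targets are chosen to be
   exactly consistent with the fixture generator, so the ideal hairpin
   sits at an exact minimum of this potential.  This is *not* a named
   force field; it is a swappable strain-and-clash penalty whose
   post-minimization energy orders good models before bad ones, which is
   all the seeding stage consumes.  Defaults: 200 steps, force tolerance
   1 kcal/(mol·Å) — convergence settings are engineering choices, as no
   reference values exist for this stage.

## Seeding

Snapshot selection splits the CG run's energy range into n equal-width
bins, draws one frame uniformly from each non-empty bin and the remainder
from the most populated bin — so the set always spans the full energy
range while over-representing the dominant basin, mirroring a random
selection from a basin-dominated trajectory.  Plain uniform selection is
available by flag; the choice between the two is genuinely open and both
are exposed.  The ladder is geometric, T_i = T_min(T_max/T_min)^(i/(n−1)),
which yields approximately uniform neighbour acceptance when the heat
capacity varies slowly; linear or explicit ladders can be passed instead.
Assignment sorts models by post-minimization energy (stable, ties keep
input order) and pairs them with temperatures ascending: energy rank =
temperature rank.

## Replica exchange

One walker per slot; between exchange attempts each slot advances
`exchange_interval` sweeps of isothermal MC at its own temperature.
Attempts alternate even pairs (0-1, 2-3, …) and odd pairs (1-2, 3-4, …) —
the standard deterministic scheme.  A swap exchanges configurations
between fixed-temperature slots with probability
min(1, exp[(1/kT_i − 1/kT_j)(E_i − E_j)]); both the slot view (constant-T
trajectories, for melting curves and folded counts) and the walker view
(slot index per walker, for round-trip diagnostics) are recorded, along
with every attempt's log-exponent and outcome.  Execution is sequential
and single-process; results are bit-reproducible per seed.

## Convergence diagnostics

- **Folded-replica count**: at each record, the number of temperature
  slots whose conformation satisfies the dRMS criterion (slot counting,
  not walker counting — the fixed-temperature view is what melting curves
  average over; walker counting is reachable through the walker paths).
- **Plateau detection**: first sweep after which the count stays within
  ±1 of its final median (median of the last quarter), after a trailing
  moving average whose window (default 200 records ≈ 10k sweeps in the
  study conditions) spans the slot-level folding/unfolding
  autocorrelation.  Without smoothing, the instantaneous count of a
  6-slot ladder fluctuates by ±1–2 replicas at equilibrium and the
  latch never holds.
- **Melting curve**: per-slot folded fraction over a sweep window with a
  moving-block bootstrap standard error (default block 20 records, 200
  resamples) — frames are autocorrelated, so i.i.d. errors would be
  optimistic.  Window-to-window agreement of the curve is the
  convergence test.
- **Exchange statistics**: per-pair acceptance (zero attempts reported as
  missing, never 0), normalized per-slot energy histograms on a common
  grid with neighbour overlap Σ min(h_i, h_{i+1})Δ, and round trips per
  walker (state machine: arm at slot 0, fire on return after touching the
  top slot).
- **Backbone H-bonds**: Kabsch–Sander electrostatic energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
  E < −0.5 and |donor − acceptor| ≥ 2; amide hydrogens are built
  geometrically (1.01 Å from N, anti to the preceding carbonyl; none on
  proline or the N-terminus), so inputs need heavy atoms only.  This
  reimplements the energy rather than shelling out to dssp, keeping the
  toolkit dependency-free and testable on fixtures.
- **Secondary structure**: three states. H for residues inside two
  consecutive (i+4→i) turns, E for residues in reciprocal antiparallel
  bridges (plus single-gap fill on a strand), else C.  This is a
  deliberately reduced assignment — enough to track strand/helix
  propagation on fixtures, not a DSSP replacement.
- **Density map**: 2-D histogram of (potential energy, CRMSD to
  reference); marginals conserve the frame count.

## Study conditions

The reference experiments (test suite and acceptance script) run on the
16-residue hairpin with a 6-slot geometric ladder over T* = 0.40–0.85,
bracketing the 8 Å-cutoff model's folding midpoint: cold slots hold the
fold almost permanently, hot slots melt it, and exchange carries
conformations between them.  The CG stage runs 60,000 sweeps (snapshots
every 20), long enough to cross the folding transition several times; the
replica-exchange runs 60,000 sweeps with exchange attempts every 50.
These sizes are the package's desk-scale study conditions: large enough
for every stage to show its behaviour (a CG run with no folding events
would make seeding vacuous), small enough to run in seconds.  The
emulated campaign bookkeeping (42 replicas over 280–562 K, four
simulations of 200 ns/replica, exchange attempts every 1 ps) is kept in
`protocol.REFERENCE_PROTOCOL`.

The two-level thermodynamic checks use (e_f, e_u, g_f, g_u) =
(−2 kcal/mol, 0, 1, 20) on a 250–600 K ladder: folded fractions run from
0.74 to 0.21 across the ladder, so every slot is informative and the
closed form exercises both the sampler and the exchange machinery.

## What the synthetic setting does and does not show

The generator-based tests demonstrate *mechanistic correctness*: exact
thermodynamics on the two-level model, oracle-level agreement of the
geometric criteria, and the qualitative seeding acceleration on a system
with a genuine two-state folding transition.  They do not emulate
explicit-solvent energetics: exchange acceptance values, equilibration
times in nanoseconds, and force-field-specific folded fractions of the
real 42-replica campaign arise from all-atom physics outside this
package's scope (the pipeline deliberately emits seed structures as
standard PDB for an external MD engine rather than invoking one).
Likewise the idealized hairpin's 7-bond H-bond ladder is a property of
ideal geometry; the experimental GB1 hairpin's 5 main-chain bonds live in
a fuzzier, twisted geometry that the stand-in does not reproduce.

## Known limitations

- The backbone rebuild's constant-tilt plane orientation is calibrated
  for β geometry; helical CA traces rebuild with distorted carbonyls.
- The reduced three-state secondary-structure assignment has no 3-10/pi
  helices, parallel bridges, bends or turns.
- The CA Gō model's kinetics are move-set kinetics (crankshaft-dominated),
  not physical dynamics; only equilibrium properties and relative
  convergence comparisons are meaningful.
- Single-process execution; the engine is observationally deterministic
  per seed but makes no use of parallel hardware.
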