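# foldscale

A multiscale protein-folding pipeline for studying how coarse-grained
conformations accelerate the convergence of replica-exchange simulations.
The package is aimed at people who work on enhanced-sampling methods for
peptide folding and want a complete, testable, desk-scale implementation of
the seeding protocol: coarse-grained Monte Carlo near the folding
transition, reconstruction of all-atom-like models from CA traces,
energy-ranked assignment of those models to a replica-exchange temperature
ladder, a replica-exchange engine, and the full set of convergence
diagnostics.

The model system is the C-terminal β-hairpin of the B1 domain of protein G
(2GB1, residues 41–56), the classic two-state folding benchmark.  The
package ships an idealized synthetic stand-in for it (real sequence and
numbering, ideal antiparallel-hairpin geometry), so everything builds and
tests without downloads; a real 2GB1 file can be supplied wherever a native
structure is accepted.

## The method

**Folded criterion.** A conformation is folded when its distance-RMSD over
native backbone contacts is below a threshold:

    dRMS = sqrt( Σ_(i,j) (r_ij − r_ij⁰)² / N_bb ),   |res(i) − res(j)| > 2,

where the sum runs over backbone-atom pairs (CA, C, N, O) within 4.5 Å in
the native conformation, and r_ij⁰ is the native distance.  dRMS is
invariant under rigid motion, unlike coordinate RMSD (CRMSD, which the
package also computes via Kabsch superposition).

**Sampling.** The coarse-grained stage is an off-lattice CA Gō model:
12-10 wells on native contacts, harmonic virtual bonds, soft-sphere
repulsion and a native-dihedral chirality term, sampled by Metropolis
Monte Carlo (single-bead displacement + two-bead crankshaft moves).  The
native state is the exact global minimum with energy −ε·N_contacts.

**Seeding.** Snapshots spanning the whole energy range are drawn from the
CG run (stratified over energy bins), rebuilt to full backbones
(peptide-plane construction from the CA trace, tetrahedral CB stubs,
steepest-descent minimization with frozen alpha carbons), and assigned to
a geometric temperature ladder so that energy rank equals temperature
rank: T_i = T_min (T_max/T_min)^(i/(n−1)).

**Replica exchange.** Neighbouring slots swap configurations with
probability min(1, exp[(1/kT_i − 1/kT_j)(E_i − E_j)]), alternating
even/odd pairs.  Diagnostics: folded-replica counts over time, melting
curves (fraction folded vs temperature, block-bootstrap errors), exchange
acceptance, energy-histogram overlap, round-trip counts, backbone H-bonds
(Kabsch–Sander), and secondary-structure propagation.

## Worked example

```bash
python examples/05_seeded_vs_extended.py
```

runs the headline experiment — two replica-exchange simulations of the Gō
hairpin with identical 6-slot ladders, one seeded from coarse-grained
snapshots and one started from the extended chain — and prints:

```
   seeded: folded-count trace [1 2 3 4 4 3 3 4 3 4 2 3]  plateau at sweep 2150
 extended: folded-count trace [0 0 0 0 4 3 2 3 4 2 3 3]  plateau at sweep 26250

seeded replicas reach the plateau 12.2x earlier (2150 vs 26250 sweeps)
```

The traces are the number of temperature slots holding a folded
conformation (dRMS < 1.5 Å) over the run.  The seeded run starts at its
stationary level because its cold replicas begin from folded CG-derived
models; the extended run spends tens of thousands of sweeps folding from
scratch.  The other scripts in `examples/` walk through each stage
(fixtures, CG sampling, reconstruction/seeding, the two-level
replica-exchange thermometer, structure diagnostics).

The same stages are available from the shell:

```bash
foldscale fixtures --hairpin 16 -o native.pdb
foldscale simulate-cg --native native.pdb --sweeps 60000 --seed 3 -o cg.pdb
foldscale seed --traj cg.pdb --tmin 0.40 --tmax 0.85 --n 6 --seed 3 -o seeds/
foldscale remd --native native.pdb --seeds seeds/ --sweeps 60000 -o remd_out/
foldscale analyze --native native.pdb --remd remd_out/ -o tables/
```

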