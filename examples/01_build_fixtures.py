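"""Build the synthetic structures every other example starts from.

Creates the idealized β-hairpin (the stand-in for the GB1 C-terminal
hairpin), the extended chain, and a noisy decoy, and reports their basic
geometry and backbone hydrogen bonds.
"""

import numpy as np

from foldscale import analysis, fixtures
from foldscale.io_formats import write_pdb

native = fixtures.make_gb1_hairpin_standin()
extended = fixtures.make_extended_chain(16, sequence=fixtures.GB1_HAIRPIN_SEQUENCE,
                                        start_index=41)
decoy = fixtures.perturb_structure(native, amplitude=1.0, seed=1)

write_pdb(native, "native.pdb")
write_pdb(extended, "extended.pdb")

bond_lengths = np.linalg.norm(np.diff(native.ca_coords(), axis=0), axis=1)
print(f"hairpin: {native.n_residues} residues "
      f"(CA-CA {bond_lengths.min():.2f}-{bond_lengths.max():.2f} Å)")

bonds = analysis.detect_backbone_hbonds(native)
print(f"backbone H-bonds in the native hairpin: {len(bonds)}")
for b in bonds:
    print(f"  N-H({b.donor}) -> O=C({b.acceptor})  E = {b.energy:.2f} kcal/mol")
print("  (the reciprocal inter-strand ladder of an antiparallel hairpin;")
print("   residue numbering 41-56 matches the GB1 C-terminal fragment)")

ncs = analysis.native_contacts(native)
print(f"\nnative backbone contacts (4.5 Å, |i-j|>2): {ncs.n_bb}")
print(f"dRMS of the native against itself: {analysis.drms(native, ncs):.2e} Å")
print(f"dRMS of the extended chain:        {analysis.drms(extended, ncs):.1f} Å")
print(f"dRMS of a 1 Å-noise decoy:         {analysis.drms(decoy, ncs):.1f} Å")
print("(folded means dRMS < 1.5 Å: only the native qualifies)")
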