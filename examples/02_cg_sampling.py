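"""Coarse-grained Monte Carlo at the folding transition.

Builds a CA Gō model from the ideal hairpin and runs isothermal Metropolis
MC from the extended chain at the calibrated transition temperature.  The
trajectory should visit both the folded and the unfolded basin repeatedly —
that two-basin traffic is what makes its snapshots useful replica seeds.
"""

import numpy as np

from foldscale import analysis, cg_sampler, fixtures

native = fixtures.make_ideal_hairpin(16)
model = cg_sampler.build_go_model(native, contact_cutoff=8.0)
print(f"Gō model: {model.n_contacts} native CA contacts, "
      f"E(native) = {model.energy(native.ca_coords()):.1f} (reduced units)")

params = cg_sampler.MCParams(
    n_sweeps=60_000,
    temperature=cg_sampler.DEFAULT_CG_TEMPERATURE,  # ~ the folding midpoint
    snapshot_interval=20,
    seed=11,
)
traj = cg_sampler.mc_isothermal(model, fixtures.make_extended_chain(16), params)

ncs = analysis.native_contacts(native, cutoff=8.0, atom_names=("CA",))
res = native.residue_indices
d = np.array([analysis.drms_ca(f.structure.ca_coords(), ncs, res) for f in traj.frames])
folded = d < analysis.DEFAULT_DRMS_THRESHOLD

print(f"{len(traj)} snapshots at T* = {params.temperature}")
print(f"energy range: [{traj.energies.min():.1f}, {traj.energies.max():.1f}]")
print(f"fraction folded (dRMS < 1.5 Å): {folded.mean():.2f}")
transitions = int(np.sum(folded[1:] != folded[:-1]))
print(f"folded/unfolded boundary crossings: {transitions}")
print("(several crossings mean the run samples the whole energy range,")
print(" so energy-spanning snapshot selection has both basins to draw from)")
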