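"""End-to-end pipeline recipes.

These functions wire the stages together the way the multiscale protocol
prescribes: an isothermal coarse-grained run near the folding transition,
random energy-spanning snapshot selection, three-step reconstruction with
post-minimization energies, energy-rank seeding of a temperature ladder,
replica exchange, and the convergence diagnostics.  They are also the
reference "study conditions" used by the test suite: a 16-residue ideal
hairpin, a 6-slot reduced-unit ladder spanning the Gō-model folding
midpoint, and run lengths sized for a desk-scale workstation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis, cg_sampler, reconstruct, seeding
from .cg_sampler import DEFAULT_CG_TEMPERATURE, GoModel, MCParams
from .fixtures import TwoLevelModel, boltzmann_fraction, make_extended_chain, make_ideal_hairpin
from .io_formats import Structure, Trajectory
from .remd import REMDResult, remd_run

__all__ = [
    "REFERENCE_PROTOCOL",
    "total_simulated_time_us",
    "HairpinStudy",
    "run_cg_stage",
    "seed_replicas",
    "seeded_vs_extended",
    "two_level_remd",
]

#: Reduced-unit ladder bracketing the Gō hairpin folding midpoint (~0.6).
DEFAULT_LADDER_BOUNDS = (0.40, 0.85)

#: Setup of the reference GB1-hairpin campaign this pipeline emulates at desk
#: scale: four replica-exchange simulations (two force fields x two starting
#: options) of 42 replicas spread over 280-562 K, 200 ns per replica, with
#: an exchange trial every 1 ps.
REFERENCE_PROTOCOL = {
    "n_simulations": 4,
    "n_replicas": 42,
    "t_per_replica_ns": 200.0,
    "ladder_t_min_K": 280.0,
    "ladder_t_max_K": 562.0,
    "exchange_interval_ps": 1.0,
}


def total_simulated_time_us(
    n_simulations: int, n_replicas: int, t_per_replica_ns: float
) -> float:
    """Aggregate simulated time of a replica-exchange campaign, in µs."""
    return n_simulations * n_replicas * t_per_replica_ns / 1000.0


@dataclass
class HairpinStudy:
    """Study conditions for the Gō-hairpin convergence experiments."""

    n_residues: int = 16
    n_slots: int = 6
    cg_sweeps: int = 60_000
    cg_snapshot_interval: int = 20
    remd_sweeps: int = 60_000
    exchange_interval: int = 50
    drms_threshold: float = analysis.DEFAULT_DRMS_THRESHOLD
    contact_cutoff: float = 8.0  # Å, CA-CA for the Gō model
    plateau_smooth: int = 200  # records (~10k sweeps); averages over slot folding/unfolding noise

    def native(self) -> Structure:
        return make_ideal_hairpin(self.n_residues)

    def model(self) -> GoModel:
        return cg_sampler.build_go_model(self.native(), contact_cutoff=self.contact_cutoff)

    def ladder(self) -> seeding.TemperatureLadder:
        return seeding.make_geometric_ladder(*DEFAULT_LADDER_BOUNDS, self.n_slots)

    def folded_fn(self, native: Structure):
        ncs = analysis.native_contacts(
            native, cutoff=self.contact_cutoff, atom_names=("CA",)
        )
        return analysis.make_drms_folded_fn(
            ncs, native.residue_indices, self.drms_threshold
        )


def run_cg_stage(study: HairpinStudy, seed: int, model: GoModel | None = None) -> Trajectory:
    """Isothermal CG run from the extended chain near the transition point."""
    model = model or study.model()
    start = make_extended_chain(study.n_residues)
    params = MCParams(
        n_sweeps=study.cg_sweeps,
        temperature=DEFAULT_CG_TEMPERATURE,
        snapshot_interval=study.cg_snapshot_interval,
        seed=seed,
    )
    return cg_sampler.mc_isothermal(model, start, params)


def seed_replicas(study: HairpinStudy, traj: Trajectory, seed: int):
    """Select energy-spanning frames, rebuild them, rank by post-minimization
    energy and pair with the ladder.  Returns (start structures ordered by
    slot, SeedAssignment, reconstructed models)."""
    frames = seeding.select_spanning_frames(traj, study.n_slots, seed=seed)
    rebuilt = reconstruct.reconstruct_all(frames)
    ladder = study.ladder()
    assignment = seeding.assign_by_energy(rebuilt, ladder)
    starts = [frames[idx].structure for idx in assignment.order]
    return starts, assignment, rebuilt


def _folded_counts(result: REMDResult, study: HairpinStudy, native: Structure):
    folded = study.folded_fn(native)
    return analysis.folded_count_series(result, folded)


def seeded_vs_extended(study: HairpinStudy, seed: int) -> dict:
    """One paired convergence experiment: identical ladder and sweep budget,
    replicas started either from CG-derived seeds or all-extended.

    Returns the folded-count series and the plateau sweep for both starting
    options.  The multiscale protocol's claim is that the seeded run reaches
    its folded-count plateau earlier.
    """
    native = study.native()
    model = cg_sampler.build_go_model(native, contact_cutoff=study.contact_cutoff)
    ladder = study.ladder()

    cg_traj = run_cg_stage(study, seed=seed, model=model)
    starts_seeded, assignment, _ = seed_replicas(study, cg_traj, seed=seed)
    starts_extended = [make_extended_chain(study.n_residues)] * study.n_slots

    out = {"assignment": assignment}
    for tag, starts, run_seed in (
        ("seeded", starts_seeded, seed + 1),
        ("extended", starts_extended, seed + 2),
    ):
        result = remd_run(
            model,
            ladder,
            starts,
            n_sweeps=study.remd_sweeps,
            exchange_interval=study.exchange_interval,
            seed=run_seed,
        )
        sweeps, counts = _folded_counts(result, study, native)
        out[tag] = {
            "result": result,
            "sweeps": sweeps,
            "counts": counts,
            "plateau": analysis.plateau_sweep(sweeps, counts, smooth=study.plateau_smooth),
        }
    return out


def two_level_remd(
    model: TwoLevelModel,
    temperatures,
    n_sweeps: int = 100_000,
    exchange_interval: int = 10,
    seed: int = 0,
):
    """Replica exchange on the discrete two-level model.

    Returns (REMDResult, per-slot sampled folded fractions, analytic
    Boltzmann fractions).  The walker starts in the unfolded level on every
    slot, so agreement with the closed form demonstrates equilibration, not
    initialization.
    """
    system = cg_sampler.TwoLevelSystem(model)
    starts = [model.g_folded for _ in temperatures]  # first unfolded state
    result = remd_run(
        system,
        temperatures,
        starts,
        n_sweeps=n_sweeps,
        exchange_interval=exchange_interval,
        seed=seed,
    )
    sampled = np.array(
        [
            np.mean([system.is_folded(s) for s in slot_states])
            for slot_states in result.slot_states
        ]
    )
    exact = np.array([boltzmann_fraction(model, t) for t in temperatures])
    return result, sampled, exact
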