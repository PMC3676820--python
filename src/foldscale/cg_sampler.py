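"""Coarse-grained isothermal Monte Carlo sampling.

The sampling stage of the pipeline needs only a contract: a model that maps
a configuration to a potential energy and proposes local moves, and a
Metropolis driver that turns it into an energy-annotated trajectory with
folded/unfolded transitions.  Two models ship with the package:

* :class:`GoModel` — an off-lattice CA Gō model built from a native
  structure: attractive 12-10 wells on native CA-CA contacts, harmonic
  virtual bonds, soft-sphere repulsion elsewhere.  The native conformation
  is its global minimum by construction, giving the two-basin
  folded/unfolded behaviour the downstream stages exercise.  Energies are in
  reduced units (well depth ε = 1, k_B = 1).

* :class:`TwoLevelSystem` — the discrete two-level model, whose equilibrium
  populations are known in closed form; it is the analytic oracle for every
  thermodynamic test of the samplers and of the replica-exchange engine.

Move set for coordinate models: single-bead Gaussian displacement and
two-bead crankshaft rotation, attempted 50/50 with fixed amplitudes, so a
run is a pure function of (model, start, parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fixtures import KB_KCAL, TwoLevelModel
from .io_formats import Frame, Structure, Trajectory

#: Default coarse-grained sampling temperature (reduced units): calibrated
#: once to the folding midpoint of the 16-residue ideal-hairpin Gō model, so
#: an isothermal run shows multiple folding/unfolding transitions.
DEFAULT_CG_TEMPERATURE = 0.5

__all__ = [
    "DEFAULT_CG_TEMPERATURE",
    "MCParams",
    "GoModel",
    "TwoLevelSystem",
    "build_go_model",
    "mc_isothermal",
    "mc_sample_states",
]


@dataclass(frozen=True)
class MCParams:
    """Isothermal Monte Carlo run parameters.

    ``temperature`` is in the model's own units (reduced for the Gō model,
    kelvin for the two-level system); ``move_amplitude`` is the displacement
    standard deviation in Å; ``snapshot_interval`` is in sweeps.
    """

    n_sweeps: int
    temperature: float
    move_amplitude: float = 0.3
    crank_amplitude: float = 0.8  # radians
    snapshot_interval: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


# ---------------------------------------------------------------------------
# Gō model
# ---------------------------------------------------------------------------

_BOND, _CONTACT, _REP = 0, 1, 2


class GoModel:
    """Structure-based (Gō) CA potential with the native state as global
    minimum.

    Energy terms over CA pairs:

    * native contacts (|i-j| >= 3, native distance <= ``contact_cutoff``):
      12-10 well ε·(5(r0/r)^12 − 6(r0/r)^10), depth −ε at the native
      distance r0;
    * virtual bonds (i, i+1): harmonic k_b(r − r0)², with r0 the native bond
      length so the native pose carries zero strain;
    * all remaining pairs: truncated-shifted soft-sphere repulsion
      ε_rep((σ/r)^12 − 1) for r < σ, with σ capped per pair at the native
      distance so repulsion vanishes identically at the native pose;
    * virtual dihedrals (CA 4-tuples): k_dih(1 − cos(φ − φ0)) about the
      native dihedral φ0.  A purely distance-based CA potential is achiral —
      the mirror image of the native fold satisfies every distance term — so
      this term is what makes the native hand the unique minimum.  Set
      ``dihedral_k=0`` for the distance-only variant.

    Consequently energy(native) = −ε × (number of native contacts) exactly.
    Reduced units: ε = 1 sets the energy scale and k_B = 1, so temperature
    is in units of ε/k_B.
    """

    k_B = 1.0
    energy_units = "reduced (eps=1)"

    def __init__(
        self,
        native: Structure,
        contact_cutoff: float = 7.0,
        well_depth: float = 1.0,
        bond_k: float = 100.0,
        repulsion_sigma: float = 4.0,
        repulsion_eps: float = 1.0,
        dihedral_k: float = 1.0,
    ):
        if contact_cutoff <= 0 or well_depth <= 0:
            raise ValueError("contact_cutoff and well_depth must be > 0")
        native.validate()
        ca = native.ca_coords()
        if len(ca) < 4:
            raise ValueError("native must have at least 4 CA atoms")
        self.topology = native
        self.native_ca = ca
        self.n = len(ca)
        self.eps = float(well_depth)
        self.contact_cutoff = float(contact_cutoff)

        pair_i, pair_j, kind, p_r0, p_sig = [], [], [], [], []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                d0 = float(np.linalg.norm(ca[i] - ca[j]))
                if j - i == 1:
                    pair_i.append(i); pair_j.append(j)
                    kind.append(_BOND); p_r0.append(d0); p_sig.append(0.0)
                elif j - i >= 3 and d0 <= contact_cutoff:
                    pair_i.append(i); pair_j.append(j)
                    kind.append(_CONTACT); p_r0.append(d0); p_sig.append(0.0)
                else:
                    pair_i.append(i); pair_j.append(j)
                    kind.append(_REP); p_r0.append(0.0)
                    p_sig.append(min(repulsion_sigma, d0))
        self.pair_i = np.array(pair_i); self.pair_j = np.array(pair_j)
        self.kind = np.array(kind)
        self.p_r0 = np.array(p_r0); self.p_sig = np.array(p_sig)
        self.bond_k = float(bond_k)
        self.rep_eps = float(repulsion_eps)
        self.n_contacts = int(np.sum(self.kind == _CONTACT))
        self.moves_per_sweep = self.n
        # kind-contiguous pair tables: one coordinate gather per energy call
        kind_arr = self.kind
        order = np.argsort(kind_arr, kind="stable")
        self._all_i = self.pair_i[order]
        self._all_j = self.pair_j[order]
        n_b = int(np.sum(kind_arr == _BOND))
        n_c = int(np.sum(kind_arr == _CONTACT))
        self._sl_b = slice(0, n_b)
        self._sl_c = slice(n_b, n_b + n_c)
        self._sl_r = slice(n_b + n_c, len(order))
        self._br0 = self.p_r0[order][self._sl_b]
        self._cr0 = self.p_r0[order][self._sl_c]
        self._rsig2 = self.p_sig[order][self._sl_r] ** 2
        self.dihedral_k = float(dihedral_k)
        self._phi0 = self._virtual_dihedrals(ca) if self.n >= 4 else np.empty(0)
        # CSR neighbour tables for the compiled sweep kernel
        nbr = [[] for _ in range(self.n)]
        for i, j, k, r0, sig in zip(pair_i, pair_j, kind, p_r0, p_sig):
            nbr[i].append((j, k, r0, sig * sig))
            nbr[j].append((i, k, r0, sig * sig))
        ptr = [0]
        other, kinds, r0s, sig2s = [], [], [], []
        for b in range(self.n):
            for o, k, r0, s2 in nbr[b]:
                other.append(o); kinds.append(k); r0s.append(r0); sig2s.append(s2)
            ptr.append(len(other))
        self._nbr_ptr = np.array(ptr, dtype=np.int64)
        self._nbr_other = np.array(other, dtype=np.int64)
        self._nbr_kind = np.array(kinds, dtype=np.int64)
        self._nbr_r0 = np.array(r0s, dtype=np.float64)
        self._nbr_sig2 = np.array(sig2s, dtype=np.float64)

    @staticmethod
    def _virtual_dihedrals(coords: np.ndarray) -> np.ndarray:
        b1 = coords[1:-2] - coords[:-3]
        b2 = coords[2:-1] - coords[1:-2]
        b3 = coords[3:] - coords[2:-1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, b2n), n2)
        return np.arctan2(y, x)

    # -- energy ------------------------------------------------------------

    def energy(self, coords: np.ndarray) -> float:
        """Total potential energy of a CA configuration (reduced units)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n, 3):
            raise ValueError(f"expected CA coordinates of shape ({self.n}, 3)")
        d = coords[self._all_i] - coords[self._all_j]
        r2 = np.einsum("ij,ij->i", d, d)
        r_b = np.sqrt(r2[self._sl_b])
        e = self.bond_k * float(np.sum((r_b - self._br0) ** 2))
        q2 = self._cr0 ** 2 / r2[self._sl_c]
        q6 = q2 * q2 * q2
        e += self.eps * float(np.sum(q6 * q2 * q2 * (5.0 * q2 - 6.0)))
        r2_r = r2[self._sl_r]
        inside = r2_r < self._rsig2
        if inside.any():
            q12 = (self._rsig2[inside] / r2_r[inside]) ** 6
            e += self.rep_eps * float(np.sum(q12 - 1.0))
        if self.dihedral_k and len(self._phi0):
            phi = self._virtual_dihedrals(coords)
            e += self.dihedral_k * float(np.sum(1.0 - np.cos(phi - self._phi0)))
        return e

    # -- moves -------------------------------------------------------------

    def propose(self, coords: np.ndarray, rng, amplitude: float, crank_amplitude: float):
        """One trial move: (new_coords, delta_energy, moved_bead_indices).

        50/50 single-bead Gaussian displacement or two-bead crankshaft
        rotation about the axis through the flanking beads.
        """
        if rng.random() < 0.5 or self.n < 4:
            beads = [int(rng.integers(self.n))]
            shift = rng.normal(0.0, amplitude, size=3)
            new = coords.copy()
            new[beads[0]] += shift
        else:
            k = int(rng.integers(1, self.n - 2))  # rotate beads k, k+1
            beads = [k, k + 1]
            axis_a, axis_b = coords[k - 1], coords[k + 2]
            axis = axis_b - axis_a
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                return coords, 0.0, []
            axis = axis / norm
            theta = rng.normal(0.0, crank_amplitude)
            new = coords.copy()
            new[beads] = _rotate_about_axis(coords[beads], axis_a, axis, theta)
        return new, None, beads

    def run_sweeps(self, coords, energy, beta, n_sweeps, rng, p: MCParams):
        """Advance ``n_sweeps`` Metropolis sweeps in place (compiled path).

        Randomness is pre-drawn from ``rng`` so results are bit-identical to
        a fixed seed regardless of chunking.
        """
        from ._go_kernel import go_sweeps

        n_moves = n_sweeps * self.moves_per_sweep
        done = 0
        while done < n_moves:
            chunk = min(n_moves - done, 200_000)
            u = rng.random((chunk, 3))
            g = rng.standard_normal((chunk, 4))
            energy = go_sweeps(
                coords, energy, beta, p.move_amplitude, p.crank_amplitude,
                u, g,
                self._nbr_ptr, self._nbr_other, self._nbr_kind,
                self._nbr_r0, self._nbr_sig2,
                self.bond_k, self.eps, self.rep_eps,
                self.dihedral_k, self._phi0,
            )
            done += chunk
        return coords, energy

    def start_state(self, structure: Structure) -> np.ndarray:
        ca = structure.ca_coords()
        if ca.shape != (self.n, 3):
            raise ValueError(
                f"start structure has {ca.shape[0]} residues, model expects {self.n}"
            )
        return ca

    def state_to_structure(self, coords: np.ndarray) -> Structure:
        return self.topology.with_ca_coords(coords)


def _rotate_about_axis(points, origin, axis, theta):
    p = points - origin
    c, s = math.cos(theta), math.sin(theta)
    rot = (
        p * c
        + np.cross(axis, p) * s
        + np.outer(p @ axis, axis) * (1.0 - c)
    )
    return rot + origin


def build_go_model(
    native: Structure, contact_cutoff: float = 7.0, well_depth: float = 1.0, **kwargs
) -> GoModel:
    """Build a CA Gō model from a native structure (see :class:`GoModel`)."""
    return GoModel(native, contact_cutoff=contact_cutoff, well_depth=well_depth, **kwargs)


# ---------------------------------------------------------------------------
# discrete two-level system
# ---------------------------------------------------------------------------


class TwoLevelSystem:
    """MC-sampleable wrapper around the analytic :class:`TwoLevelModel`.

    States are integers 0..g_f+g_u-1; the first ``g_folded`` states carry the
    folded energy.  Proposals draw a state uniformly, which is symmetric, so
    Metropolis acceptance targets the exact Boltzmann distribution.
    Energies in kcal/mol, temperatures in K.
    """

    k_B = KB_KCAL
    energy_units = "kcal/mol"
    moves_per_sweep = 1

    def __init__(self, model: TwoLevelModel):
        self.model = model
        self.n_states = model.g_folded + model.g_unfolded

    def energy(self, state: int) -> float:
        return self.model.e_folded if state < self.model.g_folded else self.model.e_unfolded

    def propose(self, state: int, rng, amplitude=None, crank_amplitude=None):
        new = int(rng.integers(self.n_states))
        return new, self.energy(new) - self.energy(state), [new]

    def is_folded(self, state: int) -> bool:
        return state < self.model.g_folded


# ---------------------------------------------------------------------------
# Metropolis driver
# ---------------------------------------------------------------------------


def _metropolis_sweeps(model, state, energy, beta, n_sweeps, rng, p: MCParams):
    """Run ``n_sweeps`` sweeps in place; returns (state, energy)."""
    if hasattr(model, "run_sweeps"):
        return model.run_sweeps(state, energy, beta, n_sweeps, rng, p)
    for _ in range(n_sweeps * model.moves_per_sweep):
        new, de, _moved = model.propose(
            state, rng, p.move_amplitude, p.crank_amplitude
        )
        if de is None:
            e_new = model.energy(new)
            de = e_new - energy
        else:
            e_new = energy + de
        if de <= 0.0 or rng.random() < math.exp(-beta * de):
            state, energy = new, e_new
    return state, energy


def mc_sample_states(model, start_state, p: MCParams):
    """Generic isothermal Metropolis run on any EnergyModel.

    Returns (steps, states, energies): snapshots every
    ``p.snapshot_interval`` sweeps, including the sweep they were taken at.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(p.seed)
    beta = 1.0 / (model.k_B * p.temperature)
    state = start_state.copy() if hasattr(start_state, "copy") else start_state
    energy = model.energy(state)
    steps, states, energies = [], [], []
    for sweep in range(1, p.n_sweeps + 1):
        state, energy = _metropolis_sweeps(model, state, energy, beta, 1, rng, p)
        if sweep % p.snapshot_interval == 0:
            energy = model.energy(state)  # kill incremental-update drift
            steps.append(sweep)
            states.append(state.copy() if hasattr(state, "copy") else state)
            energies.append(energy)
    return np.array(steps), states, np.array(energies)


def mc_isothermal(model: GoModel, start: Structure, p: MCParams) -> Trajectory:
    """Isothermal Monte Carlo on a coordinate model, as a Trajectory.

    Each frame carries the CA-trace structure, current potential energy, the
    sweep index and the run temperature.  Bit-reproducible for a fixed seed.
    """
    state = model.start_state(start)
    steps, states, energies = mc_sample_states(model, state, p)
    frames = [
        Frame(
            structure=model.state_to_structure(states[k]),
            energy=float(energies[k]),
            step=int(steps[k]),
            temperature=p.temperature,
        )
        for k in range(len(steps))
    ]
    return Trajectory(frames, energy_units=model.energy_units).validate()
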