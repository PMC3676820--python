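"""Synthetic structures and analytic models with known ground truth.

Everything downstream — contact analysis, the Gō sampler, reconstruction,
seeding, replica exchange — is exercised on structures built here from ideal
geometry, so the full pipeline runs and is tested without any external
download.  The generators are pure functions of their parameters and seed.

The idealized β-hairpin stands in for the C-terminal hairpin of the B1
domain of protein G (PDB 2GB1, residues 41-56), the classic two-state
folding model system; real 2GB1 coordinates remain usable as an optional
external input wherever a native structure is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import geometry
from .io_formats import AtomRecord, Structure

__all__ = [
    "TwoLevelModel",
    "boltzmann_fraction",
    "build_chain",
    "make_ideal_hairpin",
    "make_extended_chain",
    "make_ideal_helix",
    "make_gb1_hairpin_standin",
    "perturb_structure",
    "GB1_HAIRPIN_SEQUENCE",
    "KB_KCAL",
]

KB_KCAL = 0.0019872  # Boltzmann constant, kcal/(mol·K)

#: One-letter sequence of 2GB1 residues 41-56 (GEWTYDDATKTFTVTE).
GB1_HAIRPIN_SEQUENCE = "GEWTYDDATKTFTVTE"

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# Hairpin generator dihedrals (degrees).  Strand values are ideal
# antiparallel-β; the two central turn residues form a tight type-I'-like
# turn (positive phi) and the two flanking residues bridge turn and strand
# geometry.  The turn-region angles were refined once so that the
# cross-strand Kabsch-Sander H-bond ladder of the ideal antiparallel
# register forms without steric clashes, then frozen as construction
# constants.
STRAND_PHI = -139.0
STRAND_PSI = 135.0
TURN_FLANK_IN = (137.3, 179.8)
TURN_DIHEDRALS = ((58.6, 22.2), (58.1, 23.9))
TURN_FLANK_OUT = (-123.8, 171.2)

HELIX_PHI = -57.0
HELIX_PSI = -47.0


# ---------------------------------------------------------------------------
# analytic two-level folding model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoLevelModel:
    """Two-level surrogate for a folded/unfolded landscape.

    A single folded level at ``e_folded`` with degeneracy ``g_folded`` and an
    unfolded level at ``e_unfolded`` (> e_folded) with degeneracy
    ``g_unfolded``; energies in kcal/mol.  Its equilibrium folded fraction is
    available in closed form, which makes it the analytic oracle for every
    thermodynamic test of the samplers.
    """

    e_folded: float
    e_unfolded: float
    g_folded: int = 1
    g_unfolded: int = 1

    def __post_init__(self):
        if not self.e_unfolded > self.e_folded:
            raise ValueError("require e_unfolded > e_folded")
        if self.g_folded < 1 or self.g_unfolded < 1:
            raise ValueError("degeneracies must be >= 1")


def boltzmann_fraction(m: TwoLevelModel, temperature: float) -> float:
    """Equilibrium folded fraction of a two-level model at temperature T (K):

    g_f exp(-e_f/kT) / (g_f exp(-e_f/kT) + g_u exp(-e_u/kT)).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    beta = 1.0 / (KB_KCAL * temperature)
    # factor out the ground state for numerical stability at low T
    w_u = m.g_unfolded * math.exp(-beta * (m.e_unfolded - m.e_folded))
    return m.g_folded / (m.g_folded + w_u)


# ---------------------------------------------------------------------------
# chain construction from backbone dihedrals
# ---------------------------------------------------------------------------


def build_chain(
    phis,
    psis,
    sequence: str | None = None,
    start_index: int = 1,
    structure_id: str = "chain",
) -> Structure:
    """Build a peptide with backbone heavy atoms N, CA, C, O and a CB stub
    from per-residue (phi, psi) dihedrals, ideal bond geometry and trans
    peptide bonds.

    ``sequence`` is a one-letter string (default poly-alanine); glycine gets
    no CB.  ``start_index`` sets the first residue number so fragments cut
    from a larger protein keep their native numbering.
    """
    phis = list(phis)
    psis = list(psis)
    n = len(phis)
    if n != len(psis):
        raise ValueError("phi and psi lists must have equal length")
    if n < 2:
        raise ValueError("need at least 2 residues")
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length must match dihedral count")

    n_pos = [None] * n
    ca_pos = [None] * n
    c_pos = [None] * n

    n_pos[0] = np.zeros(3)
    ca_pos[0] = np.array([geometry.BOND_N_CA, 0.0, 0.0])
    ang = math.radians(geometry.ANGLE_N_CA_C)
    c_pos[0] = ca_pos[0] + geometry.BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, n):
        n_pos[i] = geometry.place_atom(
            n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
            geometry.BOND_C_N, geometry.ANGLE_CA_C_N, psis[i - 1],
        )
        ca_pos[i] = geometry.place_atom(
            ca_pos[i - 1], c_pos[i - 1], n_pos[i],
            geometry.BOND_N_CA, geometry.ANGLE_C_N_CA, 180.0,
        )
        c_pos[i] = geometry.place_atom(
            c_pos[i - 1], n_pos[i], ca_pos[i],
            geometry.BOND_CA_C, geometry.ANGLE_N_CA_C, phis[i],
        )

    atoms: list[AtomRecord] = []
    for i in range(n):
        resname = _THREE_LETTER[sequence[i].upper()]
        ri = start_index + i
        o = geometry.place_atom(
            n_pos[i], ca_pos[i], c_pos[i],
            geometry.BOND_C_O, geometry.ANGLE_CA_C_O, psis[i] + 180.0,
        )
        atoms.append(AtomRecord("N", ri, resname, n_pos[i]))
        atoms.append(AtomRecord("CA", ri, resname, ca_pos[i]))
        atoms.append(AtomRecord("C", ri, resname, c_pos[i]))
        atoms.append(AtomRecord("O", ri, resname, o))
        if resname != "GLY":
            atoms.append(
                AtomRecord("CB", ri, resname, geometry.cb_position(n_pos[i], ca_pos[i], c_pos[i]))
            )
    return Structure(atoms, id=structure_id).validate()


def _hairpin_dihedrals(n_residues: int):
    half = n_residues // 2
    special = {
        half - 2: TURN_FLANK_IN,
        half - 1: TURN_DIHEDRALS[0],
        half: TURN_DIHEDRALS[1],
        half + 1: TURN_FLANK_OUT,
    }
    phis, psis = [], []
    for i in range(n_residues):
        phi, psi = special.get(i, (STRAND_PHI, STRAND_PSI))
        phis.append(phi)
        psis.append(psi)
    return phis, psis


def make_ideal_hairpin(
    n_residues: int, sequence: str | None = None, start_index: int = 1
) -> Structure:
    """Idealized antiparallel β-hairpin: two strands of ideal β geometry
    joined by a tight two-residue turn.

    Consecutive CA-CA virtual bonds come out at 3.80 ± 0.05 Å and the two
    strands form the reciprocal inter-strand backbone H-bond ladder expected
    of an antiparallel hairpin (detectable by
    :func:`foldscale.analysis.detect_backbone_hbonds`).
    """
    if n_residues < 6 or n_residues % 2:
        raise ValueError("n_residues must be an even integer >= 6")
    phis, psis = _hairpin_dihedrals(n_residues)
    return build_chain(
        phis, psis, sequence=sequence, start_index=start_index, structure_id="ideal-hairpin"
    )


def make_extended_chain(
    n_residues: int, sequence: str | None = None, start_index: int = 1
) -> Structure:
    """Fully extended chain (phi ~ -180°, psi ~ +180°); forms no backbone
    hydrogen bonds."""
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    return build_chain(
        [-180.0] * n_residues,
        [180.0] * n_residues,
        sequence=sequence,
        start_index=start_index,
        structure_id="extended",
    )


def make_ideal_helix(
    n_residues: int, sequence: str | None = None, start_index: int = 1
) -> Structure:
    """Ideal α-helix (phi -57°, psi -47°) with the (i+4 -> i) H-bond ladder."""
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5 for a helix")
    return build_chain(
        [HELIX_PHI] * n_residues,
        [HELIX_PSI] * n_residues,
        sequence=sequence,
        start_index=start_index,
        structure_id="ideal-helix",
    )


def make_gb1_hairpin_standin() -> Structure:
    """Synthetic stand-in for the GB1 C-terminal β-hairpin (2GB1, residues
    41-56).

    This is NOT the experimental 2GB1 structure: it is the idealized hairpin
    generator applied to the real GEWTYDDATKTFTVTE sequence with native
    residue numbering 41-56, for use where the pipeline needs a GB1-like
    native and no structure file is supplied.
    """
    s = make_ideal_hairpin(16, sequence=GB1_HAIRPIN_SEQUENCE, start_index=41)
    s.id = "gb1-hairpin-standin-synthetic"
    return s


def perturb_structure(s: Structure, amplitude: float, seed: int) -> Structure:
    """Decoy generator: independent Gaussian displacement (sd = ``amplitude``
    Å) on every atom; same topology; deterministic for a fixed seed."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, amplitude, size=(len(s.atoms), 3)) if amplitude > 0 else 0.0
    atoms = []
    for k, a in enumerate(s.atoms):
        shift = noise[k] if amplitude > 0 else np.zeros(3)
        atoms.append(AtomRecord(a.atom_name, a.residue_index, a.residue_name, a.coords + shift))
    return Structure(atoms, id=f"{s.id}-perturbed")
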