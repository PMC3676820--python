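"""Convergence and structure diagnostics.

The folded criterion is the distance-RMSD over native backbone contacts

    dRMS = sqrt( sum_{(i,j)} (r_ij - r_ij^0)^2 / N_bb ),   |res(i)-res(j)| > 2,

where the sum runs over backbone atom pairs (CA, C, N, O) closer than a
cutoff (default 4.5 Å) in the native conformation, r_ij is the candidate
distance and r_ij^0 the native one.  Being built from internal distances,
dRMS is invariant under rigid motion of the candidate, unlike coordinate
RMSD.  A conformation counts as folded when dRMS is strictly below a
threshold.

Note on the threshold: the folded criterion is quoted in the literature as
0.15 Å, which is implausibly strict for a distance-RMSD over native contacts
and is most likely a units slip for 0.15 nm; the package default is therefore
1.5 Å, with any other value (including the literal 0.15 Å) available through
the ``threshold`` argument / ``--drms-cutoff`` flag.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model; amide hydrogens are constructed geometrically (1.01 Å from N, anti to
the preceding carbonyl), so input structures need heavy atoms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import Structure, Trajectory
from . import geometry

__all__ = [
    "NativeContactSet",
    "MeltingCurve",
    "HBond",
    "SSMatrix",
    "DEFAULT_DRMS_THRESHOLD",
    "native_contacts",
    "drms",
    "drms_ca",
    "is_folded",
    "crmsd",
    "make_drms_folded_fn",
    "folded_count_series",
    "melting_curve",
    "plateau_sweep",
    "detect_backbone_hbonds",
    "native_hbond_pattern",
    "count_native_hbonds",
    "assign_ss",
    "ss_propagation",
    "density_map",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
DEFAULT_DRMS_THRESHOLD = 1.5  # Å; see module docstring on the 0.15 value


# ---------------------------------------------------------------------------
# native contacts and dRMS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NativeContactSet:
    """Backbone atom pairs within the native cutoff, with native distances.

    ``contacts`` holds ((res_i, atom_i), (res_j, atom_j), r0) triples, each
    unordered pair once; ``n_bb`` is the contact count entering the dRMS
    normalisation.
    """

    contacts: tuple
    cutoff: float

    @property
    def n_bb(self) -> int:
        return len(self.contacts)

    def pair_arrays(self, s: Structure):
        """Index arrays (i, j, r0) into ``s.atoms`` for vectorised dRMS."""
        index = {(a.residue_index, a.atom_name): k for k, a in enumerate(s.atoms)}
        try:
            ii = np.array([index[c[0]] for c in self.contacts], dtype=int)
            jj = np.array([index[c[1]] for c in self.contacts], dtype=int)
        except KeyError as exc:
            raise ValueError(f"candidate structure lacks contact atom {exc}") from exc
        r0 = np.array([c[2] for c in self.contacts], dtype=float)
        return ii, jj, r0

    def ca_pair_arrays(self, residue_indices):
        """Row indices into a CA coordinate array, for CA-only contact sets."""
        row = {ri: k for k, ri in enumerate(residue_indices)}
        for (ri, ai), (rj, aj), _ in self.contacts:
            if ai != "CA" or aj != "CA":
                raise ValueError("contact set is not CA-only")
        ii = np.array([row[c[0][0]] for c in self.contacts], dtype=int)
        jj = np.array([row[c[1][0]] for c in self.contacts], dtype=int)
        r0 = np.array([c[2] for c in self.contacts], dtype=float)
        return ii, jj, r0


def native_contacts(
    native: Structure,
    cutoff: float = 4.5,
    min_sep: int = 2,
    atom_names=BACKBONE_ATOMS,
) -> NativeContactSet:
    """All backbone atom pairs with |res(i)-res(j)| > ``min_sep`` within
    ``cutoff`` Å in the native conformation.

    ``atom_names`` defaults to the heavy backbone atoms (N, CA, C, O); pass
    ``("CA",)`` for CA-trace contact sets used with coarse-grained sampling.
    """
    native.validate()
    sel = [a for a in native.atoms if a.atom_name in atom_names]
    for ri in native.residue_indices:
        have = {a.atom_name for a in sel if a.residue_index == ri}
        missing = set(atom_names) - have
        # terminal O may be missing in stripped files; everything else must be there
        if missing and not (missing == {"O"} and ri == native.residue_indices[-1]):
            raise ValueError(f"residue {ri} lacks backbone atom(s) {sorted(missing)}")
    coords = np.array([a.coords for a in sel])
    contacts = []
    for i in range(len(sel)):
        for j in range(i + 1, len(sel)):
            if abs(sel[i].residue_index - sel[j].residue_index) <= min_sep:
                continue
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            if r0 <= cutoff:
                contacts.append(
                    (
                        (sel[i].residue_index, sel[i].atom_name),
                        (sel[j].residue_index, sel[j].atom_name),
                        r0,
                    )
                )
    return NativeContactSet(tuple(contacts), cutoff=cutoff)


def drms(candidate: Structure, ncs: NativeContactSet) -> float:
    """Distance-RMSD of ``candidate`` over the native contact set, in Å."""
    if ncs.n_bb == 0:
        raise ValueError("dRMS is undefined for an empty contact set")
    ii, jj, r0 = ncs.pair_arrays(candidate)
    xyz = np.array([a.coords for a in candidate.atoms])
    r = np.linalg.norm(xyz[ii] - xyz[jj], axis=1)
    return float(np.sqrt(np.mean((r - r0) ** 2)))


def drms_ca(ca_coords: np.ndarray, ncs: NativeContactSet, residue_indices) -> float:
    """dRMS evaluated directly on a CA coordinate array (CA-only contact set)."""
    if ncs.n_bb == 0:
        raise ValueError("dRMS is undefined for an empty contact set")
    ii, jj, r0 = ncs.ca_pair_arrays(residue_indices)
    r = np.linalg.norm(ca_coords[ii] - ca_coords[jj], axis=1)
    return float(np.sqrt(np.mean((r - r0) ** 2)))


def is_folded(
    candidate: Structure, ncs: NativeContactSet, threshold: float = DEFAULT_DRMS_THRESHOLD
) -> bool:
    """Folded criterion: dRMS strictly below ``threshold``."""
    return drms(candidate, ncs) < threshold


def crmsd(candidate: Structure, reference: Structure) -> float:
    """CA coordinate RMSD after optimal rigid (proper-rotation) superposition."""
    p = candidate.ca_coords()
    q = reference.ca_coords()
    if p.shape != q.shape:
        raise ValueError(f"CA count mismatch: {p.shape[0]} vs {q.shape[0]}")
    r, cp, cq = geometry.kabsch_rotation(p, q)
    aligned = (p - cp) @ r.T + cq
    return float(np.sqrt(np.mean(np.sum((aligned - q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# folded-replica counts and melting curves
# ---------------------------------------------------------------------------


def make_drms_folded_fn(ncs: NativeContactSet, residue_indices, threshold: float = DEFAULT_DRMS_THRESHOLD):
    """Predicate mapping a CA coordinate array to the folded criterion."""

    ii, jj, r0 = ncs.ca_pair_arrays(residue_indices)

    def folded(state) -> bool:
        r = np.linalg.norm(state[ii] - state[jj], axis=1)
        return bool(np.sqrt(np.mean((r - r0) ** 2)) < threshold)

    return folded


def folded_count_series(result, folded_fn, stride: int = 1):
    """Number of temperature slots holding a folded conformation over time.

    ``result`` is an :class:`~foldscale.remd.REMDResult`; ``folded_fn`` maps a
    replica state to a bool (see :func:`make_drms_folded_fn`).  Returns
    (sweeps, counts) arrays; counts lie in [0, n_replicas].
    """
    sweeps = result.record_sweeps[::stride]
    counts = np.zeros(len(sweeps), dtype=int)
    for s, slot_states in enumerate(result.slot_states):
        flags = [folded_fn(slot_states[k]) for k in range(0, len(slot_states), stride)]
        counts += np.asarray(flags, dtype=int)
    return np.asarray(sweeps), counts


def _block_bootstrap_se(flags: np.ndarray, block: int, n_boot: int, rng) -> float:
    n = len(flags)
    if n == 0:
        raise ValueError("empty series")
    block = max(1, min(block, n))
    n_blocks = math.ceil(n / block)
    means = np.empty(n_boot)
    starts_max = n - block + 1
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        sample = np.concatenate([flags[s : s + block] for s in starts])[:n]
        means[b] = sample.mean()
    return float(means.std(ddof=1))


@dataclass
class MeltingCurve:
    """Per-temperature folded fraction over a sweep window, with a
    block-bootstrap standard error per point."""

    temperatures: np.ndarray
    fractions: np.ndarray
    errors: np.ndarray
    window: tuple

    def __post_init__(self):
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("folded fractions must lie in [0, 1]")


def melting_curve(
    result,
    folded_fn,
    window: tuple,
    block: int = 20,
    n_boot: int = 200,
    seed: int = 0,
) -> MeltingCurve:
    """Folded fraction vs slot temperature over a sweep window.

    ``window`` is (start_sweep, end_sweep), inclusive of records whose sweep
    lies in [start, end).  Each point averages a single fixed-temperature
    slot; uncertainty is a moving-block bootstrap (frames are autocorrelated,
    so i.i.d. errors would be optimistic).
    """
    rng = np.random.default_rng(seed)
    sweeps = np.asarray(result.record_sweeps)
    mask = (sweeps >= window[0]) & (sweeps < window[1])
    if not np.any(mask):
        raise ValueError(f"window {window} contains no records")
    fractions, errors = [], []
    for slot_states in result.slot_states:
        flags = np.array(
            [folded_fn(st) for st, m in zip(slot_states, mask) if m], dtype=float
        )
        fractions.append(flags.mean())
        errors.append(_block_bootstrap_se(flags, block, n_boot, rng))
    return MeltingCurve(
        temperatures=np.asarray(result.temperatures, dtype=float),
        fractions=np.asarray(fractions),
        errors=np.asarray(errors),
        window=tuple(window),
    )


def plateau_sweep(sweeps, counts, tolerance: float = 1.0, smooth: int = 1) -> int:
    """First sweep after which the folded-replica count stays within
    ``tolerance`` of its final median (median of the last quarter).

    The convergence diagnostic behind seeded-vs-extended comparisons: a run
    has equilibrated once the count has reached and holds its stationary
    level.  ``smooth`` applies a trailing moving average over that many
    records first — the instantaneous count of a small ladder fluctuates by
    a replica or two even at equilibrium, and the plateau is a statement
    about the level, not the noise.  Returns the last recorded sweep if the
    series never settles.
    """
    sweeps = np.asarray(sweeps)
    counts = np.asarray(counts, dtype=float)
    if smooth > 1:
        c = np.cumsum(np.insert(counts, 0, 0.0))
        idx = np.arange(len(counts))
        lo = np.maximum(0, idx - smooth + 1)
        counts = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    tail = counts[-max(1, len(counts) // 4):]
    final = np.median(tail)
    ok = np.abs(counts - final) <= tolerance
    # find earliest k with ok[k:] all true
    settled = len(counts)
    for k in range(len(counts) - 1, -1, -1):
        if ok[k]:
            settled = k
        else:
            break
    if settled >= len(counts):
        return int(sweeps[-1])
    return int(sweeps[settled])


# ---------------------------------------------------------------------------
# backbone hydrogen bonds and secondary structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HBond:
    """A backbone N-H...O=C hydrogen bond, Kabsch-Sander energy in kcal/mol."""

    donor: int
    acceptor: int
    energy: float

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


_KS_COUPLING = 0.084 * 332.0  # kcal/mol·Å, Kabsch-Sander q1*q2*f
KS_ENERGY_CUTOFF = -0.5  # kcal/mol


def _amide_hydrogens(s: Structure) -> dict:
    """Geometric amide H per residue: 1.01 Å from N, anti to the preceding
    carbonyl (H-N parallel to C=O of residue i-1).  No H on the N-terminus
    or proline."""
    res = s.residue_indices
    hydrogens = {}
    for prev, ri in zip(res, res[1:]):
        if s.residue_name(ri) == "PRO":
            continue
        n = s.atom(ri, "N").coords
        c_prev = s.atom(prev, "C").coords
        o_prev = s.atom(prev, "O").coords
        hydrogens[ri] = n + 1.01 * geometry.unit(c_prev - o_prev)
    return hydrogens


def detect_backbone_hbonds(s: Structure, energy_cutoff: float = KS_ENERGY_CUTOFF) -> list[HBond]:
    """Backbone H-bonds by the Kabsch-Sander electrostatic criterion.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol for donor
    N-H (residue d) and acceptor C=O (residue a); a bond is reported when
    E < ``energy_cutoff`` and |d - a| >= 2.  Amide hydrogens are built
    geometrically, so only heavy backbone atoms are required.
    """
    s.validate()
    res = s.residue_indices
    for ri in res:
        for name in ("N", "CA", "C"):
            if not s.has_atom(ri, name):
                raise ValueError(f"residue {ri} lacks backbone atom {name}")
        if not s.has_atom(ri, "O") and ri != res[-1]:
            raise ValueError(f"residue {ri} lacks backbone atom O")
    hydrogens = _amide_hydrogens(s)
    bonds = []
    for d in res:
        if d not in hydrogens:
            continue
        h = hydrogens[d]
        n = s.atom(d, "N").coords
        for a in res:
            if abs(d - a) < 2 or not s.has_atom(a, "O"):
                continue
            c = s.atom(a, "C").coords
            o = s.atom(a, "O").coords
            r_on = np.linalg.norm(o - n)
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - n)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clash: treat as no bond
                continue
            e = _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < energy_cutoff:
                bonds.append(HBond(donor=d, acceptor=a, energy=float(e)))
    return sorted(bonds, key=lambda b: (b.donor, b.acceptor))


def native_hbond_pattern(native: Structure) -> list[tuple[int, int]]:
    """(donor, acceptor) pairs of the native backbone H-bond network."""
    return [(b.donor, b.acceptor) for b in detect_backbone_hbonds(native)]


def count_native_hbonds(s: Structure, native_pattern) -> int:
    """How many native donor->acceptor backbone H-bonds are present in ``s``."""
    if not native_pattern:
        raise ValueError("native H-bond pattern must be non-empty")
    present = {(b.donor, b.acceptor) for b in detect_backbone_hbonds(s)}
    return sum(1 for pair in native_pattern if tuple(pair) in present)


def assign_ss(s: Structure) -> dict:
    """Per-residue secondary-structure code in {H, E, C}.

    H: residue inside a helical segment supported by two consecutive
    (i+4 -> i) backbone H-bonds.  E: residue in an antiparallel bridge
    (reciprocal inter-strand bond pair), with single-residue gaps between
    bridges on the same strand filled in.  Everything else: C.
    """
    res = s.residue_indices
    bonds = {(b.donor, b.acceptor) for b in detect_backbone_hbonds(s)}
    code = {ri: "C" for ri in res}

    # helix: 4-turn at i when bond (i+4 -> i); residues i+1..i+4 of two
    # consecutive turns are helical
    turns = {i for (d, a) in bonds if d - a == 4 for i in [a]}
    for i in sorted(turns):
        if i + 1 in turns or i - 1 in turns:
            lo = i + 1 if i - 1 not in turns else i
            for r in range(lo, i + 5):
                if r in code:
                    code[r] = "H"

    # antiparallel bridges: reciprocal pair i->j and j->i with |i-j| >= 3
    bridge = set()
    for (d, a) in bonds:
        if abs(d - a) >= 3 and (a, d) in bonds:
            bridge.add(d)
            bridge.add(a)
    for r in bridge:
        if code[r] == "C":
            code[r] = "E"
    # fill single gaps between bridge residues (the non-H-bonded partner in
    # the pleat alternation)
    for r in res:
        if code[r] == "C" and (r - 1 in bridge) and (r + 1 in bridge):
            code[r] = "E"
    return code


@dataclass
class SSMatrix:
    """Secondary-structure codes on a residue x frame grid."""

    residue_indices: list
    steps: list
    codes: np.ndarray  # dtype '<U1', shape (n_residues, n_frames)

    def __post_init__(self):
        if self.codes.shape != (len(self.residue_indices), len(self.steps)):
            raise ValueError("codes grid does not match labels")


def ss_propagation(t: Trajectory) -> SSMatrix:
    """Secondary structure per residue over the frames of a trajectory."""
    if not t.frames:
        raise ValueError("empty trajectory")
    res = t.frames[0].structure.residue_indices
    cols = []
    for k, frame in enumerate(t.frames):
        if frame.structure.residue_indices != res:
            raise ValueError(f"topology drift at frame {k}")
        code = assign_ss(frame.structure)
        cols.append([code[r] for r in res])
    return SSMatrix(
        residue_indices=res,
        steps=[f.step for f in t.frames],
        codes=np.array(cols, dtype="<U1").T,
    )


def density_map(t: Trajectory, reference: Structure, bins=50):
    """2-D histogram of (potential energy, CRMSD to reference) over frames.

    Returns (counts, energy_edges, crmsd_edges); counts sum to the frame
    count.
    """
    energies = t.energies
    if np.any(np.isnan(energies)):
        raise ValueError("density map requires an energy on every frame")
    rms = np.array([crmsd(f.structure, reference) for f in t.frames])
    counts, e_edges, r_edges = np.histogram2d(energies, rms, bins=bins)
    return counts, e_edges, r_edges
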