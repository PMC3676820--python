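"""Structures, trajectories and their on-disk formats.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of heavy atoms with 1-based residue numbering (numbering from the input
file is preserved, so a hairpin cut from a larger protein keeps its original
residue indices), and a :class:`Trajectory` is an ordered list of
:class:`Frame` objects each carrying a structure, its potential energy, a
sweep index and a temperature tag.

On disk everything is PDB v3.  Per-frame metadata has no native slot in the
PDB format, so it travels in ``REMARK 250 FOLDSCALE key=value`` lines (one
key per line, keys ``energy``, ``temperature``, ``step``); files remain valid
for third-party tools, which ignore unknown REMARKs.  Coordinates are in Å
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Frame",
    "Trajectory",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "read_multimodel",
    "write_multimodel",
    "write_tsv",
    "load_config",
]

_REMARK_PREFIX = "REMARK 250 FOLDSCALE"


class PDBFormatError(ValueError):
    """Raised when a PDB file violates the subset of the format we read."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: PDB v3 atom label, 1-based residue index, 3-letter
    residue name and Cartesian coordinates in Å."""

    atom_name: str
    residue_index: int
    residue_name: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        object.__setattr__(self, "coords", coords)


@dataclass
class Structure:
    """An ordered list of atoms forming one conformation.

    Invariants (checked by :meth:`validate`): residue indices non-decreasing
    along the chain, every residue carries a CA atom, and atom names are
    unique within a residue.
    """

    atoms: list[AtomRecord]
    id: str = ""

    def validate(self) -> "Structure":
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")
        last = None
        per_res: dict[int, set[str]] = {}
        for a in self.atoms:
            if last is not None and a.residue_index < last:
                raise ValueError(
                    f"residue indices must be non-decreasing "
                    f"(saw {a.residue_index} after {last})"
                )
            last = a.residue_index
            names = per_res.setdefault(a.residue_index, set())
            if a.atom_name in names:
                raise ValueError(
                    f"duplicate atom {a.atom_name!r} in residue {a.residue_index}"
                )
            names.add(a.atom_name)
        for idx, names in per_res.items():
            if "CA" not in names:
                raise ValueError(f"residue {idx} has no CA atom")
        return self

    # -- convenience accessors ------------------------------------------------

    @property
    def residue_indices(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if not seen or a.residue_index != seen[-1]:
                seen.append(a.residue_index)
        return seen

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise KeyError(residue_index)

    def atom(self, residue_index: int, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return a
        raise KeyError((residue_index, atom_name))

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return any(
            a.residue_index == residue_index and a.atom_name == atom_name
            for a in self.atoms
        )

    def coords_of(self, atom_name: str) -> np.ndarray:
        """Coordinates of one named atom per residue, in residue order."""
        rows = [a.coords for a in self.atoms if a.atom_name == atom_name]
        return np.array(rows, dtype=float)

    def ca_coords(self) -> np.ndarray:
        return self.coords_of("CA")

    def with_ca_coords(self, ca: np.ndarray, id: str | None = None) -> "Structure":
        """A CA-only copy of this structure's topology with new coordinates."""
        ca = np.asarray(ca, dtype=float)
        res = self.residue_indices
        if ca.shape != (len(res), 3):
            raise ValueError(f"expected CA array of shape ({len(res)}, 3)")
        atoms = [
            AtomRecord("CA", ri, self.residue_name(ri), ca[k])
            for k, ri in enumerate(res)
        ]
        return Structure(atoms, id=self.id if id is None else id)

    def copy(self) -> "Structure":
        return Structure([replace(a, coords=a.coords.copy()) for a in self.atoms], self.id)


@dataclass
class Frame:
    """One trajectory snapshot: a structure plus its potential energy
    (units declared on the trajectory), sweep index and temperature in K
    (or reduced units for reduced-unit models)."""

    structure: Structure
    energy: float | None
    step: int
    temperature: float

    def __post_init__(self):
        if self.step < 0:
            raise ValueError("step must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class Trajectory:
    frames: list[Frame]
    energy_units: str = "kcal/mol"

    def validate(self) -> "Trajectory":
        steps = [f.step for f in self.frames]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("frame steps must be strictly increasing")
        return self

    @property
    def energies(self) -> np.ndarray:
        return np.array(
            [np.nan if f.energy is None else f.energy for f in self.frames], dtype=float
        )

    @property
    def steps(self) -> np.ndarray:
        return np.array([f.step for f in self.frames], dtype=int)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB v3 reading / writing
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    try:
        return AtomRecord(name, resseq, resname, np.array([x, y, z]))
    except ValueError as exc:
        raise PDBFormatError(f"invalid atom at line {lineno}: {exc}") from exc


def _format_atom_line(serial: int, a: AtomRecord) -> str:
    if np.any(np.abs(a.coords) > 9999.999):
        raise PDBFormatError(
            f"coordinate overflow: |{a.coords}| exceeds the PDB fixed-column "
            "range (9999.999 Å)"
        )
    # PDB v3: atom names of <4 chars start in column 14
    name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s} {a.residue_name:<3s} A{a.residue_index:4d}    "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.atom_name[0]:>2s}"
    )


def read_pdb(path) -> Structure:
    """Read a single-model PDB v3 file into a :class:`Structure`.

    MODEL/ENDMDL must be absent or delimit a single model; multi-model files
    go through :func:`read_multimodel`.
    """
    atoms: list[AtomRecord] = []
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                n_models += 1
                if n_models > 1:
                    raise PDBFormatError(
                        f"multi-model file passed to read_pdb (second MODEL at "
                        f"line {lineno}); use read_multimodel"
                    )
            elif rec == "ATOM  ":
                atoms.append(_parse_atom_line(line, lineno))
    import os

    return Structure(atoms, id=os.path.splitext(os.path.basename(str(path)))[0]).validate()


def write_pdb(s: Structure, path) -> None:
    """Write a :class:`Structure` as a single-model PDB v3 file."""
    s.validate()
    with open(path, "w") as fh:
        for serial, a in enumerate(s.atoms, start=1):
            fh.write(_format_atom_line(serial, a) + "\n")
        fh.write("END\n")


def _meta_lines(frame: Frame) -> list[str]:
    lines = []
    if frame.energy is not None:
        lines.append(f"{_REMARK_PREFIX} energy={frame.energy:.10g}")
    lines.append(f"{_REMARK_PREFIX} temperature={frame.temperature:.10g}")
    lines.append(f"{_REMARK_PREFIX} step={frame.step}")
    return lines


def write_multimodel(t: Trajectory, path) -> None:
    """Write a trajectory as a MODEL/ENDMDL-delimited multi-model PDB.

    Frame metadata is carried in ``REMARK 250 FOLDSCALE key=value`` lines
    inside each model block; the energy unit label is written once at the top.
    """
    t.validate()
    with open(path, "w") as fh:
        fh.write(f"{_REMARK_PREFIX} energy_units={t.energy_units}\n")
        for i, frame in enumerate(t.frames, start=1):
            frame.structure.validate()
            fh.write(f"MODEL {i:8d}\n")
            for line in _meta_lines(frame):
                fh.write(line + "\n")
            for serial, a in enumerate(frame.structure.atoms, start=1):
                fh.write(_format_atom_line(serial, a) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel(path) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB written by :func:`write_multimodel`.

    A missing ``energy`` REMARK leaves the frame energy as ``None`` (missing),
    never zero.  All models must share one atom count.
    """
    frames: list[Frame] = []
    energy_units = "kcal/mol"
    atoms: list[AtomRecord] | None = None
    meta: dict[str, str] = {}
    n_atoms_ref: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if line.startswith(_REMARK_PREFIX):
                key, _, value = line[len(_REMARK_PREFIX):].strip().partition("=")
                if key == "energy_units":
                    energy_units = value
                else:
                    meta[key] = value
            elif rec == "MODEL ":
                atoms, meta = [], {}
            elif rec == "ATOM  ":
                if atoms is None:  # tolerate bare single-model files
                    atoms = []
                atoms.append(_parse_atom_line(line, lineno))
            elif rec == "ENDMDL":
                if atoms is None:
                    raise PDBFormatError(f"ENDMDL without MODEL at line {lineno}")
                if n_atoms_ref is None:
                    n_atoms_ref = len(atoms)
                elif len(atoms) != n_atoms_ref:
                    raise PDBFormatError(
                        f"inconsistent atom count across models: model "
                        f"{len(frames) + 1} has {len(atoms)}, expected {n_atoms_ref}"
                    )
                frames.append(
                    Frame(
                        structure=Structure(atoms).validate(),
                        energy=float(meta["energy"]) if "energy" in meta else None,
                        step=int(meta.get("step", len(frames))),
                        temperature=float(meta.get("temperature", 300.0)),
                    )
                )
                atoms = None
    if atoms:  # bare file without MODEL/ENDMDL: one frame
        frames.append(
            Frame(Structure(atoms).validate(), energy=None, step=0, temperature=300.0)
        )
    return Trajectory(frames, energy_units=energy_units).validate()


# ---------------------------------------------------------------------------
# Tabular results and configuration
# ---------------------------------------------------------------------------


def write_tsv(df, path) -> None:
    """Write a pandas DataFrame as a tab-separated table (no index column)."""
    df.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) run-configuration mapping."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg
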