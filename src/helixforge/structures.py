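"""Atomic structures: PDB reading/writing, selections, region pruning.

The :class:`Structure` is a thin, array-backed container (one row per
atom) with author residue numbering preserved verbatim.  Parsing and
serialization are delegated to biotite; alternate locations are reduced
to the highest-occupancy conformer and waters/heteroatoms are dropped by
default (cofactors can be retained on request).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "Structure",
    "RegionSpec",
    "StructureError",
    "FormatError",
    "SelectionError",
    "DegenerateStructureError",
    "read_structure",
    "write_structure",
    "prune_regions",
    "paired_coords",
    "crystal_neighbor",
    "symmetry_mates",
    "chain_id_sequence",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


class StructureError(Exception):
    """Base error for structure handling."""


class FormatError(StructureError):
    """The input file could not be parsed."""


class SelectionError(StructureError):
    """A selection matched nothing or could not be paired."""


class DegenerateStructureError(StructureError):
    """An operation left too few residues to be meaningful."""


@dataclass(frozen=True)
class Structure:
    """Array-backed atomic structure (one entry per atom)."""

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    ins_codes: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        for name in ("atom_names", "elements", "res_names", "chain_ids", "ins_codes"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype="U6"))
        object.__setattr__(self, "res_ids", np.asarray(self.res_ids, dtype=int))

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_id, ins_code) keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_ids, self.res_ids, self.ins_codes):
            seen.setdefault((str(c), int(r), str(i)))
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def max_radius(self) -> float:
        """Maximum atom distance from the centroid (the R_M of the
        filament/cyclic classification)."""
        return float(np.linalg.norm(self.coords - self.centroid(), axis=1).max())

    # -- selection -----------------------------------------------------------

    def mask(self, m: np.ndarray, label: str | None = None) -> "Structure":
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise SelectionError("selection matched no atoms")
        return Structure(
            self.atom_names[m], self.elements[m], self.res_ids[m],
            self.ins_codes[m], self.res_names[m], self.chain_ids[m],
            self.coords[m], label if label is not None else self.label,
        )

    def select_atoms(self, atom_name: str = "CA") -> "Structure":
        return self.mask(self.atom_names == atom_name)

    def select_chain(self, chain_id: str) -> "Structure":
        return self.mask(self.chain_ids == chain_id)

    def select_residues(self, res_ids) -> "Structure":
        wanted = set(int(r) for r in res_ids)
        return self.mask(np.array([int(r) in wanted for r in self.res_ids]))

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def transformed(self, T, label: str | None = None) -> "Structure":
        return replace(self, coords=T.apply(self.coords),
                       label=label if label is not None else self.label)

    def with_chain_id(self, chain_id: str) -> "Structure":
        return replace(self, chain_ids=np.full(len(self), chain_id, dtype="U6"))

    def renumber_residues(self, offset: int) -> "Structure":
        return replace(self, res_ids=self.res_ids + offset)


@dataclass(frozen=True)
class RegionSpec:
    """Named residue ranges (inclusive) plus boundary residues.

    ``ranges`` maps a region name to a list of (first, last) residue-id
    pairs.  ``boundary_residues`` lists single residues flanking the
    flexible regions; they are used by the docking pose filter, not by
    pruning.
    """

    ranges: dict[str, list[tuple[int, int]]]
    boundary_residues: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, spans in self.ranges.items():
            covered: set[int] = set()
            for lo, hi in spans:
                if lo > hi:
                    raise ValueError(f"region {name!r}: range {lo}-{hi} inverted")
                span = set(range(lo, hi + 1))
                if covered & span:
                    raise ValueError(f"region {name!r}: overlapping ranges")
                covered |= span

    def residues(self) -> set[int]:
        out: set[int] = set()
        for spans in self.ranges.values():
            for lo, hi in spans:
                out.update(range(lo, hi + 1))
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RegionSpec":
        ranges = {
            name: [(int(lo), int(hi)) for lo, hi in spans]
            for name, spans in data.get("ranges", {}).items()
        }
        return cls(ranges, tuple(int(r) for r in data.get("boundary_residues", ())))


#: region definition of the RecA monomer used throughout the worked
#: system: N-terminal domain, loops L1/L2 and the disordered termini,
#: with the boundary residues flanking the flexible regions.
RECA_REGIONS = RegionSpec(
    ranges={
        "Nter": [(1, 37)],
        "L1": [(156, 165)],
        "L2": [(194, 210)],
        "Cter": [(329, 333)],
    },
    boundary_residues=(38, 156, 165, 194, 210),
)


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure(
    path,
    model: int = 1,
    chain: str | None = None,
    keep_hetero: bool = False,
    label: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Waters are always dropped; other heteroatoms (cofactors) are dropped
    unless ``keep_hetero``.  Of alternate locations only the
    highest-occupancy conformer is kept.
    """
    try:
        pdb = bpdb.PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=model, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    keep = atoms.res_name != "HOH"
    if not keep_hetero:
        keep &= ~atoms.hetero
    keep &= atoms.element != "H"
    atoms = atoms[keep]
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise SelectionError(f"empty selection reading {path} (chain={chain!r})")
    return _from_biotite(atoms, label or str(path))


def _from_biotite(atoms: bst.AtomArray, label: str) -> Structure:
    return Structure(
        atom_names=atoms.atom_name,
        elements=atoms.element,
        res_ids=atoms.res_id,
        ins_codes=atoms.ins_code,
        res_names=atoms.res_name,
        chain_ids=atoms.chain_id,
        coords=atoms.coord,
        label=label,
    )


def _to_biotite(s: Structure) -> bst.AtomArray:
    n = len(s)
    atoms = bst.AtomArray(n)
    atoms.coord = s.coords.astype(np.float32)
    atoms.atom_name = s.atom_names
    atoms.element = s.elements
    atoms.res_id = s.res_ids
    atoms.ins_code = s.ins_codes
    atoms.res_name = s.res_names
    atoms.chain_id = np.array([c[:4] for c in s.chain_ids], dtype="U4")
    atoms.hetero = np.array([rn not in STANDARD_AA for rn in s.res_names])
    return atoms


def write_structure(s: Structure, path) -> None:
    """Write a Structure (or several chains) to a PDB file."""
    pdb = bpdb.PDBFile()
    pdb.set_structure(_to_biotite(s))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# regions


def prune_regions(s: Structure, spec: RegionSpec, min_residues: int = 10) -> Structure:
    """Remove all residues covered by ``spec`` ranges.

    Residues listed in the spec but absent from the structure (already
    disordered) are ignored silently.  Raises
    :class:`DegenerateStructureError` if fewer than ``min_residues``
    remain.
    """
    drop = spec.residues()
    if not drop:
        return s
    keep = np.array([int(r) not in drop for r in s.res_ids])
    if not keep.any():
        raise DegenerateStructureError("pruning removed every residue")
    out = s.mask(keep)
    if out.n_residues < min_residues:
        raise DegenerateStructureError(
            f"pruning left only {out.n_residues} residues (< {min_residues})"
        )
    return out


# ---------------------------------------------------------------------------
# pairing for superposition


def paired_coords(a: Structure, b: Structure, selection: str = "CA",
                  min_pairs: int = 3):
    """Coordinates of atoms shared by both structures.

    Atoms are matched by (res_id, ins_code, atom_name); chain identity is
    ignored so that copies of the same monomer placed in different chains
    can be paired.  With ``selection`` set, only that atom name is used
    (Calpha by default).
    """

    def index(s: Structure) -> dict:
        idx = {}
        for i in range(len(s)):
            if selection and s.atom_names[i] != selection:
                continue
            key = (int(s.res_ids[i]), str(s.ins_codes[i]), str(s.atom_names[i]))
            idx.setdefault(key, i)
        return idx

    ia, ib = index(a), index(b)
    common = [k for k in ia if k in ib]
    if len(common) < min_pairs:
        raise SelectionError(
            f"only {len(common)} paired atoms for selection {selection!r}"
        )
    ca = np.array([a.coords[ia[k]] for k in common])
    cb = np.array([b.coords[ib[k]] for k in common])
    return ca, cb


# ---------------------------------------------------------------------------
# crystal symmetry


def symmetry_mates(path, s: Structure, cells: int = 1) -> list[Structure]:
    """Generate crystal symmetry mates of ``s`` from the PDB header.

    Uses the REMARK 290 SMTRY operators plus lattice translations within
    ``cells`` unit cells in each direction.  The identity placement is
    excluded.
    """
    ops = _parse_smtry(path)
    cell = _parse_cryst1(path)
    if cell is None or not ops:
        raise FormatError(f"{path}: missing CRYST1 / REMARK 290 symmetry records")
    a_vec, b_vec, c_vec = cell
    mates = []
    shifts = range(-cells, cells + 1)
    for k, (R, t) in enumerate(ops):
        for ia in shifts:
            for ib in shifts:
                for ic in shifts:
                    shift = ia * a_vec + ib * b_vec + ic * c_vec
                    if k == 0 and ia == ib == ic == 0:
                        continue  # identity
                    coords = s.coords @ R.T + t + shift
                    mates.append(replace(s, coords=coords,
                                         label=f"{s.label}|sym{k}:{ia},{ib},{ic}"))
    return mates


def crystal_neighbor(path, s: Structure, contact_cutoff: float = 5.0) -> Structure:
    """Closest contacting symmetry mate of ``s`` (by centroid distance).

    This reconstructs the adjacent monomer of a helical crystal form
    (e.g. a P6_1 filament) from the asymmetric unit.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(s.coords)
    best = None
    best_d = np.inf
    c0 = s.centroid()
    for mate in symmetry_mates(path, s):
        d = np.linalg.norm(mate.centroid() - c0)
        if d < 1.0 or d >= best_d:
            continue
        n_contact = tree.query_ball_point(mate.coords, contact_cutoff,
                                          return_length=True).sum()
        if n_contact > 0:
            best, best_d = mate, d
    if best is None:
        raise SelectionError(f"no contacting symmetry mate found for {s.label}")
    return best


def _parse_cryst1(path):
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                a, b, c = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                al, be, ga = (float(line[33:40]), float(line[40:47]), float(line[47:54]))
                al, be, ga = np.radians([al, be, ga])
                av = np.array([a, 0.0, 0.0])
                bv = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
                cx = c * np.cos(be)
                cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
                cz = np.sqrt(max(c**2 - cx**2 - cy**2, 0.0))
                return av, bv, np.array([cx, cy, cz])
    return None


def _parse_smtry(path):
    rows: dict[int, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 290") and "SMTRY" in line:
                parts = line.split()
                # REMARK 290 SMTRYn  op  r1 r2 r3 t
                tag = parts[2]
                op = int(parts[3])
                vals = [float(x) for x in parts[4:8]]
                rows.setdefault(op, [None, None, None])[int(tag[-1]) - 1] = vals
    ops = []
    for op in sorted(rows):
        mat = np.array(rows[op])
        ops.append((mat[:, :3], mat[:, 3]))
    return ops


def chain_id_sequence():
    """Deterministic chain-id generator: A..Z, a..z, 0..9, AA, AB, ..."""
    singles = string.ascii_uppercase + string.ascii_lowercase + string.digits
    yield from singles
    for c1 in string.ascii_uppercase:
        for c2 in string.ascii_uppercase:
            yield c1 + c2
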