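"""RecA worked-system analyses.

Everything here is computed from deposited crystal structures; the PDB
files (2REB, 3CMW, 1U94) must be fetched separately, e.g.::

    curl -O https://files.rcsb.org/download/2REB.pdb   # etc.

and placed in a data directory (default ``data/`` at the repository
root, overridable via the ``HW_PDB_DIR`` environment variable).

The X binding mode is the adjacent monomer pair of the 2REB crystal
(P6_1 symmetry, compressed/ADP filament); X* is the pair formed by
monomers 2 and 3 of the 3CMW fusion-protein pentamer (extended/ATP
filament).  Mixed-mode filaments chain X and X* interface transforms.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .geometry import (
    Screw,
    helix_params,
    screw_between_monomers,
    screw_from_transform,
    superpose,
)
from .metrics import contacts, fnat, rmsd
from .structures import (
    RECA_REGIONS,
    RegionSpec,
    Structure,
    crystal_neighbor,
    prune_regions,
    read_structure,
)

__all__ = [
    "PdbDataMissing",
    "pdb_path",
    "load_2reb_monomer",
    "x_dimer",
    "split_3cmw_monomers",
    "x_screw",
    "xstar_screw",
    "core",
    "NTER_HELIX",
    "acceptance_values",
]

#: N-terminal helix residue range (flexibly attached to the core)
NTER_HELIX = (6, 23)

FETCH_HINT = (
    "deposited coordinates required; fetch with e.g.\n"
    "  mkdir -p data && cd data\n"
    "  for id in 2REB 3CMW 1U94; do"
    " curl -sO https://files.rcsb.org/download/$id.pdb; done"
)


class PdbDataMissing(FileNotFoundError):
    """A required deposited PDB file is not available locally."""


def pdb_dir() -> Path:
    return Path(os.environ.get("HW_PDB_DIR", "data"))


def pdb_path(accession: str) -> Path:
    p = pdb_dir() / f"{accession.upper()}.pdb"
    if not p.exists():
        alt = pdb_dir() / f"{accession.lower()}.pdb"
        if alt.exists():
            return alt
        raise PdbDataMissing(f"{p} not found; {FETCH_HINT}")
    return p


# ---------------------------------------------------------------------------
# structure loading


def load_2reb_monomer() -> Structure:
    """The single RecA chain of the 2REB asymmetric unit."""
    path = pdb_path("2REB")
    s = read_structure(path, label="2REB")
    ch = s.chains()[0]
    return s.select_chain(ch)


def x_dimer() -> tuple[Structure, Structure]:
    """Adjacent monomer pair of the 2REB crystal (X binding mode)."""
    path = pdb_path("2REB")
    m1 = load_2reb_monomer()
    m2 = crystal_neighbor(path, m1)
    return m1, m2


def split_3cmw_monomers() -> list[Structure]:
    """The five monomers of the 3CMW fusion pentamer.

    Monomer k occupies residues (k-1)*1000 + 1 ... 333; each returned
    copy is renumbered back to 1-333 so monomers pair residue-by-residue.
    """
    s = read_structure(pdb_path("3CMW"), label="3CMW")
    monomers = []
    for k in range(5):
        base = k * 1000
        mask = (s.res_ids > base) & (s.res_ids <= base + 999)
        if not mask.any():
            continue
        monomers.append(s.mask(mask, label=f"3CMW.m{k + 1}").renumber_residues(-base))
    if len(monomers) < 3:
        raise ValueError("3CMW fusion chain did not split into monomers")
    return monomers


def adjacent_1u94_pair() -> tuple[Structure, Structure]:
    """Adjacent monomers of the 1U94 RecA helix.

    Uses chains of the asymmetric unit when it contains several; falls
    back to a crystal symmetry mate otherwise.
    """
    path = pdb_path("1U94")
    s = read_structure(path, label="1U94")
    chains = s.chains()
    if len(chains) >= 2:
        a, b = s.select_chain(chains[0]), s.select_chain(chains[1])
        from .metrics import contacts as _contacts

        if len(_contacts(a, b)) > 0:
            return a, b
    a = s.select_chain(chains[0])
    return a, crystal_neighbor(path, a)


def core(s: Structure, regions: RegionSpec = RECA_REGIONS) -> Structure:
    """Rigid core: the monomer minus N-terminal domain, loops L1/L2 and
    the disordered termini."""
    extra = RegionSpec(
        ranges={**regions.ranges, "Nter5": [(1, 5)]},
        boundary_residues=regions.boundary_residues,
    )
    return prune_regions(s, extra)


# ---------------------------------------------------------------------------
# screws


def x_screw() -> Screw:
    m1, m2 = x_dimer()
    return screw_between_monomers(m1, m2)


def xstar_screw() -> Screw:
    monomers = split_3cmw_monomers()
    return screw_between_monomers(monomers[1], monomers[2])


# ---------------------------------------------------------------------------
# acceptance quantities


def acceptance_values(seed: int = 0) -> dict:
    """All RecA acceptance quantities computable from the deposited PDBs.

    Returns ``{target_id: {"value": float, "n": int}}``; raises
    :class:`PdbDataMissing` if a required file is absent.
    """
    out: dict[str, dict] = {}

    # 2REB: adjacent crystal monomers -> X screw
    m1, m2 = x_dimer()
    sx = screw_between_monomers(m1, m2)
    hp_x = helix_params(sx, m1)
    out["t1"] = {"value": hp_x.pitch, "n": len(m1)}

    # 3CMW monomers 2-3 -> X* screw
    mono = split_3cmw_monomers()
    sxs = screw_between_monomers(mono[1], mono[2])
    hp_xs = helix_params(sxs, mono[2])
    out["t2"] = {"value": hp_xs.pitch, "n": len(mono[2])}
    out["t3"] = {"value": hp_xs.n_per_turn, "n": len(mono[2])}

    # core-vs-core and full-monomer superposition RMSD
    core_2reb = core(m1)
    core_3cmw = core(mono[2])
    _, rmsd_core = superpose(core_2reb, core_3cmw, "CA")
    out["t4"] = {"value": rmsd_core, "n": core_2reb.n_residues}
    _, rmsd_full = superpose(m1, mono[2], "CA")
    out["t5"] = {"value": rmsd_full, "n": m1.n_residues}

    # ligand RMSD between the X and X* dimers
    val = rmsd((m1, m2), (mono[1], mono[2]), mode="ligand")
    out["t6"] = {"value": val, "n": m2.n_residues}

    # mixed-mode repeat blocks; both interface transforms expressed for
    # the same monomer frame (X* monomer 3, with X mapped onto it)
    tx, txs = _common_frame_transforms(m1, m2, mono)
    block = tx
    for _ in range(5):
        block = block.compose(txs)
    hp_super = helix_params(screw_from_transform(block), mono[2])
    # per-monomer step count of the repeat block is 6
    out["t9"] = {"value": hp_super.pitch, "n": 6}
    alt = tx.compose(txs)
    hp_alt = helix_params(screw_from_transform(alt), mono[2])
    # the 2-monomer block: N is counted in blocks; per-monomer N doubles
    out["t10"] = {"value": hp_alt.pitch, "n": 2}

    # mean local pitch over the four successive 3CMW interfaces
    pitches = []
    for a, b in zip(mono, mono[1:]):
        hp = helix_params(screw_between_monomers(a, b), b)
        pitches.append(hp.pitch)
    out["t11"] = {"value": float(np.mean(pitches)), "n": len(pitches)}

    # 1U94 helix pitch
    try:
        a, b = adjacent_1u94_pair()
        hp = helix_params(screw_between_monomers(a, b), a)
        out["t12"] = {"value": hp.pitch, "n": a.n_residues}
    except PdbDataMissing:
        pass

    return out


def _common_frame_transforms(m1: Structure, m2: Structure, mono: list):
    """Interface transforms of the X and X* modes expressed in one
    common monomer frame (3CMW monomer 3).

    The X step is conjugated into that frame by superposing the 2REB
    monomer onto the 3CMW reference monomer.
    """
    t_xstar, _ = superpose(mono[1], mono[2], "CA")
    t_x_raw, _ = superpose(m1, m2, "CA")
    u, _ = superpose(m1, mono[2], "CA")  # 2REB frame -> reference frame
    t_x = u.compose(t_x_raw).compose(u.inverse())
    return t_x, t_xstar


def nter_fnat(cs_ref, cs_test, helix_range: tuple[int, int] = NTER_HELIX) -> float:
    """f_NAT restricted to contact pairs involving the N-terminal helix."""
    lo, hi = helix_range
    sub = frozenset(
        p for p in cs_ref.pairs
        if lo <= p[0][0] <= hi or lo <= p[1][0] <= hi
    )
    if not sub:
        raise ValueError("no reference contacts involve the N-terminal helix")
    return len(sub & cs_test.pairs) / len(sub)
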