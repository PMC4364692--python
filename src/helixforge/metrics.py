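"""Interface and morphology metrics.

Contacts are residue pairs with any heavy-atom distance below a cutoff
(5 A default).  f_NAT is the fraction of reference contact pairs
reproduced by a test geometry; f_IR the fraction of reference interface
residues (one monomer side) reproduced.  SASA uses sphere-point
(Shrake-Rupley) sampling; BSA is the accessible area lost on complex
formation, decomposed over named regions by truncate-and-subtract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Screw, kabsch
from .structures import RegionSpec, SelectionError, Structure, paired_coords

__all__ = [
    "ContactSet",
    "GrooveProfile",
    "contacts",
    "interface_residues",
    "fnat",
    "fir",
    "rmsd",
    "sasa",
    "total_sasa",
    "buried_surface",
    "groove_width",
    "VDW_RADII",
    "CONTACT_CUTOFF",
]

CONTACT_CUTOFF = 5.0  # A, heavy-atom residue contact criterion

#: van der Waals radii (A) for SASA; heavy atoms only
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "CA": 2.31, "MN": 1.97, "FE": 1.94,
    "K": 2.75, "NA": 2.27, "AL": 1.84,
}


@dataclass(frozen=True)
class ContactSet:
    """Residue-pair contacts between two monomers."""

    pairs: frozenset  # {(receptor residue key, ligand residue key)}
    cutoff: float = CONTACT_CUTOFF

    def __len__(self) -> int:
        return len(self.pairs)

    def receptor_residues(self) -> frozenset:
        return frozenset(p[0] for p in self.pairs)

    def ligand_residues(self) -> frozenset:
        return frozenset(p[1] for p in self.pairs)


def _residue_keys(s: Structure) -> list[tuple[int, str]]:
    """Per-atom residue keys by (res_id, ins_code); chain-agnostic so the
    same monomer in different chains compares equal."""
    return [(int(r), str(i)) for r, i in zip(s.res_ids, s.ins_codes)]


def contacts(a: Structure, b: Structure, cutoff: float = CONTACT_CUTOFF,
             brute_force: bool = False) -> ContactSet:
    """Residue pairs with any heavy-atom distance below ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keys_a, keys_b = _residue_keys(a), _residue_keys(b)
    pairs = set()
    if brute_force:
        d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
        for i, j in zip(*np.nonzero(d < cutoff)):
            pairs.add((keys_a[i], keys_b[j]))
    else:
        hits = cKDTree(a.coords).query_ball_tree(cKDTree(b.coords), cutoff)
        for i, js in enumerate(hits):
            for j in js:
                pairs.add((keys_a[i], keys_b[j]))
    return ContactSet(frozenset(pairs), cutoff)


def interface_residues(cs: ContactSet, side: str = "receptor") -> frozenset:
    if side == "receptor":
        return cs.receptor_residues()
    if side == "ligand":
        return cs.ligand_residues()
    raise ValueError("side must be 'receptor' or 'ligand'")


def fnat(reference: ContactSet, test: ContactSet) -> float:
    """Fraction of reference contact pairs present in the test set."""
    if len(reference) == 0:
        raise ValueError("empty reference contact set: f_NAT undefined")
    return len(reference.pairs & test.pairs) / len(reference.pairs)


def fir(reference: ContactSet, test: ContactSet, side: str = "receptor") -> float:
    """Fraction of reference interface residues (one side) present in the
    test interface."""
    ref = interface_residues(reference, side)
    if not ref:
        raise ValueError(f"empty reference {side} interface: f_IR undefined")
    return len(ref & interface_residues(test, side)) / len(ref)


# ---------------------------------------------------------------------------
# RMSD


def rmsd(a, b, selection: str = "CA", mode: str = "global",
         reference_interface: ContactSet | None = None) -> float:
    """RMSD between paired structures or dimers.

    ``mode='global'`` superposes and reports the residual RMSD.
    ``mode='ligand'`` expects (receptor, ligand) tuples for ``a`` and
    ``b``: receptors are superposed and the RMSD of the ligand monomers
    is reported without further fitting.
    ``mode='interface'`` is ``ligand`` restricted to residues of the
    reference interface (either side).
    """
    if mode == "global":
        ca, cb = paired_coords(a, b, selection)
        _, val = kabsch(ca, cb)
        return val
    if mode in ("ligand", "interface"):
        (rec_a, lig_a), (rec_b, lig_b) = a, b
        rca, rcb = paired_coords(rec_a, rec_b, selection)
        T, _ = kabsch(rca, rcb)
        lig_a = lig_a.transformed(T)
        if mode == "interface":
            if reference_interface is None:
                raise ValueError("interface mode needs a reference ContactSet")
            keep = {r[0] for r in reference_interface.ligand_residues()}
            lig_a = lig_a.select_residues(keep)
            lig_b = lig_b.select_residues(keep)
        # no refitting here, so even a single paired atom is meaningful
        ca, cb = paired_coords(lig_a, lig_b, selection, min_pairs=1)
        return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))
    raise ValueError(f"unknown rmsd mode {mode!r}")


# ---------------------------------------------------------------------------
# SASA


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley)."""
    radii = np.empty(len(s))
    for i, el in enumerate(s.elements):
        el = str(el).upper()
        if el not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii[i] = VDW_RADII[el]
    radii = radii + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(s.coords)
    max_r = radii.max()
    out = np.empty(len(s))
    for i in range(len(s)):
        shell = s.coords[i] + radii[i] * pts
        neigh = [j for j in tree.query_ball_point(s.coords[i], radii[i] + max_r)
                 if j != i]
        if neigh:
            d = np.linalg.norm(
                shell[:, None, :] - s.coords[neigh][None, :, :], axis=-1)
            exposed = np.all(d >= radii[neigh][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return out


def total_sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> float:
    return float(sasa(s, probe, n_points).sum())


def buried_surface(a: Structure, b: Structure,
                   regions: RegionSpec | None = None,
                   probe: float = 1.4, n_points: int = 960) -> dict:
    """Buried surface area per monomer, with optional region breakdown.

    BSA_X = ASA(X alone) - ASA(X in complex).  Region contributions come
    from repeating the calculation with the region truncated and
    subtracting, so the core contribution is total minus the sum of
    region terms (additive by construction).
    """
    from .assembly import concat_chains

    def bsa_pair(ma: Structure, mb: Structure) -> tuple[float, float]:
        complex_ = concat_chains([ma, mb])
        areas = sasa(complex_, probe, n_points)
        na = len(ma)
        asa_a = total_sasa(ma, probe, n_points)
        asa_b = total_sasa(mb, probe, n_points)
        return asa_a - float(areas[:na].sum()), asa_b - float(areas[na:].sum())

    total_a, total_b = bsa_pair(a, b)
    out = {"A": {"total": total_a}, "B": {"total": total_b}}
    if regions is None:
        return out
    rem_a, rem_b = total_a, total_b
    for name, spans in regions.ranges.items():
        drop = {r for lo, hi in spans for r in range(lo, hi + 1)}

        def cut(s: Structure) -> Structure:
            keep = np.array([int(r) not in drop for r in s.res_ids])
            return s.mask(keep) if keep.any() and not keep.all() else s

        ta, tb = cut(a), cut(b)
        if len(ta) == len(a) and len(tb) == len(b):
            contrib_a = contrib_b = 0.0  # region absent from both monomers
        else:
            cut_a, cut_b = bsa_pair(ta, tb)
            contrib_a, contrib_b = total_a - cut_a, total_b - cut_b
        out["A"][name] = contrib_a
        out["B"][name] = contrib_b
        rem_a -= contrib_a
        rem_b -= contrib_b
    out["A"]["core"] = rem_a
    out["B"]["core"] = rem_b
    return out


# ---------------------------------------------------------------------------
# groove width


@dataclass(frozen=True)
class GrooveProfile:
    angles_deg: np.ndarray
    width_mean: np.ndarray
    width_min: np.ndarray
    width_max: np.ndarray
    r_inner: float
    r_outer: float


def groove_width(filament: Structure, axis: Screw,
                 angle_step_deg: float = 0.5, shell_step: float = 1.0,
                 atom_radius: float = 1.7) -> GrooveProfile:
    """Groove width versus azimuthal angle for one helical turn.

    For every angular station (0.5 degree default) and radial shell
    (1 A steps between (r+R)/2 and R) the protein-free axial gap between
    successive surface crossings at mid-filament is measured; the
    per-angle width is aggregated over shells (mean, min and max all
    reported).
    """
    rel = filament.coords - axis.point
    zax = rel @ axis.axis
    perp = rel - np.outer(zax, axis.axis)
    rho = np.linalg.norm(perp, axis=1)
    r, R = float(rho.min()), float(rho.max())
    # azimuth needs a reference normal in the plane
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis.axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = ref - (ref @ axis.axis) * axis.axis
    u /= np.linalg.norm(u)
    v = np.cross(axis.axis, u)
    phi = np.degrees(np.arctan2(perp @ v, perp @ u)) % 360.0

    shells = np.arange((r + R) / 2.0, R + 1e-9, shell_step)
    angles = np.arange(0.0, 360.0, angle_step_deg)
    z_mid = float(np.median(zax))
    half_span = max(abs(axis.trans) * 4.0, 10.0)

    w_mean = np.zeros(len(angles))
    w_min = np.zeros(len(angles))
    w_max = np.zeros(len(angles))
    ang_tol = max(angle_step_deg, np.degrees(atom_radius / max(r, 1.0)))
    for ai, ang in enumerate(angles):
        dphi = np.abs((phi - ang + 180.0) % 360.0 - 180.0)
        sel_ang = dphi <= ang_tol
        widths = []
        for shell in shells:
            sel = sel_ang & (np.abs(rho - shell) <= shell_step)
            if not sel.any():
                continue
            z = np.sort(zax[sel])
            z = z[(z > z_mid - half_span) & (z < z_mid + half_span)]
            if len(z) < 2:
                continue
            gaps = np.diff(z) - 2 * atom_radius
            widths.append(max(float(gaps.max()), 0.0))
        if widths:
            w_mean[ai] = float(np.mean(widths))
            w_min[ai] = float(np.min(widths))
            w_max[ai] = float(np.max(widths))
    return GrooveProfile(angles, w_mean, w_min, w_max, r, R)
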