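"""Reduced-representation interaction energies between rigid bodies.

Functional form, per bead pair within the cutoff:

    E(r) = A_ij / r^8  -  B_ij / r^6  +  q_i q_j / (eps0 * r^2) * C

i.e. a smooth 8-6 van der Waals term plus a Coulomb term screened by a
distance-dependent dielectric  eps(r) = eps0 * r.  Energies are in RT at
300 K throughout.  A_ij and B_ij derive from per-bead-class radii and
well depths via Lorentz-Berthelot-style combination:

    r_min = R_i + R_j,   eps = sqrt(eps_i eps_j)
    B = 4 eps r_min^6,   A = 3 eps r_min^8

which places the single pair minimum exactly at r_min (r_min^2 = 4A/3B)
with depth -eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, Screw, helix_params
from .reduce import ReducedStructure

__all__ = [
    "ForceFieldParams",
    "Pose",
    "interaction_energy",
    "pair_energy_minimum",
    "per_residue_best_energy",
    "steric_screen",
    "DEFAULT_FF",
    "COULOMB_RT",
]

#: 332.0637 kcal mol^-1 A e^-2 expressed in RT at 300 K
COULOMB_RT = 332.0637 / 0.59616

#: per-bead-class (radius A, well depth RT); pair parameters combined
DEFAULT_BEAD_CLASSES = {
    "BB": (2.0, 0.30),
    "SCP": (2.0, 0.25),
    "SCD": (2.2, 0.35),
    "HET": (2.2, 0.25),
}


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of the reduced force field.

    ``bead_classes`` maps a bead class to (r_min_half, well depth);
    ``repulsive_pairs`` lists frozenset pairs for which the attractive
    r^-6 term is sign-flipped.
    """

    bead_classes: dict = field(default_factory=lambda: dict(DEFAULT_BEAD_CLASSES))
    eps0: float = 15.0
    cutoff: float = 16.0
    repulsive_pairs: frozenset = frozenset()
    r_floor: float = 0.1  # soft cap: distances clamped here, flagged
    clash_energy: float = 5.0  # RT; total E above this is a steric clash

    def pair_coefficients(self, class_a: str, class_b: str) -> tuple[float, float]:
        """(A, B) coefficients of the 8-6 term for a bead-class pair."""
        ra, ea = self.bead_classes[class_a]
        rb, eb = self.bead_classes[class_b]
        r_min = ra + rb
        eps = float(np.sqrt(ea * eb))
        B = 4.0 * eps * r_min**6
        A = 3.0 * eps * r_min**8
        if frozenset((class_a, class_b)) in self.repulsive_pairs:
            B = -B
        return A, B


DEFAULT_FF = ForceFieldParams()


def pair_energy_minimum(ff: ForceFieldParams, class_a: str, class_b: str):
    """Analytic (r_min, E_min) of the 8-6 term for one pair (no charge)."""
    A, B = ff.pair_coefficients(class_a, class_b)
    if B <= 0:
        return float("inf"), 0.0
    r2 = 4.0 * A / (3.0 * B)
    r = float(np.sqrt(r2))
    return r, float(A / r**8 - B / r**6)


@dataclass(frozen=True)
class Pose:
    """Rigid placement of a ligand relative to a fixed receptor."""

    transform: RigidTransform
    energy: float = float("nan")
    start_id: int = -1
    converged: bool = False
    capped: bool = False  # bead overlap hit the soft distance floor

    def with_energy(self, e: float, **kw) -> "Pose":
        return Pose(self.transform, e, kw.get("start_id", self.start_id),
                    kw.get("converged", self.converged), kw.get("capped", self.capped))


def _energy_arrays(coords_a, classes_a, q_a, coords_b, classes_b, q_b, ff, brute=False):
    """Core pairwise sum.  KD-tree pair list by default; ``brute`` forces
    the O(n^2) double loop (used as an independent oracle in tests)."""
    capped = False
    if brute:
        diff = coords_a[:, None, :] - coords_b[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        ii, jj = np.nonzero(r < ff.cutoff)
        rr = r[ii, jj]
    else:
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
        pairs = tree_a.query_ball_tree(tree_b, ff.cutoff)
        ii = np.array([i for i, js in enumerate(pairs) for _ in js], dtype=int)
        jj = np.array([j for js in pairs for j in js], dtype=int)
        if len(ii) == 0:
            return 0.0, False
        rr = np.linalg.norm(coords_a[ii] - coords_b[jj], axis=1)
    if len(ii) == 0:
        return 0.0, False
    if np.any(rr < ff.r_floor):
        rr = np.maximum(rr, ff.r_floor)
        capped = True
    coeff = {}
    A = np.empty(len(ii))
    B = np.empty(len(ii))
    for k, (i, j) in enumerate(zip(ii, jj)):
        key = (classes_a[i], classes_b[j])
        if key not in coeff:
            coeff[key] = ff.pair_coefficients(*key)
        A[k], B[k] = coeff[key]
    r2 = rr * rr
    r6 = r2 * r2 * r2
    e = A / (r6 * r2) - B / r6
    qq = q_a[ii] * q_b[jj]
    nz = qq != 0
    if np.any(nz):
        e[nz] += COULOMB_RT * qq[nz] / (ff.eps0 * r2[nz])
    return float(e.sum()), capped


def interaction_energy(
    receptor: ReducedStructure,
    ligand: ReducedStructure,
    pose: RigidTransform | Pose | None = None,
    ff: ForceFieldParams = DEFAULT_FF,
    brute_force: bool = False,
) -> float:
    """Interaction energy (RT) between receptor and posed ligand."""
    e, _ = interaction_energy_flagged(receptor, ligand, pose, ff, brute_force)
    return e


def interaction_energy_flagged(receptor, ligand, pose=None, ff=DEFAULT_FF,
                               brute_force=False):
    if receptor.scheme != ligand.scheme:
        raise ValueError("receptor and ligand use different bead schemes")
    T = pose.transform if isinstance(pose, Pose) else pose
    lig_coords = ligand.coords if T is None else T.apply(ligand.coords)
    return _energy_arrays(
        receptor.coords, receptor.type_ids, receptor.charges,
        lig_coords, ligand.type_ids, ligand.charges, ff, brute=brute_force,
    )


def energy_and_ligand_gradient(receptor: ReducedStructure,
                               lig_coords: np.ndarray,
                               ligand: ReducedStructure,
                               ff: ForceFieldParams = DEFAULT_FF):
    """Energy plus the analytic gradient with respect to each ligand bead
    position (used by the rigid-body minimizer)."""
    coords_a = receptor.coords
    q_a, q_b = receptor.charges, ligand.charges
    pairs = cKDTree(coords_a).query_ball_tree(cKDTree(lig_coords), ff.cutoff)
    grad = np.zeros_like(lig_coords)
    ii = np.array([i for i, js in enumerate(pairs) for _ in js], dtype=int)
    jj = np.array([j for js in pairs for j in js], dtype=int)
    if len(ii) == 0:
        return 0.0, grad
    d = lig_coords[jj] - coords_a[ii]
    r = np.linalg.norm(d, axis=1)
    flat = r < ff.r_floor  # flat region of the soft cap: no force
    r = np.maximum(r, ff.r_floor)
    coeff: dict = {}
    A = np.empty(len(ii))
    B = np.empty(len(ii))
    classes_a, classes_b = receptor.type_ids, ligand.type_ids
    for k, (i, j) in enumerate(zip(ii, jj)):
        key = (classes_a[i], classes_b[j])
        if key not in coeff:
            coeff[key] = ff.pair_coefficients(*key)
        A[k], B[k] = coeff[key]
    r2 = r * r
    r6 = r2 * r2 * r2
    e = A / (r6 * r2) - B / r6
    dEdr = -8.0 * A / (r6 * r2 * r) + 6.0 * B / (r6 * r)
    qq = q_a[ii] * q_b[jj]
    nz = qq != 0
    if np.any(nz):
        e[nz] += COULOMB_RT * qq[nz] / (ff.eps0 * r2[nz])
        dEdr[nz] += -2.0 * COULOMB_RT * qq[nz] / (ff.eps0 * r2[nz] * r[nz])
    dEdr[flat] = 0.0
    np.add.at(grad, jj, (dEdr / r)[:, None] * d)
    return float(e.sum()), grad


# ---------------------------------------------------------------------------
# per-residue best-energy map


NOT_CONTACTED = float("nan")


def per_residue_best_energy(poses, receptor: ReducedStructure,
                            ligand: ReducedStructure, contact_cutoff: float = 5.0):
    """Best (most favorable) interface energy per residue over many poses.

    For each pose the interface residues (receptor and ligand side) are
    found from bead contacts; each such residue is annotated with the
    minimum energy over all poses whose interface contains it.  Returns
    ``(best, normalized)`` where ``normalized`` rescales to 0-100 % of
    the best interaction value found (best residue = 100).  Residues in
    no interface are absent from the maps.
    """
    best: dict[tuple, float] = {}
    rec_tree = cKDTree(receptor.coords)
    for pose in poses:
        lig_coords = pose.transform.apply(ligand.coords)
        pairs = rec_tree.query_ball_point(lig_coords, contact_cutoff)
        rec_res = {receptor.residues[i] for js in pairs for i in js}
        lig_res = {ligand.residues[j] for j, js in enumerate(pairs) if js}
        for res in rec_res | {("LIG",) + r for r in lig_res}:
            if res not in best or pose.energy < best[res]:
                best[res] = pose.energy
    if not best:
        return {}, {}
    e_best = min(best.values())
    if e_best >= 0:
        normalized = {r: 0.0 for r in best}
    else:
        normalized = {r: 100.0 * max(e, e_best) / e_best if e < 0 else 0.0
                      for r, e in best.items()}
    return best, normalized


# ---------------------------------------------------------------------------
# steric screen for helical assemblies


def steric_screen(monomer: ReducedStructure, s: Screw,
                  ff: ForceFieldParams = DEFAULT_FF) -> dict:
    """Cross-turn steric screen of the regular assembly implied by ``s``.

    The energy is computed between monomer i and the two closest
    monomers of the next helical turn, i+M and i+M+1, with M = floor(N).
    A clash is flagged when either energy exceeds ``ff.clash_energy``.
    Pure translations (N infinite) trivially have no cross-turn contact.
    """
    hp = helix_params(s)
    if not np.isfinite(hp.n_per_turn):
        return {"M": None, "energies": {}, "clash": False}
    M = int(np.floor(hp.n_per_turn))
    T = s.to_transform()
    energies = {}
    clash = False
    for k in (M, M + 1):
        mate = monomer.transformed(T.power(k))
        e, capped = interaction_energy_flagged(monomer, mate, None, ff)
        energies[k] = e
        if e > ff.clash_energy or capped:
            clash = True
    return {"M": M, "energies": energies, "clash": clash}
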