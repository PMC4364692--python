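"""Multi-start rigid-body self-docking.

Global mode scatters ligand copies on a quasi-spherical shell at a
constant surface-to-surface distance from the receptor (about 10 A
between neighboring start positions); targeted mode uses a dense 2 A
grid within 20 A of a reference ligand placement.  Each start is locally
energy-minimized over the six rigid-body degrees of freedom; results are
energy-sorted, filtered and deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .energetics import (
    DEFAULT_FF,
    ForceFieldParams,
    Pose,
    interaction_energy,
    interaction_energy_flagged,
)
from .geometry import RigidTransform, Screw, screw_from_transform, helix_params
from .reduce import ReducedStructure

__all__ = [
    "StartGrid",
    "DockResult",
    "generate_starts",
    "sphere_point_count",
    "minimize_pose",
    "dock",
    "filter_poses",
    "FilterCriteria",
]

ENERGY_WINDOW_RT = 20.0  # retain poses up to this much above the reference
GLOBAL_SPACING = 10.0  # A between neighboring global start positions
TARGETED_SPACING = 2.0  # A grid pitch for targeted starts
TARGETED_RADIUS = 20.0  # A max distance from the reference ligand center
DEDUP_RMSD = 1.0  # A ligand-RMSD below which poses are duplicates


@dataclass(frozen=True)
class StartGrid:
    """Deterministic set of rigid-body starting placements."""

    transforms: tuple  # of RigidTransform
    mode: str  # 'global' | 'targeted'
    spacing: float

    def __len__(self) -> int:
        return len(self.transforms)


def sphere_point_count(radius: float, spacing: float) -> int:
    """Number of quasi-uniform points covering a sphere at the given
    neighbor spacing (area / spacing^2)."""
    return max(int(round(4.0 * np.pi * radius**2 / spacing**2)), 12)


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def _orientation_set(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Quasi-uniform rotations: deterministic low-discrepancy sample."""
    qs = Rotation.random(n, random_state=np.random.RandomState(rng.integers(2**31)))
    return [q.as_matrix() for q in qs]


def generate_starts(
    receptor: ReducedStructure,
    ligand: ReducedStructure,
    mode: str = "global",
    surface_distance: float = 5.0,
    spacing: float | None = None,
    orientations: int = 6,
    reference: RigidTransform | None = None,
    seed: int = 0,
) -> StartGrid:
    """Build the start grid for a docking run (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    rec_coords = receptor.coords
    rec_center = rec_coords.mean(axis=0)
    lig_center = ligand.coords.mean(axis=0)
    lig_radius = float(np.linalg.norm(ligand.coords - lig_center, axis=1).max())

    positions: list[np.ndarray] = []
    if mode == "global":
        spacing = GLOBAL_SPACING if spacing is None else spacing
        rec_radius = float(np.linalg.norm(rec_coords - rec_center, axis=1).max())
        shell = rec_radius + surface_distance + lig_radius
        n_pos = sphere_point_count(shell, spacing)
        dirs = _fibonacci_directions(n_pos)
        for d in dirs:
            # push out to constant surface-to-surface distance along d
            proj = (rec_coords - rec_center) @ d
            r = proj.max() + surface_distance + lig_radius
            positions.append(rec_center + r * d)
    elif mode == "targeted":
        if reference is None:
            raise ValueError("targeted mode needs a reference transform")
        spacing = TARGETED_SPACING if spacing is None else spacing
        ref_center = reference.apply(ligand.coords).mean(axis=0)
        ticks = np.arange(-TARGETED_RADIUS, TARGETED_RADIUS + 1e-9, spacing)
        for dx in ticks:
            for dy in ticks:
                for dz in ticks:
                    off = np.array([dx, dy, dz])
                    if np.linalg.norm(off) <= TARGETED_RADIUS:
                        positions.append(ref_center + off)
    else:
        raise ValueError(f"unknown start mode {mode!r}")

    transforms = []
    if mode == "targeted":
        # keep the reference orientation, with small deterministic tilts
        base = reference.rotation
        tilts = [np.eye(3)] + [
            Rotation.from_rotvec(np.radians(8.0) * ax).as_matrix()
            for ax in np.eye(3)
        ][: max(orientations - 1, 0)]
        for pos in positions:
            for tilt in tilts:
                R = tilt @ base
                transforms.append(RigidTransform(R, pos - R @ lig_center))
    else:
        rots = _orientation_set(orientations, rng)
        for pos in positions:
            for R in rots:
                transforms.append(RigidTransform(R, pos - R @ lig_center))
    return StartGrid(tuple(transforms), mode, float(spacing))


# ---------------------------------------------------------------------------
# minimization


def _transform_from_x(x: np.ndarray, base: RigidTransform) -> RigidTransform:
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(R @ base.rotation, R @ base.translation + x[3:])


def _so3_left_jacobian(w: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3): maps rotation-vector increments to spatial
    angular increments, d(R(w) p) = (J_l(w) dw) x (R(w) p)."""
    theta = np.linalg.norm(w)
    W = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    if theta < 1e-8:
        return np.eye(3) + 0.5 * W
    return (np.eye(3)
            + (1 - np.cos(theta)) / theta**2 * W
            + (theta - np.sin(theta)) / theta**3 * (W @ W))


def minimize_pose(
    receptor: ReducedStructure,
    ligand: ReducedStructure,
    start: RigidTransform,
    ff: ForceFieldParams = DEFAULT_FF,
    start_id: int = -1,
    max_iter: int = 200,
) -> Pose:
    """Local energy minimization over the 6 rigid-body degrees of freedom.

    Gradient-based descent (L-BFGS-B with numerical gradients) from the
    start placement; the returned energy never exceeds the start energy.
    """
    from .energetics import energy_and_ligand_gradient

    e_start, capped0 = interaction_energy_flagged(receptor, ligand, start, ff)
    base_coords = start.apply(ligand.coords)

    def fun(x):
        w, t = x[:3], x[3:]
        R = Rotation.from_rotvec(w).as_matrix()
        lig = base_coords @ R.T + t
        e, g = energy_and_ligand_gradient(receptor, lig, ligand, ff)
        grad_t = g.sum(axis=0)
        torque = np.cross(lig - t, g).sum(axis=0)
        grad_w = _so3_left_jacobian(w).T @ torque
        return e, np.concatenate([grad_w, grad_t])

    res = minimize(
        fun, np.zeros(6), method="L-BFGS-B", jac=True,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    e_final = float(res.fun)
    if e_final > e_start:  # descent guarantee
        return Pose(start, e_start, start_id, converged=False, capped=capped0)
    T = _transform_from_x(res.x, start)
    _, capped = interaction_energy_flagged(receptor, ligand, T, ff)
    return Pose(T, e_final, start_id, converged=bool(res.success), capped=capped)


# ---------------------------------------------------------------------------
# docking driver


@dataclass(frozen=True)
class DockResult:
    """Energy-sorted minimized poses plus per-pose screw analysis."""

    poses: tuple  # of Pose, ascending energy (ties by start id)
    screws: tuple  # of Screw, parallel to poses
    seed: int = 0
    n_starts: int = 0

    def __len__(self) -> int:
        return len(self.poses)

    def sorted_copy(self) -> "DockResult":
        order = sorted(range(len(self.poses)),
                       key=lambda i: (self.poses[i].energy, self.poses[i].start_id))
        return replace(self,
                       poses=tuple(self.poses[i] for i in order),
                       screws=tuple(self.screws[i] for i in order))


def dock(
    receptor: ReducedStructure,
    ligand: ReducedStructure,
    grid: StartGrid,
    ff: ForceFieldParams = DEFAULT_FF,
    seed: int = 0,
) -> DockResult:
    """Minimize every start of the grid; deterministic given the grid."""
    poses = []
    for i, T in enumerate(grid.transforms):
        poses.append(minimize_pose(receptor, ligand, T, ff, start_id=i))
    screws = tuple(screw_from_transform(p.transform) for p in poses)
    return DockResult(tuple(poses), screws, seed, len(grid)).sorted_copy()


def merge_results(*results: DockResult) -> DockResult:
    poses: list = []
    screws: list = []
    offset = 0
    for r in results:
        for p, s in zip(r.poses, r.screws):
            poses.append(replace(p, start_id=p.start_id + offset))
            screws.append(s)
        offset += max((p.start_id for p in r.poses), default=0) + 1
    return DockResult(tuple(poses), tuple(screws),
                      results[0].seed if results else 0,
                      sum(r.n_starts for r in results)).sorted_copy()


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterCriteria:
    """Pose retention rules.

    ``reference_energy`` defaults to the best energy in the run; poses
    above ``reference_energy + energy_window`` are dropped.  Poses whose
    interface with the preceding or following monomer of the implied
    filament touches a boundary residue are dropped.  Remaining poses
    are deduplicated by ligand-RMSD clustering.
    """

    energy_window: float = ENERGY_WINDOW_RT
    reference_energy: float | None = None
    boundary_residues: tuple = ()
    dedup_rmsd: float = DEDUP_RMSD


def _ligand_rmsd(ligand: ReducedStructure, ta: RigidTransform,
                 tb: RigidTransform) -> float:
    ca, cb = ta.apply(ligand.coords), tb.apply(ligand.coords)
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def _interface_touches(receptor: ReducedStructure, ligand: ReducedStructure,
                       T: RigidTransform, residues: set, cutoff: float = 5.0) -> bool:
    from scipy.spatial import cKDTree

    lig = T.apply(ligand.coords)
    hits = cKDTree(receptor.coords).query_ball_point(lig, cutoff)
    for j, js in enumerate(hits):
        if not js:
            continue
        if ligand.residues[j][1] in residues:
            return True
        for i in js:
            if receptor.residues[i][1] in residues:
                return True
    return False


def filter_poses(result: DockResult, criteria: FilterCriteria,
                 receptor: ReducedStructure | None = None,
                 ligand: ReducedStructure | None = None) -> DockResult:
    """Energy window + boundary-residue filter + RMSD deduplication.

    Never increases the pose count and is idempotent.
    """
    if not result.poses:
        return result
    e_ref = (criteria.reference_energy if criteria.reference_energy is not None
             else min(p.energy for p in result.poses))
    keep = [i for i, p in enumerate(result.poses)
            if p.energy <= e_ref + criteria.energy_window]

    if criteria.boundary_residues and receptor is not None and ligand is not None:
        boundary = set(int(r) for r in criteria.boundary_residues)
        kept = []
        for i in keep:
            T = result.poses[i].transform
            # interfaces with the following (T) and preceding (T^-1) monomer
            if _interface_touches(receptor, ligand, T, boundary):
                continue
            if _interface_touches(receptor, ligand, T.inverse(), boundary):
                continue
            kept.append(i)
        keep = kept

    if ligand is not None:
        unique: list[int] = []
        for i in keep:
            dup = any(
                _ligand_rmsd(ligand, result.poses[i].transform,
                             result.poses[j].transform) < criteria.dedup_rmsd
                for j in unique)
            if not dup:
                unique.append(i)
        keep = unique

    return replace(result,
                   poses=tuple(result.poses[i] for i in keep),
                   screws=tuple(result.screws[i] for i in keep))
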