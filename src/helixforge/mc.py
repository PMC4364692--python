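"""Constrained Metropolis Monte Carlo exploration of a binding-mode family.

The ligand monomer moves rigidly relative to the fixed receptor; moves
are uniform within +/-5 degrees (rotations) and +/-3 A (translations).
The walk is confined to poses sharing more than half of the reference
contact pairs (f_NAT > 0.5); proposals violating the constraint are
rejected outright and counted as rejections.  Helix descriptors, RMSD
and interface fractions are recorded at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .energetics import DEFAULT_FF, ForceFieldParams, Pose, interaction_energy
from .geometry import RigidTransform, helix_params, screw_from_transform
from .reduce import ReducedStructure

__all__ = ["McConfig", "TrajectoryRecord", "explore", "select_mc_starts",
           "bead_contacts", "ConstraintError"]

FNAT_CONSTRAINT = 0.5


class ConstraintError(ValueError):
    """The starting pose violates the f_NAT constraint."""


def metropolis_accept(delta_e: float, rng: np.random.Generator,
                      kt: float) -> bool:
    """Metropolis criterion: accept downhill moves always, uphill moves
    with probability exp(-dE/kT).  ``kt <= 0`` is the quench limit."""
    if delta_e <= 0:
        return True
    if kt <= 0:
        return False
    return bool(rng.random() < np.exp(-delta_e / kt))


@dataclass(frozen=True)
class McConfig:
    steps: int = 100_000
    temperature_rt: float = 1.0  # kT in RT units (1.0 = 300 K)
    rot_step_deg: float = 5.0
    trans_step: float = 3.0
    fnat_min: float = FNAT_CONSTRAINT
    contact_cutoff: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.rot_step_deg <= 0 or self.trans_step <= 0:
            raise ValueError("proposal widths must be positive")


@dataclass(frozen=True)
class TrajectoryRecord:
    step: int
    energy: float
    n_per_turn: float
    pitch: float
    handedness: str
    rmsd_ca: float
    fnat: float
    fir: float
    accepted: bool


def bead_contacts(receptor: ReducedStructure, ligand: ReducedStructure,
                  T: RigidTransform | None, cutoff: float = 5.0) -> frozenset:
    """Residue-pair contacts evaluated on beads (cheap f_NAT proxy used
    inside sampling loops; same residue-pair semantics as the atomic
    contact criterion)."""
    lig = ligand.coords if T is None else T.apply(ligand.coords)
    hits = cKDTree(receptor.coords).query_ball_point(lig, cutoff)
    pairs = set()
    for j, js in enumerate(hits):
        for i in js:
            pairs.add((receptor.residues[i][1:], ligand.residues[j][1:]))
    return frozenset(pairs)


def _fnat(ref: frozenset, test: frozenset) -> float:
    return len(ref & test) / len(ref)


def _fir(ref: frozenset, test: frozenset) -> float:
    ref_r = frozenset(p[0] for p in ref)
    test_r = frozenset(p[0] for p in test)
    return len(ref_r & test_r) / len(ref_r) if ref_r else 0.0


def explore(
    receptor: ReducedStructure,
    ligand: ReducedStructure,
    start: Pose,
    ref_contacts: frozenset | None = None,
    cfg: McConfig = McConfig(),
    ff: ForceFieldParams = DEFAULT_FF,
) -> list[TrajectoryRecord]:
    """Metropolis walk around a binding mode, f_NAT-constrained.

    ``ref_contacts`` defaults to the contacts of the start pose.  Raises
    :class:`ConstraintError` when the start itself fails the constraint.
    """
    rng = np.random.default_rng(cfg.seed)
    if ref_contacts is None:
        ref_contacts = bead_contacts(receptor, ligand, start.transform,
                                     cfg.contact_cutoff)
    if not ref_contacts:
        raise ConstraintError("reference contact set is empty")

    ref_lig = start.transform.apply(ligand.coords)

    def describe(T: RigidTransform, energy: float, step: int,
                 accepted: bool, test_contacts: frozenset) -> TrajectoryRecord:
        s = screw_from_transform(T)
        hp = helix_params(s, ligand)
        lig = T.apply(ligand.coords)
        rmsd = float(np.sqrt(np.mean(np.sum((lig - ref_lig) ** 2, axis=1))))
        return TrajectoryRecord(
            step, energy, hp.n_per_turn, hp.pitch, hp.handedness, rmsd,
            _fnat(ref_contacts, test_contacts), _fir(ref_contacts, test_contacts),
            accepted,
        )

    cur = start.transform
    cur_contacts = bead_contacts(receptor, ligand, cur, cfg.contact_cutoff)
    if _fnat(ref_contacts, cur_contacts) <= cfg.fnat_min:
        raise ConstraintError(
            f"start pose has f_NAT {_fnat(ref_contacts, cur_contacts):.2f} "
            f"<= {cfg.fnat_min}")
    cur_e = interaction_energy(receptor, ligand, cur, ff)

    records = [describe(cur, cur_e, 0, True, cur_contacts)]
    n_accept = 0
    for step in range(1, cfg.steps + 1):
        rotvec = np.radians(rng.uniform(-cfg.rot_step_deg, cfg.rot_step_deg, 3))
        dt = rng.uniform(-cfg.trans_step, cfg.trans_step, 3)
        dR = Rotation.from_rotvec(rotvec).as_matrix()
        # rotate about the current ligand center, then translate
        center = cur.apply(ligand.coords).mean(axis=0)
        cand = RigidTransform(
            dR @ cur.rotation,
            dR @ (cur.translation - center) + center + dt,
        )
        cand_contacts = bead_contacts(receptor, ligand, cand, cfg.contact_cutoff)
        if _fnat(ref_contacts, cand_contacts) <= cfg.fnat_min:
            records.append(describe(cur, cur_e, step, False, cur_contacts))
            continue
        cand_e = interaction_energy(receptor, ligand, cand, ff)
        if metropolis_accept(cand_e - cur_e, rng, cfg.temperature_rt):
            cur, cur_e, cur_contacts = cand, cand_e, cand_contacts
            n_accept += 1
            records.append(describe(cur, cur_e, step, True, cur_contacts))
        else:
            records.append(describe(cur, cur_e, step, False, cur_contacts))
    return records


def acceptance_rate(records: list[TrajectoryRecord]) -> float:
    moves = [r for r in records if r.step > 0]
    return sum(r.accepted for r in moves) / len(moves) if moves else 0.0


@dataclass(frozen=True)
class StartSelection:
    fnat_min: float = 0.5
    irmsd_max: float = 3.5
    energy_window: float = 5.0  # above the reference mode energy


def select_mc_starts(poses, metrics: list[dict],
                     reference_energy: float,
                     thresholds: StartSelection = StartSelection()) -> list:
    """Select docking poses suitable as MC starting geometries.

    ``metrics`` carries one dict per pose with keys ``fnat`` and
    ``irmsd`` (vs the reference mode).  Retains poses with
    f_NAT > threshold, interface RMSD below the cap, and energy within
    the window above the reference mode energy.
    """
    out = []
    for pose, m in zip(poses, metrics):
        if m["fnat"] <= thresholds.fnat_min:
            continue
        if m["irmsd"] >= thresholds.irmsd_max:
            continue
        if pose.energy >= reference_energy + thresholds.energy_window:
            continue
        out.append(pose)
    return out
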