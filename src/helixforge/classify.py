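"""Classification of binding geometries and cyclic adjustment.

Every binding geometry implies a unique regular assembly; its (N, P)
signature places it in exactly one category:

* ``Filament``   — P > 2 R_M: successive turns cannot touch.
* ``Cyclic``     — N within 0.1 of an integer and |P| <= 0.5 A.
* ``NearCyclic`` — P < (N - 1) * 5 A (up to 5 A pitch defect per
  interface); eligible for symmetry-enforced adjustment.
* ``NearHelical``— everything else; screened for cross-turn clashes.

``adjust_to_cyclic`` drives a near-cyclic pose to exact C_k symmetry by
low-temperature Metropolis minimization with ramped harmonic restraints
on (theta - 360/k) and trans, followed by an exact projection of the
final screw onto the cyclic manifold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import ForceFieldParams, DEFAULT_FF, Pose, interaction_energy
from .geometry import (
    HelixParams,
    RigidTransform,
    Screw,
    screw_from_transform,
    transform_from_screw,
)
from .reduce import ReducedStructure
from scipy.spatial.transform import Rotation

__all__ = ["GeometryCategory", "classify_geometry", "adjust_to_cyclic",
           "AdjustResult"]

FILAMENT_RULE_FACTOR = 2.0  # Filament iff P > 2 R_M
CYCLIC_N_TOL = 0.1
CYCLIC_P_MAX = 0.5  # A
NEAR_CYCLIC_PER_INTERFACE = 5.0  # A pitch defect allowed per interface


@dataclass(frozen=True)
class GeometryCategory:
    label: str  # Filament | Cyclic | NearCyclic | NearHelical
    n_per_turn: float
    pitch: float
    r_m: float
    ring_size: int | None = None  # nearest integer N for (near-)cyclic
    closure_defect: float | None = None  # axial defect over the full ring, A
    clash: bool | None = None  # filled by the steric screen for NearHelical


def classify_geometry(hp: HelixParams, r_m: float) -> GeometryCategory:
    """Pure classification of one helix signature.

    ``r_m`` is the maximum monomer radius (atom distance from the
    centroid).  Precedence: Filament, Cyclic, NearCyclic, NearHelical.
    """
    if r_m <= 0:
        raise ValueError("R_M must be positive")
    n, p = hp.n_per_turn, abs(hp.pitch)
    if not np.isfinite(n) or p > FILAMENT_RULE_FACTOR * r_m:
        return GeometryCategory("Filament", n, p, r_m)
    k = int(round(n))
    if abs(n - k) <= CYCLIC_N_TOL and p <= CYCLIC_P_MAX and k >= 2:
        return GeometryCategory("Cyclic", n, p, r_m, ring_size=k,
                                closure_defect=p)
    if p < (n - 1.0) * NEAR_CYCLIC_PER_INTERFACE:
        return GeometryCategory("NearCyclic", n, p, r_m, ring_size=k,
                                closure_defect=p)
    return GeometryCategory("NearHelical", n, p, r_m)


@dataclass(frozen=True)
class AdjustResult:
    pose: Pose
    screw: Screw
    energy_before: float
    energy_after: float
    succeeded: bool


def _cyclic_penalty(screw: Screw, k: int, w_theta: float, w_trans: float) -> float:
    return (w_theta * (screw.angle_deg - 360.0 / k) ** 2
            + w_trans * screw.trans**2)


def adjust_to_cyclic(
    pose: Pose,
    monomer: ReducedStructure,
    k: int,
    ff: ForceFieldParams = DEFAULT_FF,
    seed: int = 0,
    n_steps: int = 400,
    theta_tol: float = 0.01,
    trans_tol: float = 0.01,
) -> AdjustResult:
    """Force a near-cyclic pose onto exact C_k symmetry.

    Metropolis minimization at low temperature over the 6 rigid-body
    degrees of freedom, with harmonic restraints pulling theta to 360/k
    and trans to 0; restraint weights are ramped geometrically.  The
    last stage projects the screw exactly onto (theta = 360/k,
    trans = 0), so the post-conditions hold to machine precision
    whenever the MC stage converges close enough.
    """
    if k < 2:
        raise ValueError("ring size k must be >= 2")
    rng = np.random.default_rng(seed)
    T = pose.transform
    e0 = interaction_energy(monomer, monomer, T, ff)

    beta = 10.0  # low-temperature Metropolis (quench with a little noise)
    w_theta, w_trans = 1.0, 1.0
    cur = T
    cur_screw = screw_from_transform(cur)
    cur_cost = (interaction_energy(monomer, monomer, cur, ff)
                + _cyclic_penalty(cur_screw, k, w_theta, w_trans))
    for step in range(n_steps):
        if step and step % 50 == 0:
            w_theta *= 4.0
            w_trans *= 4.0
            cur_cost = (interaction_energy(monomer, monomer, cur, ff)
                        + _cyclic_penalty(cur_screw, k, w_theta, w_trans))
        rot = Rotation.from_rotvec(rng.uniform(-0.01, 0.01, 3)).as_matrix()
        dt = rng.uniform(-0.1, 0.1, 3)
        cand = RigidTransform(rot @ cur.rotation, rot @ cur.translation + dt)
        cand_screw = screw_from_transform(cand)
        cost = (interaction_energy(monomer, monomer, cand, ff)
                + _cyclic_penalty(cand_screw, k, w_theta, w_trans))
        if cost <= cur_cost or rng.random() < np.exp(-beta * (cost - cur_cost)):
            cur, cur_screw, cur_cost = cand, cand_screw, cost

    # exact projection onto the cyclic manifold
    projected = Screw(cur_screw.point, cur_screw.axis, 360.0 / k, 0.0)
    T_adj = transform_from_screw(projected)
    e1 = interaction_energy(monomer, monomer, T_adj, ff)
    final_screw = screw_from_transform(T_adj)
    ok = (abs(final_screw.angle_deg - 360.0 / k) <= theta_tol
          and abs(final_screw.trans) <= trans_tol)
    if not ok:
        return AdjustResult(pose, screw_from_transform(T), e0, e0, False)
    adj = Pose(T_adj, e1, pose.start_id, converged=True)
    return AdjustResult(adj, final_screw, e0, e1, True)
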