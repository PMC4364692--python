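"""Rigid transforms, screw decomposition and helical parameters.

A screw motion is a rotation by ``theta`` about an axis (point ``O``,
unit direction ``omega``) combined with a translation ``trans`` along
that axis.  Repeating the motion generates a helix; ``trans = 0`` gives
a ring and ``theta = 0`` a straight filament.  The global descriptors of
the implied regular assembly are

    N   = 360 / theta          (monomers per turn, theta in degrees)
    P   = N * |trans|          (pitch, A)
    dir = 'R' if theta * trans > 0 else 'L'

Convention used throughout: theta is kept in (0, 180] degrees and the
handedness is carried by the sign of ``trans`` relative to ``omega``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "Screw",
    "HelixParams",
    "kabsch",
    "superpose",
    "screw_from_transform",
    "transform_from_screw",
    "screw_between_monomers",
    "helix_params",
    "angular_deviation",
    "PURE_TRANSLATION_THETA_DEG",
]

#: below this rotation angle (degrees) a transform is treated as a pure
#: translation (N is infinite, the geometry is a straight filament)
PURE_TRANSLATION_THETA_DEG = 0.1


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def power(self, k: int) -> "RigidTransform":
        out = RigidTransform(np.eye(3), np.zeros(3))
        base = self if k >= 0 else self.inverse()
        for _ in range(abs(k)):
            out = base.compose(out)
        return out

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class Screw:
    """Screw-axis representation of a rigid motion.

    Attributes
    ----------
    point : ndarray
        A point O on the axis (the perpendicular foot from the origin,
        so the representation is unique and deterministic).
    axis : ndarray
        Unit direction of the axis.
    angle_deg : float
        Rotation angle in degrees, in (0, 180]; 0.0 for the
        pure-translation sentinel.
    trans : float
        Signed translation along ``axis`` in Angstrom.
    pure_translation : bool
        Set when the rotation part is (numerically) the identity.
    """

    point: np.ndarray
    axis: np.ndarray
    angle_deg: float
    trans: float
    pure_translation: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("screw axis must be a nonzero vector")
        object.__setattr__(self, "axis", a / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))

    def to_transform(self) -> RigidTransform:
        return transform_from_screw(self)


@dataclass(frozen=True)
class HelixParams:
    """Global parameters of the regular assembly implied by one screw step."""

    n_per_turn: float  # monomers per turn, inf for a straight filament
    pitch: float  # axial rise per turn, A (absolute value)
    handedness: str  # 'R', 'L' or '-' when undefined (ring / straight)
    r_int: float = field(default=float("nan"))
    r_ext: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of paired point sets.

    Returns the rigid transform mapping ``mobile`` onto ``target``
    (minimizing the RMSD) and the residual RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("superposition requires at least 3 paired points")
    cm, ct = mob.mean(axis=0), tgt.mean(axis=0)
    H = (mob - cm).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cm
    T = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((T.apply(mob) - tgt) ** 2, axis=1))))
    return T, rmsd


def superpose(mobile, target, selection: str = "CA"):
    """Superpose two structures over a paired atom selection.

    Accepts either raw coordinate arrays or ``Structure`` objects (the
    pairing is then done by (chain, residue, atom name); see
    :func:`helixforge.structures.paired_coords`).
    """
    if isinstance(mobile, np.ndarray) and isinstance(target, np.ndarray):
        return kabsch(mobile, target)
    from .structures import paired_coords

    mc, tc = paired_coords(mobile, target, selection)
    return kabsch(mc, tc)


# ---------------------------------------------------------------------------
# screw decomposition


def screw_from_transform(T: RigidTransform) -> Screw:
    """Decompose a rigid transform into its screw parameters.

    The angle is reported in (0, 180] with the axis oriented so that the
    rotation about it is positive; the translation along the axis keeps
    its sign.  Rotations below ``PURE_TRANSLATION_THETA_DEG`` are
    returned as a flagged pure translation.
    """
    rot = Rotation.from_matrix(T.rotation)
    rotvec = rot.as_rotvec()
    theta = np.linalg.norm(rotvec)
    theta_deg = float(np.degrees(theta))

    if theta_deg < PURE_TRANSLATION_THETA_DEG:
        t = T.translation
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            return Screw(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0, 0.0, True)
        return Screw(np.zeros(3), t / norm, 0.0, float(norm), True)

    axis = rotvec / theta
    trans = float(T.translation @ axis)
    t_perp = T.translation - trans * axis
    # axis point solves (I - R) O = t_perp; (I - R) is singular along the
    # axis, so use least squares and take the perpendicular foot from the
    # origin for a unique representative.
    O, *_ = np.linalg.lstsq(np.eye(3) - T.rotation, t_perp, rcond=None)
    O = O - (O @ axis) * axis
    return Screw(O, axis, theta_deg, trans, False)


def transform_from_screw(s: Screw) -> RigidTransform:
    """Exact inverse of :func:`screw_from_transform`."""
    if s.pure_translation or s.angle_deg == 0.0:
        return RigidTransform(np.eye(3), s.trans * s.axis)
    R = Rotation.from_rotvec(np.radians(s.angle_deg) * s.axis).as_matrix()
    t = s.point - R @ s.point + s.trans * s.axis
    return RigidTransform(R, t)


def screw_between_monomers(a, b, selection: str = "CA", rmsd_warn: float = 3.0) -> Screw:
    """Screw transform mapping monomer ``a`` onto its copy ``b``.

    Emits a warning when the superposition residual exceeds
    ``rmsd_warn`` A (the two structures are then probably not copies of
    the same monomer).
    """
    T, rmsd = superpose(a, b, selection)
    if rmsd > rmsd_warn:
        import warnings

        warnings.warn(
            f"superposition rmsd {rmsd:.2f} A > {rmsd_warn} A: "
            "inputs may not be copies of the same monomer",
            stacklevel=2,
        )
    return screw_from_transform(T)


def helix_params(s: Screw, monomer=None) -> HelixParams:
    """Global helix descriptors for one screw step.

    When ``monomer`` (a Structure, ReducedStructure or coordinate array)
    is given, the inner and outer radii of the implied fiber are the
    min/max distances of its atoms from the axis line.
    """
    if s.pure_translation or s.angle_deg < PURE_TRANSLATION_THETA_DEG:
        n = float("inf")
        pitch = float("inf")
        direction = "-"
    else:
        n = 360.0 / s.angle_deg
        pitch = n * abs(s.trans)
        if abs(s.trans) < 1e-9:
            direction = "-"  # ring: no handedness
        else:
            direction = "R" if s.trans > 0 else "L"

    r_int = r_ext = float("nan")
    if monomer is not None:
        coords = _coords_of(monomer)
        rel = coords - s.point
        par = rel @ s.axis
        perp = rel - np.outer(par, s.axis)
        d = np.linalg.norm(perp, axis=1)
        r_int, r_ext = float(d.min()), float(d.max())
    return HelixParams(n, pitch, direction, r_int, r_ext)


def angular_deviation(t1: RigidTransform, t2: RigidTransform) -> float:
    """Rotation angle (degrees) of ``t1 . t2^-1``.

    Used as the scalar deviation between two binding geometries.
    """
    diff = t1.compose(t2.inverse())
    vec = Rotation.from_matrix(diff.rotation).as_rotvec()
    return float(np.degrees(np.linalg.norm(vec)))


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, np.ndarray):
        return obj
    if hasattr(obj, "coords"):
        return np.asarray(obj.coords)
    raise TypeError(f"cannot extract coordinates from {type(obj)!r}")
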