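"""Construction of oligomeric assemblies from screw transforms.

Regular filaments repeat a single screw step; mixed-mode filaments chain
an arbitrary sequence of interface transforms; curved-axis construction
re-plays the screw geometry along a guide curve using a
rotation-minimizing (parallel-transport) frame, which reproduces the
straight-line construction exactly in the zero-curvature limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    HelixParams,
    RigidTransform,
    Screw,
    helix_params,
    screw_from_transform,
)
from .structures import Structure, chain_id_sequence

__all__ = [
    "FilamentSpec",
    "GuideCurve",
    "helical_guide",
    "circular_guide",
    "straight_guide",
    "build_filament",
    "build_mixed_filament",
    "build_on_curve",
    "build_supercoiled_pair",
    "concat_chains",
    "ClashWarning",
]

MAX_MONOMERS = 2000  # memory guard for construction


class ClashWarning(UserWarning):
    """Consecutive placements overlap or strands collide."""


@dataclass(frozen=True)
class FilamentSpec:
    """Recipe for a mixed-mode filament.

    ``steps`` is an ordered list of (screw-or-label, repeat count); the
    expanded sequence of interface transforms places monomer i+1 from
    monomer i.  Labels resolve through ``interfaces``.
    """

    steps: tuple
    interfaces: dict = field(default_factory=dict)

    def resolve(self) -> list[Screw]:
        out: list[Screw] = []
        for item, count in self.steps:
            if isinstance(item, str):
                if item not in self.interfaces:
                    raise KeyError(f"unknown interface label {item!r}")
                item = self.interfaces[item]
            out.extend([item] * int(count))
        if not out:
            raise ValueError("empty filament spec")
        return out


def concat_chains(monomers: list[Structure], label: str = "") -> Structure:
    """Merge monomer copies into one multi-chain structure with a
    deterministic chain-id sequence (A, B, ..., AA, AB, ...)."""
    ids = chain_id_sequence()
    parts = [m.with_chain_id(next(ids)) for m in monomers]
    return Structure(
        np.concatenate([p.atom_names for p in parts]),
        np.concatenate([p.elements for p in parts]),
        np.concatenate([p.res_ids for p in parts]),
        np.concatenate([p.ins_codes for p in parts]),
        np.concatenate([p.res_names for p in parts]),
        np.concatenate([p.chain_ids for p in parts]),
        np.concatenate([p.coords for p in parts]),
        label=label,
    )


def _check_clashes(monomers: list[Structure], min_dist: float = 1.0) -> None:
    from scipy.spatial import cKDTree

    for a, b in zip(monomers, monomers[1:]):
        if cKDTree(a.coords).query_ball_point(b.coords, min_dist,
                                              return_length=True).sum() > 0:
            warnings.warn("consecutive monomers overlap", ClashWarning, stacklevel=3)
            return


def build_filament(monomer: Structure, s: Screw, n: int) -> Structure:
    """n copies of ``monomer`` related by powers of the screw transform."""
    if n < 2:
        raise ValueError("a filament needs at least 2 monomers")
    if n > MAX_MONOMERS:
        raise ValueError(f"n={n} exceeds the construction budget ({MAX_MONOMERS})")
    T = s.to_transform()
    placed = []
    cur = RigidTransform.identity()
    for _ in range(n):
        placed.append(monomer.transformed(cur))
        cur = T.compose(cur)
    return concat_chains(placed, label=f"{monomer.label}|filament-{n}")


def build_mixed_filament(monomer: Structure, spec: FilamentSpec
                         ) -> tuple[Structure, HelixParams]:
    """Filament chaining heterogeneous interface transforms.

    Returns the structure plus the helix parameters of the repeat-block
    composite transform (the super-helix the full step sequence
    generates when repeated).
    """
    screws = spec.resolve()
    n = len(screws) + 1
    if n > MAX_MONOMERS:
        raise ValueError(f"{n} monomers exceed the construction budget")
    placed = [monomer]
    cur = RigidTransform.identity()
    block = RigidTransform.identity()
    for s in screws:
        T = s.to_transform()
        cur = cur.compose(T)  # monomer i+1 = T_1 ... T_i applied to monomer 0
        block = block.compose(T)
        placed.append(monomer.transformed(cur))
    _check_clashes(placed)
    super_screw = screw_from_transform(block)
    hp_block = helix_params(super_screw, monomer)
    struct = concat_chains(placed, label=f"{monomer.label}|mixed-{n}")
    return struct, hp_block


# ---------------------------------------------------------------------------
# guide curves


@dataclass(frozen=True)
class GuideCurve:
    """Arc-length parameterized C1 curve with rotation-minimizing frames."""

    points: np.ndarray  # densely sampled curve points
    arc: np.ndarray  # cumulative arc length at each sample

    @classmethod
    def from_samples(cls, points: np.ndarray) -> "GuideCurve":
        pts = np.asarray(points, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(pts, arc)

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def frames(self, stations: np.ndarray):
        """Position + rotation-minimizing orthonormal frame (t, u, v) at
        the requested arc lengths.

        Frames are propagated by the double-reflection parallel
        transport, which keeps normal rotation minimal (no Frenet
        torsion blow-up at inflections).
        """
        stations = np.asarray(stations, dtype=float)
        if np.any(stations > self.length + 1e-9):
            raise ValueError("guide curve shorter than requested span")
        # tangents from finite differences on the dense sampling
        tang = np.gradient(self.points, self.arc, axis=0)
        tang /= np.linalg.norm(tang, axis=1)[:, None]
        # initial normal: any unit vector orthogonal to t0
        t0 = tang[0]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(t0 @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = ref - (ref @ t0) * t0
        u /= np.linalg.norm(u)
        us = [u]
        for i in range(1, len(self.points)):
            # double-reflection step (Wang et al. rotation-minimizing frames)
            v1 = self.points[i] - self.points[i - 1]
            c1 = v1 @ v1
            if c1 < 1e-18:
                us.append(us[-1])
                continue
            uL = us[-1] - (2.0 / c1) * (v1 @ us[-1]) * v1
            tL = tang[i - 1] - (2.0 / c1) * (v1 @ tang[i - 1]) * v1
            v2 = tang[i] - tL
            c2 = v2 @ v2
            if c2 < 1e-18:
                ui = uL
            else:
                ui = uL - (2.0 / c2) * (v2 @ uL) * v2
            ui -= (ui @ tang[i]) * tang[i]
            ui /= np.linalg.norm(ui)
            us.append(ui)
        us = np.array(us)

        out = []
        for sv in stations:
            i = int(np.searchsorted(self.arc, sv, side="right")) - 1
            i = min(max(i, 0), len(self.arc) - 2)
            f = (sv - self.arc[i]) / max(self.arc[i + 1] - self.arc[i], 1e-12)
            pos = (1 - f) * self.points[i] + f * self.points[i + 1]
            t = (1 - f) * tang[i] + f * tang[i + 1]
            t /= np.linalg.norm(t)
            u = (1 - f) * us[i] + f * us[i + 1]
            u -= (u @ t) * t
            u /= np.linalg.norm(u)
            v = np.cross(t, u)
            out.append((pos, t, u, v))
        return out


def straight_guide(length: float, n_samples: int = 512) -> GuideCurve:
    z = np.linspace(0.0, length, n_samples)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return GuideCurve.from_samples(pts)


def circular_guide(circumference: float, n_samples: int = 4096) -> GuideCurve:
    radius = circumference / (2 * np.pi)
    t = np.linspace(0.0, 2 * np.pi, n_samples)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                           np.zeros_like(t)])
    return GuideCurve.from_samples(pts)


def helical_guide(pitch: float, radius: float, turns: float,
                  phase: float = 0.0, n_samples: int = 4096) -> GuideCurve:
    t = np.linspace(0.0, 2 * np.pi * turns, n_samples)
    pts = np.column_stack([
        radius * np.cos(t + phase),
        radius * np.sin(t + phase),
        pitch * t / (2 * np.pi),
    ])
    return GuideCurve.from_samples(pts)


def build_on_curve(monomer: Structure, s: Screw, curve: GuideCurve,
                   n: int) -> Structure:
    """Place ``n`` monomers along a guide curve.

    Monomer i sits at arc length i*|trans| in the local
    rotation-minimizing frame, twisted by i*theta about the local
    tangent; for a straight guide this equals :func:`build_filament` (up
    to the global placement of the screw axis at the curve origin).
    """
    rise = abs(s.trans)
    if rise < 1e-9:
        raise ValueError("curved construction needs a nonzero axial rise")
    if (n - 1) * rise > curve.length + 1e-9:
        raise ValueError("guide curve shorter than the requested filament")
    hp = helix_params(s, monomer)
    # monomer coordinates in the axis frame of the generating screw:
    # axis -> +z through the origin
    axis_frame = _axis_frame(s)
    local = monomer.transformed(axis_frame)
    local_coords = local.coords
    theta = np.radians(s.angle_deg) * np.sign(s.trans)
    stations = np.arange(n) * rise
    frames = curve.frames(stations)
    # warn if the curve bends tighter than the monomer extent
    _warn_if_overcurved(curve, hp.r_ext)
    placed = []
    for i, (pos, t, u, v) in enumerate(frames):
        # frame basis with cumulative twist i*theta applied about the tangent;
        # columns map local (x, y, z) onto (twisted u, twisted v, t)
        c, sn = np.cos(i * theta), np.sin(i * theta)
        basis = np.column_stack([u * c + v * sn, -u * sn + v * c, t])
        placed_coords = local_coords @ basis.T + pos
        placed.append(replace(local, coords=placed_coords))
    return concat_chains(placed, label=f"{monomer.label}|curved-{n}")


def _axis_frame(s: Screw) -> RigidTransform:
    """Transform taking the screw axis onto +z through the origin."""
    z = np.array([0.0, 0.0, 1.0])
    a = s.axis
    v = np.cross(a, z)
    c = float(a @ z)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return RigidTransform(R, -R @ s.point)


def _warn_if_overcurved(curve: GuideCurve, r_ext: float) -> None:
    if not np.isfinite(r_ext):
        return
    d1 = np.gradient(curve.points, curve.arc, axis=0)
    d2 = np.gradient(d1, curve.arc, axis=0)
    kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(
        np.linalg.norm(d1, axis=1) ** 3, 1e-12)
    kmax = np.percentile(kappa, 95)
    if kmax > 0 and 1.0 / kmax < r_ext:
        warnings.warn(
            f"curvature radius {1.0 / kmax:.1f} A below monomer extent "
            f"{r_ext:.1f} A: self-intersection likely",
            ClashWarning, stacklevel=3,
        )


def build_supercoiled_pair(monomer: Structure, s: Screw,
                           supercoil_pitch: float, separation: float,
                           n: int) -> Structure:
    """Two filaments wound on parallel helical guide curves.

    ``supercoil_pitch`` is the pitch of the superhelical guides (pass
    ``inf`` for two straight parallel filaments); ``separation`` the
    distance between the two strand axes.
    """
    if separation <= 0:
        raise ValueError("strand separation must be positive")
    hp = helix_params(s, monomer)
    if np.isfinite(hp.r_ext) and separation < 2 * hp.r_ext:
        warnings.warn(
            f"strand separation {separation:.1f} A below twice the monomer "
            f"extent {hp.r_ext:.1f} A: inter-strand clash likely",
            ClashWarning, stacklevel=2,
        )
    radius = separation / 2.0
    length_needed = (n - 1) * abs(s.trans) * 1.05 + abs(s.trans)
    strands = []
    for phase in (0.0, np.pi):
        if np.isfinite(supercoil_pitch):
            turns = length_needed / supercoil_pitch + 0.05
            guide = helical_guide(supercoil_pitch, radius, turns, phase=phase)
        else:
            offset = np.array([radius * np.cos(phase), radius * np.sin(phase), 0.0])
            z = np.linspace(0.0, length_needed, 512)
            pts = offset + np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
            guide = GuideCurve.from_samples(pts)
        strands.append(build_on_curve(monomer, s, guide, n))
    merged = [strands[0].mask(strands[0].chain_ids == c) for c in strands[0].chains()]
    merged += [strands[1].mask(strands[1].chain_ids == c) for c in strands[1].chains()]
    return concat_chains(merged, label=f"{monomer.label}|supercoil-2x{n}")
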