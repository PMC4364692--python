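"""Deterministic synthetic structures for testing without downloads.

Toy monomers are self-avoiding pseudo-proteins with one CA and one
side-chain pseudo-atom (CB) per residue; three shapes are available:
``blob`` (compact random walk), ``rod`` (extended) and ``horseshoe``
(an arc, so rings assembled from it have a hollow center).  All
generation is reproducible from the seed, and the generating truth
(screw, jitter) is recorded alongside assembly fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import concat_chains
from .geometry import RigidTransform, Screw, transform_from_screw
from .structures import Structure

__all__ = ["FixtureTruth", "make_toy_monomer", "make_assembly_fixture"]

CA_STEP = 3.8  # A, consecutive CA distance
MIN_SEPARATION = 4.0  # A, self-avoidance radius

# residue-name cycle: mixes neutral and ionizable types so reduced
# representations carry charges
RES_CYCLE = ("ALA", "LEU", "ASP", "SER", "LYS", "VAL", "GLU", "THR", "ARG", "GLY")


@dataclass(frozen=True)
class FixtureTruth:
    screw: Screw | None
    n_monomers: int
    jitter_trans: float
    jitter_angle_deg: float
    seed: int
    category_hint: str = ""


def _self_avoiding_walk(n: int, rng: np.random.Generator,
                        compactness: float) -> np.ndarray:
    """CA trace: random walk with a bias toward the origin controlled by
    ``compactness`` (0 = free walk, 1 = strongly collapsed)."""
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        for _attempt in range(200):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pull = -pts[-1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                d = (1 - compactness) * d + compactness * pull / norm
                d /= np.linalg.norm(d)
            cand = pts[-1] + CA_STEP * d
            prev = np.array(pts[:-1]) if len(pts) > 1 else None
            if prev is None or np.linalg.norm(prev - cand, axis=1).min() >= MIN_SEPARATION:
                pts.append(cand)
                break
        else:  # give up self-avoidance for this step (rare)
            pts.append(pts[-1] + CA_STEP * d)
    return np.array(pts)


def _arc_trace(n: int, bend_deg: float) -> np.ndarray:
    """CA trace along a circular arc in the xy plane."""
    total = np.radians(bend_deg)
    radius = CA_STEP / (2 * np.sin(total / (2 * (n - 1)))) if n > 1 else 1.0
    t = np.linspace(0.0, total, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            np.zeros_like(t)])


def make_toy_monomer(n_residues: int, shape: str = "blob",
                     seed: int = 0, label: str | None = None) -> Structure:
    """Deterministic pseudo-protein with CA + CB atoms per residue."""
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if shape == "blob":
        ca = _self_avoiding_walk(n_residues, rng, compactness=0.35)
    elif shape == "rod":
        ca = np.column_stack([
            np.zeros(n_residues), np.zeros(n_residues),
            CA_STEP * np.arange(n_residues, dtype=float)])
        ca += rng.normal(scale=0.3, size=ca.shape)
    elif shape == "horseshoe":
        ca = _arc_trace(n_residues, bend_deg=200.0)
        ca += rng.normal(scale=0.2, size=ca.shape)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    ca -= ca.mean(axis=0)

    atom_names, elements, res_ids, res_names, coords = [], [], [], [], []
    for i in range(n_residues):
        res_name = RES_CYCLE[i % len(RES_CYCLE)]
        atom_names.append("CA")
        elements.append("C")
        res_ids.append(i + 1)
        res_names.append(res_name)
        coords.append(ca[i])
        if res_name != "GLY":
            # pseudo side chain pointing away from the local backbone
            away = ca[i] - ca.mean(axis=0)
            norm = np.linalg.norm(away)
            away = away / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            atom_names.append("CB")
            elements.append("C")
            res_ids.append(i + 1)
            res_names.append(res_name)
            coords.append(ca[i] + 1.5 * away)
    n = len(coords)
    return Structure(
        np.array(atom_names), np.array(elements), np.array(res_ids),
        np.array([""] * n), np.array(res_names), np.array(["A"] * n),
        np.array(coords), label=label or f"toy-{shape}-{n_residues}-s{seed}",
    )


def make_assembly_fixture(
    monomer: Structure,
    screw: Screw,
    n: int,
    jitter_trans: float = 0.0,
    jitter_angle_deg: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, FixtureTruth]:
    """Place ``n`` copies of the monomer by the screw, with optional
    per-interface jitter (axial offset and random small rotation) used to
    engineer near-cyclic closure defects."""
    rng = np.random.default_rng(seed)
    T = transform_from_screw(screw)
    placed = []
    cur = RigidTransform.identity()
    for i in range(n):
        placed.append(monomer.transformed(cur))
        step = T
        if jitter_trans or jitter_angle_deg:
            dR = Rotation.from_rotvec(
                np.radians(jitter_angle_deg) * _unit(rng)).as_matrix()
            dt = jitter_trans * screw.axis
            step = RigidTransform(dR @ T.rotation, dR @ T.translation + dt)
        cur = step.compose(cur)
    truth = FixtureTruth(screw, n, jitter_trans, jitter_angle_deg, seed)
    return concat_chains(placed, label=f"{monomer.label}|fixture-{n}"), truth


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
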