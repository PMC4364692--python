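"""End-to-end pipeline: dock -> filter -> screw analysis -> classify ->
adjust/screen -> gallery.

One configuration dictionary drives every stage and threshold; the
report names the config hash so each artifact is attributable to the
exact settings that produced it.  All stages are deterministic given the
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .assembly import build_filament
from .classify import GeometryCategory, adjust_to_cyclic, classify_geometry
from .docking import (
    DockResult,
    FilterCriteria,
    dock,
    filter_poses,
    generate_starts,
)
from .energetics import (
    DEFAULT_FF,
    ForceFieldParams,
    per_residue_best_energy,
    steric_screen,
)
from .geometry import helix_params
from .reduce import coarse_grain
from .structures import Structure, write_structure

__all__ = ["WorkflowConfig", "WorkflowReport", "run_workflow"]


@dataclass(frozen=True)
class WorkflowConfig:
    seed: int = 0
    mode: str = "global"
    surface_distance: float = 5.0
    spacing: float | None = None
    orientations: int = 4
    energy_window: float = 20.0
    boundary_residues: tuple = ()
    dedup_rmsd: float = 1.0
    gallery_size: int = 10
    ring_monomers_cap: int = 24
    outdir: str | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class WorkflowReport:
    config_hash: str
    n_starts: int
    n_after_filter: int
    categories: dict = field(default_factory=dict)
    signature: list = field(default_factory=list)  # (N, P, dir, E, category)
    gallery: list = field(default_factory=list)  # (label, category, structure)
    residue_energy: dict = field(default_factory=dict)

    def signature_table(self) -> str:
        lines = ["n_per_turn\tpitch\tdir\tenergy_rt\tcategory"]
        for n, p, d, e, cat in self.signature:
            lines.append(f"{n:.3f}\t{p:.3f}\t{d}\t{e:.3f}\t{cat}")
        return "\n".join(lines) + "\n"


def run_workflow(monomer: Structure, config: WorkflowConfig,
                 ff: ForceFieldParams = DEFAULT_FF) -> WorkflowReport:
    """Run the full assembly-discovery pipeline on one monomer."""
    reduced = coarse_grain(monomer)
    grid = generate_starts(
        reduced, reduced, mode=config.mode,
        surface_distance=config.surface_distance,
        spacing=config.spacing, orientations=config.orientations,
        seed=config.seed,
    )
    result = dock(reduced, reduced, grid, ff, seed=config.seed)
    criteria = FilterCriteria(
        energy_window=config.energy_window,
        boundary_residues=config.boundary_residues,
        dedup_rmsd=config.dedup_rmsd,
    )
    kept = filter_poses(result, criteria, reduced, reduced)

    r_m = monomer.max_radius()
    categories: dict[str, int] = {}
    signature = []
    gallery = []
    for rank, (pose, screw) in enumerate(zip(kept.poses, kept.screws)):
        hp = helix_params(screw, monomer)
        cat = classify_geometry(hp, r_m)
        if cat.label == "NearCyclic" and cat.ring_size:
            best = None
            for k in (int(np.floor(hp.n_per_turn)), int(np.ceil(hp.n_per_turn))):
                if k < 2 or k > config.ring_monomers_cap:
                    continue
                adj = adjust_to_cyclic(pose, reduced, k, ff, seed=config.seed)
                if adj.succeeded and (best is None
                                      or adj.energy_after < best[0].energy_after):
                    best = (adj, k)
            if best is not None:
                adj, k = best
                pose = adj.pose
                screw = adj.screw
                hp = helix_params(screw, monomer)
                cat = classify_geometry(hp, r_m)
        elif cat.label == "NearHelical":
            screen = steric_screen(reduced, screw, ff)
            cat = GeometryCategory(cat.label, cat.n_per_turn, cat.pitch,
                                   cat.r_m, cat.ring_size, cat.closure_defect,
                                   clash=screen["clash"])
        categories[cat.label] = categories.get(cat.label, 0) + 1
        signature.append((hp.n_per_turn if np.isfinite(hp.n_per_turn) else -1.0,
                          hp.pitch if np.isfinite(hp.pitch) else -1.0,
                          hp.handedness, pose.energy, cat.label))
        if len(gallery) < config.gallery_size and not (cat.clash or False):
            n_build = (cat.ring_size if cat.label == "Cyclic" and cat.ring_size
                       else min(8, config.ring_monomers_cap))
            try:
                built = build_filament(monomer, screw, n_build)
            except ValueError:
                continue
            gallery.append((f"pose{rank:03d}", cat.label, built))

    best_e, _norm = per_residue_best_energy(kept.poses, reduced, reduced)
    report = WorkflowReport(
        config_hash=config.digest(),
        n_starts=len(grid),
        n_after_filter=len(kept),
        categories=categories,
        signature=signature,
        gallery=gallery,
        residue_energy={str(k): v for k, v in best_e.items()},
    )
    if config.outdir:
        _write_artifacts(report, config)
    return report


def _write_artifacts(report: WorkflowReport, config: WorkflowConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = report.config_hash
    (out / f"signature-{tag}.tsv").write_text(report.signature_table())
    (out / f"categories-{tag}.json").write_text(
        json.dumps(report.categories, indent=2) + "\n")
    (out / f"residue_energy-{tag}.json").write_text(
        json.dumps(report.residue_energy, indent=2, sort_keys=True) + "\n")
    for label, cat, built in report.gallery:
        write_structure(built, out / f"gallery-{tag}-{label}-{cat}.pdb")
    (out / f"provenance-{tag}.json").write_text(
        json.dumps({"config": asdict(config), "hash": tag}, indent=2,
                   default=str) + "\n")
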