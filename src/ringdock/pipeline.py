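"""End-to-end orchestration: map -> restrain -> dock -> cluster -> validate.

One schema-validated config drives the whole run; every stage writes its
outputs under the run directory in the same formats the library reads back
(PDB, TSV, JSON), and a manifest with config hash, seeds, input checksums
and stage timings is written even when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from . import clustering as clustering_mod
from . import docking as docking_mod
from . import interface_analysis
from . import nmr_mapping
from . import synthetic_data
from .restraints import CrosslinkRestraint, RestraintSet, define_airs
from .structure_io import StructureModel, merge, read_structure, write_structure

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ToySection(_Section):
    enabled: bool = False
    nx: int = 13
    ny: int = 13
    n_ligand_res: int = 26
    mu: float = 0.10
    sigma: float = 0.02
    rho: float = 0.0
    n_true_links: int = 1
    n_decoy_links: int = 0


class MappingSection(_Section):
    table: Optional[str] = None  # TSV path; ignored in toy mode
    kind: Literal["csp", "intensity_ratio"] = "csp"
    min_class: Literal["one_sd", "two_sd"] = "two_sd"
    trim_fraction: float = 0.10


class RestraintSection(_Section):
    ligand_actives: list[tuple[str, int]] = []
    rsa_threshold: float = 0.15
    neighbor_cutoff: float = 6.5
    crosslinks: list[tuple[str, int, str, str, int, str, float]] = []  # + upper bound
    # AIR effective-distance bound; None resolves to 2.0 A for all-atom
    # structures and to the 5.0 A contact scale for coarse toy systems
    air_upper_bound: Optional[float] = None


class DockSection(_Section):
    n_trials: int = 500
    n_keep: int = 200
    w_air: float = 1.0
    w_xl: float = 1.0
    w_clash: float = 10.0
    sasd_reject: float = 35.0
    local_steps: int = 80
    polish_top: int = 150
    polish_maxfev: int = 150
    search_sasd_voxel: float = 2.0
    final_sasd_voxel: Optional[float] = 1.0
    final_sasd_top: int = 10
    supplied_ensemble: Optional[str] = None  # validation-only runs


class ClusterSection(_Section):
    similarity_cutoff: float = 0.75
    min_size: int = 4
    contact_cutoff: float = 5.0


class ValidateSection(_Section):
    max_sasd: float = 30.0
    n_models: int = 10
    e2_chain: Optional[str] = None
    catalytic_residue: int = 85
    target_lysines: list[tuple[str, int]] = []


import warnings as _warnings

with _warnings.catch_warnings():
    # the stage flag legitimately shares its name with a deprecated
    # BaseModel classmethod
    _warnings.filterwarnings("ignore", message='Field name "validate"')

    class StageToggles(_Section):
        map: bool = True
        restrain: bool = True
        dock: bool = True
        cluster: bool = True
        validate: bool = True


class PipelineConfig(_Section):
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "ringdock_run"
    receptor: Optional[str] = None
    ligand: Optional[str] = None
    toy: ToySection = ToySection()
    mapping: MappingSection = MappingSection()
    restraints: RestraintSection = RestraintSection()
    docking: DockSection = DockSection()
    clustering: ClusterSection = ClusterSection()
    validation: ValidateSection = ValidateSection()
    stages: StageToggles = StageToggles()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    config_hash: str
    seed: int
    version: str
    input_checksums: dict[str, str] = {}
    stage_timings: dict[str, float] = {}
    stage_counts: dict[str, dict] = {}
    failed_stage: Optional[str] = None
    error: Optional[str] = None

    def write(self, path: Path) -> None:
        path.write_text(self.model_dump_json(indent=1))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order; outputs land in ``output_dir``.

    Re-running with the same config and inputs is bit-identical for the
    deterministic stages (everything except wall-clock timings in the
    manifest).  On stage failure the manifest records the stage and cause
    and the exception propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           version=__version__)
    stage = "setup"
    try:
        t0 = time.perf_counter()
        toy = None
        if config.toy.enabled:
            toy = synthetic_data.make_toy_complex(
                seed=config.seed, nx=config.toy.nx, ny=config.toy.ny,
                n_ligand_res=config.toy.n_ligand_res,
            )
            receptor, ligand = toy.receptor, toy.ligand
            write_structure(receptor, out / "receptor.pdb")
            write_structure(ligand, out / "ligand.pdb")
            table = synthetic_data.synthesize_perturbation_table(
                toy, mu=config.toy.mu, sigma=config.toy.sigma,
                rho=config.toy.rho, seed=config.seed + 1,
            )
            table.to_csv(out / "perturbations.tsv")
            links, link_truth = synthetic_data.synthesize_crosslinks(
                toy, n_true=config.toy.n_true_links,
                n_decoys=config.toy.n_decoy_links, seed=config.seed + 2,
            )
            ligand_actives = toy.ligand_actives
            (out / "truth.json").write_text(json.dumps({
                "planted_pose": toy.planted_pose.to_dict(),
                "true_interface_receptor": toy.true_interface_receptor,
                "true_interface_ligand": toy.true_interface_ligand,
                "crosslinks": {k: v for k, v in link_truth.items() if k != "candidates"},
                "generator": toy.manifest,
            }, indent=1, default=str))
        else:
            if not config.receptor or not config.ligand:
                raise ValueError("receptor and ligand paths required outside toy mode")
            rpath, lpath = Path(config.receptor), Path(config.ligand)
            manifest.input_checksums[rpath.name] = _checksum(rpath)
            manifest.input_checksums[lpath.name] = _checksum(lpath)
            receptor = read_structure(rpath)[0]
            ligand = read_structure(lpath)[0]
            table = None
            if config.mapping.table:
                tpath = Path(config.mapping.table)
                manifest.input_checksums[tpath.name] = _checksum(tpath)
                table = nmr_mapping.PerturbationTable.from_csv(tpath, kind=config.mapping.kind)
            links = [
                CrosslinkRestraint(atom_receptor=(c[0], c[1], c[2]),
                                   atom_ligand=(c[3], c[4], c[5]), upper_bound=c[6])
                for c in config.restraints.crosslinks
            ]
            ligand_actives = list(config.restraints.ligand_actives)
        manifest.stage_timings["setup"] = time.perf_counter() - t0

        receptor_actives: list[tuple[str, int]] = []
        if config.stages.map:
            stage = "map"
            t0 = time.perf_counter()
            if table is None:
                raise ValueError("mapping stage enabled but no perturbation table")
            params = nmr_mapping.SignificanceParams(
                trim_fraction=config.mapping.trim_fraction,
                side="high" if table.kind == "csp" else "low",
            )
            classified = nmr_mapping.classify_perturbations(table, params)
            classified.to_csv(out / "mapping.tsv")
            receptor_actives = classified.significant(config.mapping.min_class)
            manifest.stage_counts["map"] = {
                "n_residues": len(classified.frame),
                "n_active": len(receptor_actives),
            }
            manifest.stage_timings["map"] = time.perf_counter() - t0

        restraint_set = None
        if config.stages.restrain:
            stage = "restrain"
            t0 = time.perf_counter()
            bound = config.restraints.air_upper_bound
            if bound is None:
                bound = 5.0 if config.toy.enabled else 2.0
            restraint_set = define_airs(
                receptor_actives, ligand_actives, receptor, ligand,
                rsa_threshold=config.restraints.rsa_threshold,
                neighbor_cutoff=config.restraints.neighbor_cutoff,
                crosslinks=links,
                air_upper_bound=bound,
            )
            restraint_set.to_json(out / "restraints.json")
            manifest.stage_counts["restrain"] = {
                "n_airs": len(restraint_set.airs),
                "n_crosslinks": len(restraint_set.crosslinks),
            }
            manifest.stage_timings["restrain"] = time.perf_counter() - t0

        poses: list = []
        if config.stages.dock:
            stage = "dock"
            t0 = time.perf_counter()
            if config.docking.supplied_ensemble:
                raise ValueError("supplied_ensemble is for validation-only runs; disable dock")
            if restraint_set is None:
                raise ValueError("docking requires the restrain stage")
            dcfg = docking_mod.DockingConfig(
                n_trials=config.docking.n_trials, n_keep=config.docking.n_keep,
                seed=config.seed, w_air=config.docking.w_air,
                w_xl=config.docking.w_xl, w_clash=config.docking.w_clash,
                sasd_reject=config.docking.sasd_reject,
                local_steps=config.docking.local_steps,
                polish_top=config.docking.polish_top,
                polish_maxfev=config.docking.polish_maxfev,
                search_sasd_voxel=config.docking.search_sasd_voxel,
                final_sasd_voxel=config.docking.final_sasd_voxel,
                final_sasd_top=config.docking.final_sasd_top,
            )
            poses, dock_stats = docking_mod.generate_poses(receptor, ligand, restraint_set, dcfg)
            _write_scores(poses, out / "scores.tsv")
            n_write = min(len(poses), config.validation.n_models)
            if n_write:
                models = [
                    merge([receptor, ligand.transformed(
                        sp.pose.rotation_matrix, sp.pose.translation)], model_id=i + 1)
                    for i, sp in enumerate(poses[:n_write])
                ]
                write_structure(models, out / "ensemble.pdb")
            (out / "poses.json").write_text(json.dumps(
                [dict(rank=sp.rank, total=sp.total, pose=sp.pose.to_dict()) for sp in poses],
                indent=1))
            manifest.stage_counts["dock"] = {k: v for k, v in dock_stats.items()}
            manifest.stage_timings["dock"] = time.perf_counter() - t0

        cluster_result = None
        if config.stages.cluster and poses:
            stage = "cluster"
            t0 = time.perf_counter()
            cluster_result = clustering_mod.cluster_poses(
                poses, receptor, ligand,
                similarity_cutoff=config.clustering.similarity_cutoff,
                min_size=config.clustering.min_size,
                contact_cutoff=config.clustering.contact_cutoff,
            )
            (out / "clusters.json").write_text(json.dumps({
                "clusters": cluster_result.clusters,
                "representatives": cluster_result.representatives,
                "fraction_clustered": cluster_result.fraction_clustered,
                "unclustered": cluster_result.unclustered,
            }, indent=1))
            manifest.stage_counts["cluster"] = {
                "n_clusters": cluster_result.n_clusters,
                "fraction_clustered": cluster_result.fraction_clustered,
            }
            manifest.stage_timings["cluster"] = time.perf_counter() - t0

        if config.stages.validate:
            stage = "validate"
            t0 = time.perf_counter()
            if config.docking.supplied_ensemble:
                models = read_structure(Path(config.docking.supplied_ensemble))
            elif poses:
                models = [
                    merge([receptor, ligand.transformed(
                        sp.pose.rotation_matrix, sp.pose.translation)], model_id=i + 1)
                    for i, sp in enumerate(poses[: config.validation.n_models])
                ]
            else:
                models = [merge([receptor, ligand])]
            report = validate_models(
                models, links,
                max_sasd=config.validation.max_sasd,
                e2_chain=config.validation.e2_chain,
                catalytic_residue=config.validation.catalytic_residue,
                target_lysines=config.validation.target_lysines,
            )
            if toy is not None and cluster_result is not None and cluster_result.representatives:
                rep_rank = cluster_result.representatives[
                    cluster_result.top_cluster_index()
                ]
                rep = next(sp for sp in poses if sp.rank == rep_rank)
                report["toy_recovery"] = {
                    "top_cluster_representative_rank": rep_rank,
                    "ligand_rmsd_to_planted": toy.ligand_rmsd(rep.pose),
                    "best_pose_rmsd_to_planted": toy.ligand_rmsd(poses[0].pose),
                }
            (out / "validation.json").write_text(json.dumps(report, indent=1, default=str))
            manifest.stage_timings["validate"] = time.perf_counter() - t0
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        traceback.print_exc()
        raise
    manifest.write(out / "manifest.json")
    return manifest


def validate_models(
    models,
    observed_links,
    max_sasd: float = 30.0,
    e2_chain: str | None = None,
    catalytic_residue: int = 85,
    target_lysines=(),
) -> dict:
    """Bundle the validation read-outs for an ensemble into one report."""
    first = models[0]
    groups: dict[str, list[str]] = {}
    from .sasd import molecule_groups

    per_atom = molecule_groups(first)
    for ch in sorted(set(first.chain_ids)):
        g = per_atom[np.flatnonzero(first.chain_ids == ch)[0]]
        groups.setdefault(g, []).append(ch)
    group_names = sorted(groups)
    report: dict = {"n_models": len(models)}
    report["crosslinks"] = interface_analysis.crosslink_compatibility(
        models, observed_links, max_sasd=max_sasd)
    if len(group_names) >= 2:
        a, b = group_names[0], group_names[1]
        hb = interface_analysis.hydrogen_bonds(first, groups[a], groups[b])
        report["hydrogen_bonds"] = [
            {"donor": h.donor, "acceptor": h.acceptor, "distance": round(h.distance, 2)}
            for h in hb
        ]
    if e2_chain and target_lysines:
        geom = interface_analysis.catalytic_geometry(
            models, e2_chain, target_lysines, catalytic_residue=catalytic_residue)
        report["catalytic_geometry"] = {
            f"{c}:{n}": {"min": geom.ensemble_min((c, n)), "mean": geom.ensemble_mean((c, n))}
            for c, n in geom.lysines
        }
    else:
        report["catalytic_geometry"] = {}
    return report


def _write_scores(poses, path: Path) -> None:
    import pandas as pd

    rows = [
        {"rank": sp.rank, "trial": sp.trial_index, "e_air": sp.e_air,
         "e_xl": sp.e_xl, "e_clash": sp.e_clash, "total": sp.total,
         "max_crosslink_sasd": max(
             [v for v in sp.sasd_annotations.values()], default=float("nan"))}
        for sp in poses
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
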