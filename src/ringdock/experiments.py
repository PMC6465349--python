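"""Planted-pose recovery experiments on the synthetic toy system.

The package's primary self-validation: generate a toy complex with a known
bound pose, derive restraints the same way the real pipeline does (classify
a noisy perturbation table, take mutagenesis-analog ligand actives, add one
observed crosslink), dock, cluster, and measure how far the top cluster's
representative lands from the planted pose.  The scrambled variant replaces
the footprint with a wrong surface patch and the crosslink with a decoy and
must fail to recover the pose.
"""

from __future__ import annotations

import numpy as np

from . import clustering as clustering_mod
from . import docking as docking_mod
from . import synthetic_data
from .nmr_mapping import classify_perturbations
from .restraints import define_airs

__all__ = ["run_recovery_trial", "recovery_rate"]

TOY_AIR_BOUND = 5.0  # A; the toy's contact scale (one/two-atom residues)


def run_recovery_trial(
    seed: int,
    n_trials: int = 500,
    n_keep: int = 200,
    rho: float = 0.1,
    scrambled: bool = False,
    recovered_below: float = 5.0,
) -> dict:
    """One end-to-end toy run; returns recovery metrics and run statistics.

    ``seed`` drives the toy geometry, the synthetic observables and the
    docking search.  ``rho`` is the false-positive fraction of the
    perturbation footprint.  With ``scrambled`` the actives come from a
    random far surface patch and the crosslink is a decoy (negative
    control).
    """
    toy = synthetic_data.make_toy_complex(seed=seed)
    if scrambled:
        actives, link = synthetic_data.scramble_footprint(toy, seed=seed + 1)
        links = [link]
    else:
        table = synthetic_data.synthesize_perturbation_table(
            toy, rho=rho, seed=seed + 1)
        actives = classify_perturbations(table).significant("two_sd")
        links, _ = synthetic_data.synthesize_crosslinks(toy, seed=seed + 2)
    restraints = define_airs(
        actives, toy.ligand_actives, toy.receptor, toy.ligand,
        crosslinks=links, air_upper_bound=TOY_AIR_BOUND,
    )
    config = docking_mod.DockingConfig(
        n_trials=n_trials, n_keep=n_keep, seed=seed, final_sasd_voxel=None)
    poses, stats = docking_mod.generate_poses(
        toy.receptor, toy.ligand, restraints, config)
    result = {
        "seed": seed,
        "scrambled": scrambled,
        "n_actives": len(actives),
        "n_poses": len(poses),
        "dock_stats": stats,
        "recovered": False,
        "rep_rmsd": None,
        "rank1_rmsd": None,
        "fraction_clustered": None,
        "cluster_sizes": [],
    }
    if not poses:
        return result
    result["rank1_rmsd"] = toy.ligand_rmsd(poses[0].pose)
    clusters = clustering_mod.cluster_poses(poses, toy.receptor, toy.ligand)
    result["fraction_clustered"] = clusters.fraction_clustered
    result["cluster_sizes"] = sorted((len(c) for c in clusters.clusters), reverse=True)
    if clusters.clusters:
        top = clusters.top_cluster_index()
        rep_rank = clusters.representatives[top]
        rep = next(sp for sp in poses if sp.rank == rep_rank)
        result["rep_rmsd"] = toy.ligand_rmsd(rep.pose)
        result["recovered"] = result["rep_rmsd"] < recovered_below
    return result


def recovery_rate(results: list[dict]) -> float:
    return sum(r["recovered"] for r in results) / len(results)
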