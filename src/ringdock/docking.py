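"""Restraint-driven rigid-body docking with crosslink-SASD filtering.

The search is deliberately simple and fully documented: ``n_trials`` random
initial placements of the ligand over the restraint-defined face of the
receptor, each refined by a seeded stochastic rigid-body descent (small
random translations/rotations, accepted only when the total score drops).
The score is a weighted sum of three terms,

    total = w_air * E_AIR + w_xl * E_crosslink + w_clash * E_clash,

where the restraint terms are the flat-bottom energies of the AIR and
crosslink sets and the clash term penalizes inter-molecular heavy-atom
overlap quadratically.  It is a documented surrogate for the physics-based
score of full docking programs: restraint bounds drive the geometry and the
absolute energies only rank poses.

Because the docking score imposes crosslinks as Euclidean distances while a
chemical crosslinker must travel around the protein surface, every
candidate solution is additionally filtered on the solvent-accessible
surface distance (SASD) of the observed crosslinks: poses with any
crosslink SASD above the rejection limit (35 A by default) are dropped.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import sasd as sasd_mod
from .pose import Pose
from .restraints import RestraintEvaluator, RestraintSet
from .structure_io import StructureModel

__all__ = [
    "DockingConfig",
    "ScoredPose",
    "generate_poses",
    "score_pose",
    "filter_by_sasd",
    "mutate_residue_in_silico",
]

CLASH_SOFTENING = 0.4  # A subtracted from the radius sum before penalizing


@dataclasses.dataclass
class DockingConfig:
    """Search and scoring parameters.

    ``n_keep`` defaults to 200 ranked poses (the rigid-body analog of a
    200-member refined ensemble); ``sasd_reject`` is the crosslink-SASD
    rejection limit in Angstrom.
    """

    n_trials: int = 500
    n_keep: int = 200
    seed: int = 0
    w_air: float = 1.0
    w_xl: float = 1.0
    w_clash: float = 10.0
    sasd_reject: float = 35.0
    local_steps: int = 80
    max_step_trans: float = 2.0  # A per move
    max_step_rot: float = 10.0  # degrees per move
    polish_top: int = 150  # candidates refined by the deterministic local polish
    polish_maxfev: int = 150  # score evaluations per polish
    search_sasd_voxel: float = 2.0  # coarse grid during filtering
    final_sasd_voxel: float | None = 1.0  # best poses re-measured; None skips
    final_sasd_top: int = 10  # how many top poses get the fine re-measure

    def __post_init__(self):
        if self.n_keep > max(self.n_trials, 0) and self.n_trials > 0:
            self.n_keep = self.n_trials
        if self.sasd_reject <= 0:
            raise ValueError("sasd_reject must be positive")


@dataclasses.dataclass
class ScoredPose:
    pose: Pose
    e_air: float
    e_xl: float
    e_clash: float
    total: float
    trial_index: int
    sasd_annotations: dict = dataclasses.field(default_factory=dict)
    rank: int | None = None

    def sort_key(self):
        return (self.total, self.e_air, self.trial_index)


class _Scorer:
    """Caches receptor geometry and restraint indices for fast re-scoring."""

    def __init__(self, receptor: StructureModel, ligand: StructureModel,
                 restraints: RestraintSet, config: DockingConfig):
        self.config = config
        self.evaluator = RestraintEvaluator(restraints, receptor, ligand)
        heavy_r = receptor.heavy_mask()
        self.rec_heavy_pos = receptor.positions[heavy_r]
        self.rec_heavy_radii = receptor.radii[heavy_r]
        self.rec_tree = cKDTree(self.rec_heavy_pos)
        self.lig_heavy = ligand.heavy_mask()
        self.lig_heavy_radii = ligand.radii[self.lig_heavy]
        self.max_radius_sum = float(self.rec_heavy_radii.max() + self.lig_heavy_radii.max())

    def clash(self, ligand_pos: np.ndarray) -> float:
        lig = ligand_pos[self.lig_heavy]
        k = min(16, len(self.rec_heavy_pos))
        d, idx = self.rec_tree.query(
            lig, k=k, distance_upper_bound=self.max_radius_sum - CLASH_SOFTENING
        )
        d = np.asarray(d).reshape(len(lig), -1)
        idx = np.asarray(idx).reshape(len(lig), -1)
        valid = np.isfinite(d)
        if not valid.any():
            return 0.0
        li, _ = np.nonzero(valid)
        allowed = (self.rec_heavy_radii[idx[valid]] + self.lig_heavy_radii[li]
                   - CLASH_SOFTENING)
        overlap = allowed - d[valid]
        overlap = overlap[overlap > 0]
        return float((overlap ** 2).sum())

    def score(self, ligand_pos: np.ndarray) -> tuple[float, float, float, float]:
        e_air, e_xl = self.evaluator.energy(ligand_pos)
        e_clash = self.clash(ligand_pos)
        total = (self.config.w_air * e_air + self.config.w_xl * e_xl
                 + self.config.w_clash * e_clash)
        return e_air, e_xl, e_clash, total


def score_pose(
    pose: Pose,
    receptor: StructureModel,
    ligand: StructureModel,
    restraints: RestraintSet,
    config: DockingConfig | None = None,
) -> ScoredPose:
    """Score one pose; all components are invariant under joint rigid motion
    of the complex because they depend only on inter-atomic distances."""
    config = config or DockingConfig()
    scorer = _Scorer(receptor, ligand, restraints, config)
    e_air, e_xl, e_clash, total = scorer.score(pose.apply(ligand.positions))
    return ScoredPose(pose=pose, e_air=e_air, e_xl=e_xl, e_clash=e_clash,
                      total=total, trial_index=0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _small_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0, max_deg))
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle).as_matrix()


def generate_poses(
    receptor: StructureModel,
    ligand: StructureModel,
    restraints: RestraintSet,
    config: DockingConfig | None = None,
) -> tuple[list[ScoredPose], dict]:
    """Run the rigid-body search and return the ranked, SASD-filtered ensemble.

    Initial placements put the ligand centroid over the centroid of the
    receptor active residues, offset outward to contact distance, with a
    random orientation and lateral jitter; each placement is refined by
    ``local_steps`` greedy stochastic moves (<= 2 A translation, <= 10 deg
    rotation about the ligand centroid, accepted when the total score
    decreases).  Candidates are ranked by (total, e_air, trial index) and
    walked from the top through the crosslink-SASD filter until ``n_keep``
    poses are accepted.  Fully deterministic for a fixed config and seed.

    Returns ``(poses, stats)``; an empty ensemble comes back with rejection
    statistics rather than raising.
    """
    config = config or DockingConfig()
    stats = {"n_trials": config.n_trials, "n_candidates": 0,
             "n_sasd_evaluated": 0, "n_sasd_rejected": 0,
             "accepted_mean_sasd": None, "rejected_mean_sasd": None}
    if config.n_trials <= 0:
        return [], stats
    scorer = _Scorer(receptor, ligand, restraints, config)

    # restraint-defined face: centroid of receptor actives (fall back to the
    # whole surface if the set is empty)
    rec_actives = [a.active for a in restraints.airs if a.active_molecule == "receptor"]
    for a in restraints.airs:
        if a.active_molecule == "ligand":
            rec_actives.extend(a.partners)
    if rec_actives:
        pts = []
        for c, n in dict.fromkeys(rec_actives):
            mask = receptor.select_mask(chain=c, residue_number=n)
            if mask.any():
                pts.append(receptor.positions[mask].mean(axis=0))
        active_centroid = np.mean(pts, axis=0)
    else:
        active_centroid = receptor.positions.mean(axis=0)
    rec_centroid = receptor.positions.mean(axis=0)
    normal = active_centroid - rec_centroid
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 1e-6 else np.array([0.0, 0.0, 1.0])

    lig_centroid = ligand.positions.mean(axis=0)
    lig_radius = float(np.linalg.norm(ligand.positions - lig_centroid, axis=1).max())
    contact_dist = 0.6 * lig_radius + 3.0

    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    candidates: list[ScoredPose] = []
    lig_pos0 = ligand.positions
    for trial in range(config.n_trials):
        rng = np.random.default_rng(children[trial])
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_quat(_random_rotation(rng)).as_matrix()
        lateral = rng.normal(0, 4.0, 3)
        lateral -= normal * (lateral @ normal)  # jitter in the surface plane
        center = active_centroid + normal * contact_dist + lateral
        trans = center - rot @ lig_centroid
        pos = lig_pos0 @ rot.T + trans
        e_air, e_xl, e_clash, total = scorer.score(pos)
        # annealed greedy descent
        for step in range(config.local_steps):
            scale = 1.0 - 0.8 * step / max(config.local_steps - 1, 1)
            dr = _small_rotation(rng, config.max_step_rot * scale)
            dt = rng.uniform(-1, 1, 3)
            dt *= config.max_step_trans * scale * rng.uniform(0, 1) / max(np.linalg.norm(dt), 1e-9)
            cen = pos.mean(axis=0)
            new_pos = (pos - cen) @ dr.T + cen + dt
            cand = scorer.score(new_pos)
            if cand[3] < total:
                pos = new_pos
                e_air, e_xl, e_clash, total = cand
                rot = dr @ rot
        # recover the final transform from the aligned coordinates
        final_trans = pos[0] - rot @ lig_pos0[0]
        pose = Pose.from_matrix(rot, final_trans)
        candidates.append(ScoredPose(pose=pose, e_air=e_air, e_xl=e_xl,
                                     e_clash=e_clash, total=total, trial_index=trial))
    stats["n_candidates"] = len(candidates)
    candidates.sort(key=ScoredPose.sort_key)
    # deterministic local polish: collapses every basin's members onto its
    # minimum so that clustering sees tight families instead of scatter
    if config.polish_top > 0 and config.polish_maxfev > 0:
        for cand in candidates[: config.polish_top]:
            _polish(cand, scorer, ligand, config)
        candidates.sort(key=ScoredPose.sort_key)

    accepted, rejected_sasds, accepted_sasds = [], [], []
    if restraints.crosslinks:
        base_grid = _receptor_base_grid(receptor, lig_radius, config.search_sasd_voxel)
        lig_radii = ligand.radii
        for cand in candidates:
            if len(accepted) >= config.n_keep:
                break
            pos = cand.pose.apply(ligand.positions)
            ann = _pose_crosslink_sasd(base_grid, receptor, pos, ligand, restraints,
                                       lig_radii, config.sasd_reject)
            stats["n_sasd_evaluated"] += 1
            cand.sasd_annotations = ann
            worst = max(ann.values()) if ann else 0.0
            if worst > config.sasd_reject:
                stats["n_sasd_rejected"] += 1
                if math.isfinite(worst):
                    rejected_sasds.append(worst)
                continue
            accepted_sasds.extend(v for v in ann.values() if math.isfinite(v))
            accepted.append(cand)
    else:
        accepted = candidates[: config.n_keep]
    if config.final_sasd_voxel and restraints.crosslinks and accepted:
        fine_grid = _receptor_base_grid(receptor, lig_radius, config.final_sasd_voxel)
        for cand in accepted[: config.final_sasd_top]:
            pos = cand.pose.apply(ligand.positions)
            cand.sasd_annotations = _pose_crosslink_sasd(
                fine_grid, receptor, pos, ligand, restraints, ligand.radii, math.inf)
    for rank, cand in enumerate(accepted, start=1):
        cand.rank = rank
    if accepted_sasds:
        stats["accepted_mean_sasd"] = float(np.mean(accepted_sasds))
    if rejected_sasds:
        stats["rejected_mean_sasd"] = float(np.mean(rejected_sasds))
    return accepted, stats


def _polish(cand: ScoredPose, scorer: _Scorer, ligand: StructureModel,
            config: DockingConfig) -> None:
    """Derivative-free (Powell) refinement of one pose, in place.

    Parameters are a rotation vector (about the posed ligand centroid) and a
    translation, both relative to the incoming pose; deterministic.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    base_pos = cand.pose.apply(ligand.positions)
    cen = base_pos.mean(axis=0)

    def objective(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        pos = (base_pos - cen) @ rot.T + cen + p[3:]
        return scorer.score(pos)[3]

    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"maxfev": config.polish_maxfev, "xtol": 1e-3, "ftol": 1e-4})
    if res.fun < cand.total:
        rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
        pos = (base_pos - cen) @ rot.T + cen + res.x[3:]
        full_rot = rot @ cand.pose.rotation_matrix
        trans = pos[0] - full_rot @ ligand.positions[0]
        cand.pose = Pose.from_matrix(full_rot, trans)
        cand.e_air, cand.e_xl, cand.e_clash, cand.total = scorer.score(pos)


def _receptor_base_grid(receptor: StructureModel, lig_radius: float, voxel: float):
    lo, hi = receptor.bounding_box()
    margin = lig_radius + 4.0
    return sasd_mod.build_grid(receptor, voxel=voxel,
                               bounds=(lo - margin, hi + margin))


def _pose_crosslink_sasd(
    base_grid, receptor: StructureModel, ligand_pos: np.ndarray,
    ligand: StructureModel, restraints: RestraintSet,
    lig_radii: np.ndarray, limit: float,
) -> dict:
    grid = sasd_mod.block_atoms(base_grid, ligand_pos, lig_radii)
    slack = 2.0 * grid.voxel * math.sqrt(3.0)
    out = {}
    for x in restraints.crosslinks:
        pa = receptor.atom_position(*x.atom_receptor)
        ib = ligand.atom_index(*x.atom_ligand)
        pb = ligand_pos[ib]
        res = sasd_mod.compute_sasd(grid, pa, pb, max_dist=limit + slack if math.isfinite(limit) else math.inf)
        out[(x.atom_receptor, x.atom_ligand)] = res.sasd
    return out


def filter_by_sasd(
    poses: Sequence[ScoredPose],
    receptor: StructureModel,
    ligand: StructureModel,
    crosslinks: RestraintSet | Sequence,
    limit: float = 35.0,
    voxel: float = 2.0,
) -> tuple[list[ScoredPose], list[ScoredPose], dict]:
    """Partition poses on observed-crosslink SASD.

    A pose is rejected iff any observed crosslink has SASD > ``limit``
    (unreachable endpoints count as above the limit).  Returns
    ``(accepted, rejected, stats)`` with mean SASD of both sets.
    """
    links = crosslinks.crosslinks if isinstance(crosslinks, RestraintSet) else list(crosslinks)
    rset = RestraintSet(airs=[], crosslinks=list(links))
    lig_centroid = ligand.positions.mean(axis=0)
    lig_radius = float(np.linalg.norm(ligand.positions - lig_centroid, axis=1).max())
    base_grid = _receptor_base_grid(receptor, lig_radius, voxel)
    accepted, rejected = [], []
    acc_vals, rej_vals = [], []
    for sp in poses:
        pos = sp.pose.apply(ligand.positions)
        ann = _pose_crosslink_sasd(base_grid, receptor, pos, ligand, rset,
                                   ligand.radii, math.inf)
        sp.sasd_annotations = ann
        finite = [v for v in ann.values() if math.isfinite(v)]
        if ann and (any(not math.isfinite(v) for v in ann.values()) or max(finite, default=0) > limit):
            rejected.append(sp)
            rej_vals.extend(finite)
        else:
            accepted.append(sp)
            acc_vals.extend(finite)
    stats = {
        "n_accepted": len(accepted),
        "n_rejected": len(rejected),
        "accepted_mean_sasd": float(np.mean(acc_vals)) if acc_vals else None,
        "rejected_mean_sasd": float(np.mean(rej_vals)) if rej_vals else None,
    }
    return accepted, rejected, stats


# ------------------------------------------------- in-silico species matching

_SIDE_CHAIN_ATOMS = {
    "GLY": [],
    "ALA": ["CB"],
    "SER": ["CB", "OG"],
    "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1", "CG2"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PRO": ["CB", "CG", "CD"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
}


def mutate_residue_in_silico(
    structure: StructureModel, chain: str, residue_number: int, new_name: str
) -> StructureModel:
    """Rename a residue, truncating the side chain to the atoms shared with
    the target residue type (no rotamer building).

    This is how histone sequence differences between species are matched
    before docking: the residue keeps its backbone and the largest common
    side-chain atom set and simply changes identity.
    """
    new_name = new_name.upper()
    if new_name not in _SIDE_CHAIN_ATOMS:
        raise ValueError(f"unknown residue type {new_name!r}")
    allowed = set(_SIDE_CHAIN_ATOMS[new_name]) | {"N", "CA", "C", "O", "OXT", "H", "HA"}
    res_mask = structure.select_mask(chain=chain, residue_number=residue_number)
    if not res_mask.any():
        raise KeyError(f"residue {chain}:{residue_number} not found")
    drop = res_mask & ~np.isin(structure.atom_names, list(allowed))
    out = structure.subset(~drop)
    out.residue_names[out.select_mask(chain=chain, residue_number=residue_number)] = new_name
    return out
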