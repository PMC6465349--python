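"""Self-contained toy systems with planted ground truth.

Every pipeline stage can be exercised without external downloads on a toy
complex: a pseudo-atom slab receptor carrying a concave "acidic groove"
(the desk-scale stand-in for the nucleosome disc face and its acidic
patch), and a helix-like ligand whose basic face binds into the groove (the
stand-in for the RING-domain arginine helix).  The generator plants the
bound pose, records the true interface on both sides, and synthesizes the
observables the real pipeline consumes: per-residue perturbation tables
with elevated interface values over half-normal background noise, fast
exchange titration series, and crosslinkable lysine pairs whose
planted-pose SASD falls inside a stated window plus decoys.

All generators are pure functions of (seed, parameters); the returned
manifest allows exact regeneration.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import sasd as sasd_mod
from .nmr_mapping import PerturbationTable
from .pose import Pose
from .restraints import CrosslinkRestraint, solvent_exposure
from .structure_io import StructureModel, merge

__all__ = [
    "ToyComplex",
    "make_toy_complex",
    "synthesize_perturbation_table",
    "synthesize_titration",
    "synthesize_crosslinks",
    "scramble_footprint",
    "bound_fraction",
]

LATTICE = 3.8  # A, receptor pseudo-residue spacing
LAYER_DZ = 3.5  # A, slab layer separation
CONTACT_CUTOFF = 5.0  # A, defines the true interface
CLASH_TOLERANCE = 0.4  # A, allowed overlap of united-atom radii
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_R_CA = 2.3  # A, backbone radius
HELIX_R_CB = 3.8  # A, side-chain pseudo-atom radius


@dataclasses.dataclass
class ToyComplex:
    """Receptor + ligand (ligand in its own local frame) with planted truth."""

    receptor: StructureModel
    ligand: StructureModel
    planted_pose: Pose
    true_interface_receptor: list[tuple[str, int]]
    true_interface_ligand: list[tuple[str, int]]
    ligand_actives: list[tuple[str, int]]  # mutagenesis-analog basic residues
    reporter_residues: list[tuple[str, int]]  # receptor residues with observable probes
    manifest: dict

    def ligand_placed(self) -> StructureModel:
        """Ligand transformed into the receptor frame at the planted pose."""
        return self.ligand.transformed(
            self.planted_pose.rotation_matrix, self.planted_pose.translation
        )

    def complex_model(self, pose: Pose | None = None) -> StructureModel:
        pose = pose or self.planted_pose
        return merge([self.receptor, self.ligand.transformed(pose.rotation_matrix, pose.translation)])

    def ligand_rmsd(self, pose: Pose) -> float:
        """RMSD of ligand atoms between a candidate pose and the planted pose."""
        a = self.planted_pose.apply(self.ligand.positions)
        b = pose.apply(self.ligand.positions)
        return float(np.sqrt(((a - b) ** 2).sum() / len(a)))


def _min_clearance(receptor: StructureModel, ligand_pos: np.ndarray, ligand_radii: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(receptor.positions)
    pairs = tree.query_ball_point(ligand_pos, r=8.0)
    best = math.inf
    for i, neigh in enumerate(pairs):
        if not neigh:
            continue
        d = np.linalg.norm(receptor.positions[neigh] - ligand_pos[i], axis=1)
        allowed = receptor.radii[neigh] + ligand_radii[i] - CLASH_TOLERANCE
        best = min(best, float(np.min(d - allowed)))
    return best


def make_toy_complex(
    seed: int = 0,
    nx: int = 13,
    ny: int = 13,
    n_ligand_res: int = 26,
    jitter: float = 0.2,
) -> ToyComplex:
    """Build a deterministic toy receptor/ligand pair with a planted pose.

    The receptor is an ``nx x ny x 3`` slab of single-atom pseudo-residues
    (chain A) with a three-column trench carved from the top layer; trench
    floor and wall residues are labelled GLU (the acidic groove) and two rim
    residues are LYS with an NZ probe atom.  The ligand (chain B) is an
    ideal helix of CA/CB pseudo-residues with two interface ARG residues
    (the mutagenesis-analog actives) and three LYS residues carrying NZ
    probes.  The planted pose drops the helix into the trench at the lowest
    clash-free height, so it is clash-free by construction.
    """
    rng = np.random.default_rng(seed)
    trench_cols = (5, 6, 7)
    wall_cols = (4, 8)
    layers_z = (0.0, -LAYER_DZ, -2 * LAYER_DZ)

    chains, nums, rnames, anames, elems, pos = [], [], [], [], [], []
    resnum = 0
    # rim lysines near the trench ends: their crosslinks to the ligand's
    # terminal lysines encode the binding orientation (a mid-helix link
    # would be blind to the end-to-end flip pseudo-symmetry of the groove)
    lys_sites = {(wall_cols[0] - 1, 2, 0), (wall_cols[1] + 1, ny - 3, 0)}
    for iz, z in enumerate(layers_z):
        for ix in range(nx):
            for iy in range(ny):
                if iz == 0 and ix in trench_cols:
                    continue  # trench
                resnum += 1
                p = np.array([ix * LATTICE, iy * LATTICE, z]) + rng.normal(0, jitter, 3)
                is_lys = (ix, iy, iz) in lys_sites
                if is_lys:
                    name = "LYS"
                elif (iz == 1 and ix in trench_cols) or (iz == 0 and ix in wall_cols):
                    name = "GLU"  # groove floor and walls: the acidic face
                else:
                    name = "ALA"
                chains.append("A"); nums.append(resnum); rnames.append(name)
                anames.append("CA"); elems.append("C"); pos.append(p)
                if is_lys:
                    chains.append("A"); nums.append(resnum); rnames.append(name)
                    anames.append("NZ"); elems.append("N")
                    pos.append(p + np.array([0.0, 0.0, 3.0]))
    receptor = StructureModel(
        chains, nums, rnames, anames, elems, np.asarray(pos),
        entity_labels={"A": "nucleosome"},
    )

    # ligand helix in its local frame: axis along +y, centred on the origin
    lchains, lnums, lrnames, lanames, lelems, lpos = [], [], [], [], [], []
    arg_residues = (10, 17)  # phases point toward the groove floor (-z)
    lys_residues = (2, n_ligand_res - 3)  # terminal probes, see lys_sites
    phi0 = math.radians(-90.0) - 10 * math.radians(HELIX_TWIST)
    for i in range(n_ligand_res):
        phi = phi0 + i * math.radians(HELIX_TWIST)
        y = (i - (n_ligand_res - 1) / 2.0) * HELIX_RISE
        radial = np.array([math.cos(phi), 0.0, math.sin(phi)])
        num = i + 1
        if i in arg_residues:
            name = "ARG"
        elif i in lys_residues:
            name = "LYS"
        else:
            name = "ALA"
        for aname, r, el in (("CA", HELIX_R_CA, "C"), ("CB", HELIX_R_CB, "C")):
            lchains.append("B"); lnums.append(num); lrnames.append(name)
            lanames.append(aname); lelems.append(el)
            lpos.append(radial * r + np.array([0.0, y, 0.0]))
        if i in lys_residues:
            lchains.append("B"); lnums.append(num); lrnames.append(name)
            lanames.append("NZ"); lelems.append("N")
            lpos.append(radial * (HELIX_R_CB + 1.5) + np.array([0.0, y, 0.0]))
    ligand = StructureModel(
        lchains, lnums, lrnames, lanames, lelems, np.asarray(lpos),
        entity_labels={"B": "E3"},
    )

    # plant the pose: drop the helix into the trench, raise until clash-free
    x_c = np.mean([c * LATTICE for c in trench_cols])
    y_c = (ny - 1) * LATTICE / 2.0
    z = -LAYER_DZ  # start at the trench floor, clearly clashing
    while True:
        t = np.array([x_c, y_c, z])
        if _min_clearance(receptor, ligand.positions + t, ligand.radii) >= 0.2:
            break
        z += 0.1
        if z > 20:  # pragma: no cover - geometry guard
            raise RuntimeError("failed to place toy ligand")
    planted = Pose.identity(ligand_id="B", receptor_id="A")
    planted = Pose(planted.quaternion, t, ligand_id="B", receptor_id="A")

    placed = ligand.positions + t
    from scipy.spatial import cKDTree

    rec_tree = cKDTree(receptor.positions)
    lig_tree = cKDTree(placed)
    rec_iface, lig_iface = set(), set()
    for i, neigh in enumerate(rec_tree.query_ball_point(placed, r=CONTACT_CUTOFF)):
        if neigh:
            lig_iface.add(("B", int(ligand.residue_numbers[i])))
            for j in neigh:
                rec_iface.add(("A", int(receptor.residue_numbers[j])))

    # observable probes: every solvent-exposed receptor residue
    exposure = solvent_exposure(receptor, side_chain_only=False)
    reporters = sorted([r for r, e in exposure.items() if e >= 0.05], key=lambda r: r[1])

    manifest = {
        "seed": seed, "nx": nx, "ny": ny, "n_ligand_res": n_ligand_res,
        "jitter": jitter, "planted_pose": planted.to_dict(),
        "n_receptor_atoms": receptor.n_atoms, "n_ligand_atoms": ligand.n_atoms,
    }
    return ToyComplex(
        receptor=receptor,
        ligand=ligand,
        planted_pose=planted,
        true_interface_receptor=sorted(rec_iface, key=lambda r: r[1]),
        true_interface_ligand=sorted(lig_iface, key=lambda r: r[1]),
        ligand_actives=[("B", r + 1) for r in arg_residues],
        reporter_residues=reporters,
        manifest=manifest,
    )


def synthesize_perturbation_table(
    complex_: ToyComplex,
    mu: float = 0.10,
    sigma: float = 0.02,
    rho: float = 0.0,
    seed: int = 0,
) -> PerturbationTable:
    """Per-residue CSP table over the receptor's observable residues.

    Interface reporters draw ``|N(mu, sigma)|``, background reporters
    ``|N(0, sigma)|``; ``ceil(rho * n_interface_reporters)`` background
    reporters are swapped to interface-level values, so ``rho`` is the
    false-positive fraction relative to the true footprint.  Values are in
    ppm; defaults put the effect at five noise SDs.
    """
    rng = np.random.default_rng(seed)
    iface = set(complex_.true_interface_receptor)
    reporters = list(complex_.reporter_residues)
    iface_reporters = [r for r in reporters if r in iface]
    background = [r for r in reporters if r not in iface]
    n_fp = int(np.ceil(rho * len(iface_reporters))) if rho > 0 else 0
    fp: set = set()
    if n_fp:
        fp_idx = rng.choice(len(background), size=min(n_fp, len(background)), replace=False)
        fp = {background[i] for i in fp_idx}
    rows = []
    for res in reporters:
        elevated = res in iface or res in fp
        val = abs(rng.normal(mu if elevated else 0.0, sigma))
        rows.append({"molecule": res[0], "residue_number": res[1], "value": val})
    frame = pd.DataFrame(rows)
    table = PerturbationTable(frame, kind="csp")
    table.truth = {  # type: ignore[attr-defined]
        "interface_reporters": iface_reporters,
        "false_positives": sorted(fp, key=lambda r: r[1]),
        "mu": mu, "sigma": sigma, "rho": rho, "seed": seed,
    }
    return table


def scramble_footprint(
    complex_: ToyComplex, seed: int = 0, min_distance: float = 20.0
) -> tuple[list[tuple[str, int]], CrosslinkRestraint]:
    """Negative-control restraint inputs: a wrong surface patch plus a decoy link.

    Picks a random exposed receptor residue at least ``min_distance`` from
    the true-interface centroid, takes it and its surface neighbours (8 A)
    as fake actives, and returns a crosslink between lysines on the wrong
    side of the planted window.  Restraints built from these should not
    recover the planted pose.
    """
    rng = np.random.default_rng(seed)
    rec = complex_.receptor
    iface_mask = np.zeros(rec.n_atoms, dtype=bool)
    for c, n in complex_.true_interface_receptor:
        iface_mask |= rec.select_mask(chain=c, residue_number=n)
    iface_centroid = rec.positions[iface_mask].mean(axis=0)
    candidates = [
        r for r in complex_.reporter_residues
        if np.linalg.norm(
            rec.positions[rec.select_mask(chain=r[0], residue_number=r[1])].mean(axis=0)
            - iface_centroid
        ) >= min_distance
    ]
    if not candidates:
        raise ValueError("no surface residue far enough from the interface")
    seedres = candidates[int(rng.integers(len(candidates)))]
    center = rec.positions[rec.select_mask(chain=seedres[0], residue_number=seedres[1])].mean(axis=0)
    fake = [
        r for r in complex_.reporter_residues
        if np.linalg.norm(
            rec.positions[rec.select_mask(chain=r[0], residue_number=r[1])].mean(axis=0)
            - center
        ) <= 8.0
    ]
    _, manifest = synthesize_crosslinks(complex_, seed=seed)
    violating = [c for c in manifest["candidates"] if not c["in_window"]]
    decoy = violating[int(rng.integers(len(violating)))]
    link = CrosslinkRestraint(
        atom_receptor=(decoy["receptor"][0], decoy["receptor"][1], "CA"),
        atom_ligand=(decoy["ligand"][0], decoy["ligand"][1], "CA"),
    )
    return fake, link


def bound_fraction(kd: float, receptor_conc: float, ligand_conc: float) -> float:
    """Exact two-state bound fraction of the receptor from the binding quadratic.

    For R + L <-> RL with dissociation constant ``kd`` (same units as the
    total concentrations), the complex concentration is the physical root of
    ``c^2 - (R + L + Kd) c + R L = 0``.
    """
    if receptor_conc <= 0:
        raise ValueError("receptor concentration must be positive")
    s = receptor_conc + ligand_conc + kd
    c = (s - math.sqrt(s * s - 4.0 * receptor_conc * ligand_conc)) / 2.0
    return c / receptor_conc


def synthesize_titration(
    delta_free: dict[tuple[str, int], tuple[float, float]],
    delta_bound: dict[tuple[str, int], tuple[float, float]],
    kd: float,
    receptor_conc: float,
    ligand_concs: list[float],
    noise: float = 0.0,
    seed: int = 0,
) -> list[dict[tuple[str, int], tuple[float, float]]]:
    """Fast-exchange titration series of observed (1H, X) shifts.

    Each titration point returns per-residue observed shifts
    ``delta_free + f_bound * (delta_bound - delta_free)`` with the bound
    fraction from :func:`bound_fraction` and optional Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    series = []
    for lig in ligand_concs:
        f = bound_fraction(kd, receptor_conc, lig) if lig > 0 else 0.0
        point = {}
        for res, (h0, x0) in delta_free.items():
            h1, x1 = delta_bound[res]
            h = h0 + f * (h1 - h0)
            x = x0 + f * (x1 - x0)
            if noise > 0:
                h += rng.normal(0, noise)
                x += rng.normal(0, noise)
            point[res] = (h, x)
        series.append(point)
    return series


def synthesize_crosslinks(
    complex_: ToyComplex,
    s_min: float = 5.0,
    s_max: float = 30.0,
    n_true: int = 1,
    n_decoys: int = 0,
    seed: int = 0,
    voxel: float = 1.0,
) -> tuple[list[CrosslinkRestraint], dict]:
    """Crosslink list from lysine pairs at the planted pose.

    True links are drawn (seeded) from inter-molecule lysine CA pairs whose
    planted-pose SASD lies in ``[s_min, s_max]``; decoys from pairs
    violating the window.  Returns the restraints plus a truth manifest
    with every candidate pair's SASD and its label.
    """
    rng = np.random.default_rng(seed)
    model = complex_.complex_model()
    grid = sasd_mod.build_grid(model, voxel=voxel)
    rec, lig = complex_.receptor, complex_.ligand_placed()
    rec_lys = [(c, int(n)) for (c, n, _i) in rec.residues()
               if np.any(rec.residue_mask((c, n, _i)) & (rec.residue_names == "LYS"))]
    lig_lys = [(c, int(n)) for (c, n, _i) in lig.residues()
               if np.any(lig.residue_mask((c, n, _i)) & (lig.residue_names == "LYS"))]
    candidates = []
    for ra in sorted(set(rec_lys), key=lambda r: r[1]):
        for rb in sorted(set(lig_lys), key=lambda r: r[1]):
            pa = model.atom_position(ra[0], ra[1], "CA")
            pb = model.atom_position(rb[0], rb[1], "CA")
            res = sasd_mod.compute_sasd(grid, pa, pb)
            candidates.append({"receptor": ra, "ligand": rb, "sasd": res.sasd,
                               "euclidean": res.euclidean,
                               "in_window": s_min <= res.sasd <= s_max})
    eligible = [c for c in candidates if c["in_window"]]
    violating = [c for c in candidates if not c["in_window"]]
    if n_true > len(eligible):
        raise ValueError(f"only {len(eligible)} lysine pairs inside the SASD window")
    chosen = [eligible[i] for i in sorted(rng.choice(len(eligible), size=n_true, replace=False))]
    decoys = [violating[i] for i in sorted(
        rng.choice(len(violating), size=min(n_decoys, len(violating)), replace=False))] \
        if n_decoys and violating else []
    links = [
        CrosslinkRestraint(
            atom_receptor=(c["receptor"][0], c["receptor"][1], "CA"),
            atom_ligand=(c["ligand"][0], c["ligand"][1], "CA"),
        )
        for c in chosen + decoys
    ]
    manifest = {
        "s_min": s_min, "s_max": s_max, "seed": seed,
        "candidates": candidates,
        "true_links": [(c["receptor"], c["ligand"]) for c in chosen],
        "decoys": [(c["receptor"], c["ligand"]) for c in decoys],
    }
    return links, manifest
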