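"""Ambiguous interface restraints (AIRs) and unambiguous crosslink bounds.

An AIR couples one experimentally implicated "active" residue on one
molecule to the set of actives plus solvent-exposed neighbouring "passive"
residues on the partner molecule.  The restraint acts on an effective
distance that aggregates all heavy-atom pairs with an r^-6 sum,

    d_eff = ( sum_ij d_ij^-6 )^(-1/6)  <=  min_ij d_ij,

so the restraint is satisfied as soon as the active residue approaches any
part of the allowed partner surface.  A crosslink restraint is a plain
upper bound on one Calpha-Calpha Euclidean distance (28 A for a BS3-bridged
lysine pair).  Both use a flat-bottom quadratic penalty: zero up to the
upper bound, k*(d - bound)^2 beyond it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import BACKBONE_ATOMS, StructureModel

__all__ = [
    "AmbiguousRestraint",
    "CrosslinkRestraint",
    "RestraintSet",
    "solvent_exposure",
    "find_passives",
    "define_airs",
    "effective_distance",
    "restraint_energy",
    "RestraintEvaluator",
]

ResidueRef = tuple[str, int]  # (chain_id, author residue number)

AIR_UPPER_BOUND = 2.0  # A, on the effective distance
AIR_FORCE_CONSTANT = 10.0  # arbitrary energy units / A^2
XL_UPPER_BOUND = 28.0  # A, Calpha-Calpha for a BS3 lysine-lysine link
XL_FORCE_CONSTANT = 10.0
PASSIVE_RSA_THRESHOLD = 0.15
PASSIVE_NEIGHBOR_CUTOFF = 6.5  # A, heavy-atom distance from any active


@dataclasses.dataclass(frozen=True)
class AmbiguousRestraint:
    active: ResidueRef
    active_molecule: str  # "receptor" or "ligand"
    partners: tuple[ResidueRef, ...]
    upper_bound: float = AIR_UPPER_BOUND
    force_constant: float = AIR_FORCE_CONSTANT

    def __post_init__(self):
        if not self.partners:
            raise ValueError("AIR partner set must be non-empty")
        if self.upper_bound <= 0:
            raise ValueError("upper bound must be positive")
        if self.active_molecule not in ("receptor", "ligand"):
            raise ValueError("active_molecule must be 'receptor' or 'ligand'")


@dataclasses.dataclass(frozen=True)
class CrosslinkRestraint:
    """Upper bound on one atom-pair distance; endpoints on opposite molecules."""

    atom_receptor: tuple[str, int, str]  # (chain, resnum, atom name)
    atom_ligand: tuple[str, int, str]
    upper_bound: float = XL_UPPER_BOUND
    force_constant: float = XL_FORCE_CONSTANT

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise ValueError("upper bound must be positive")


@dataclasses.dataclass
class RestraintSet:
    airs: list[AmbiguousRestraint] = dataclasses.field(default_factory=list)
    crosslinks: list[CrosslinkRestraint] = dataclasses.field(default_factory=list)
    random_exclusion_fraction: float = 0.0  # default OFF

    def __post_init__(self):
        if not 0 <= self.random_exclusion_fraction < 1:
            raise ValueError("exclusion fraction must be in [0, 1)")

    # -- JSON round trip so runs are auditable -----------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "random_exclusion_fraction": self.random_exclusion_fraction,
            "airs": [
                {
                    "active": list(a.active),
                    "active_molecule": a.active_molecule,
                    "partners": [list(p) for p in a.partners],
                    "upper_bound": a.upper_bound,
                    "force_constant": a.force_constant,
                }
                for a in self.airs
            ],
            "crosslinks": [
                {
                    "atom_receptor": list(x.atom_receptor),
                    "atom_ligand": list(x.atom_ligand),
                    "upper_bound": x.upper_bound,
                    "force_constant": x.force_constant,
                }
                for x in self.crosslinks
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RestraintSet":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            source = Path(source).read_text()
        data = json.loads(source)
        airs = [
            AmbiguousRestraint(
                active=(a["active"][0], int(a["active"][1])),
                active_molecule=a["active_molecule"],
                partners=tuple((p[0], int(p[1])) for p in a["partners"]),
                upper_bound=a["upper_bound"],
                force_constant=a["force_constant"],
            )
            for a in data["airs"]
        ]
        xls = [
            CrosslinkRestraint(
                atom_receptor=(x["atom_receptor"][0], int(x["atom_receptor"][1]), x["atom_receptor"][2]),
                atom_ligand=(x["atom_ligand"][0], int(x["atom_ligand"][1]), x["atom_ligand"][2]),
                upper_bound=x["upper_bound"],
                force_constant=x["force_constant"],
            )
            for x in data["crosslinks"]
        ]
        return cls(airs=airs, crosslinks=xls,
                   random_exclusion_fraction=data.get("random_exclusion_fraction", 0.0))


# ------------------------------------------------------------------ passives

def solvent_exposure(
    structure: StructureModel,
    probe: float = 1.4,
    side_chain_only: bool = True,
    point_number: int = 120,
) -> dict[ResidueRef, float]:
    """Per-residue fractional solvent accessibility via Shrake-Rupley.

    The per-atom areas come from biotite's `sasa` with this package's radius
    table; a residue's exposure is its (side-chain) SASA divided by the total
    isolated-atom sphere area of the same atoms, so 0 means fully buried and
    values of a few tens of percent indicate surface residues.  Residues
    without side-chain atoms (toy pseudo-residues, glycine) fall back to all
    atoms.
    """
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.positions.astype(np.float32)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.residue_numbers
    arr.res_name = structure.residue_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = np.array([e.upper() or "C" for e in structure.elements], dtype="U2")
    heavy = structure.heavy_mask()
    radii = structure.radii.astype(float)
    areas = struc.sasa(
        arr,
        probe_radius=probe,
        vdw_radii=radii,
        point_number=point_number,
        atom_filter=heavy,
        ignore_ions=False,
    )
    areas = np.nan_to_num(areas, nan=0.0)
    iso = 4.0 * np.pi * (radii + probe) ** 2
    out: dict[ResidueRef, float] = {}
    for key in structure.residues():
        rmask = structure.residue_mask(key) & heavy
        side = rmask & ~np.isin(structure.atom_names, list(BACKBONE_ATOMS))
        use = side if side.any() and side_chain_only else rmask
        denom = iso[use].sum()
        out[(key[0], key[1])] = float(areas[use].sum() / denom) if denom > 0 else 0.0
    return out


def find_passives(
    structure: StructureModel,
    actives: Sequence[ResidueRef],
    rsa_threshold: float = PASSIVE_RSA_THRESHOLD,
    neighbor_cutoff: float = PASSIVE_NEIGHBOR_CUTOFF,
) -> list[ResidueRef]:
    """Solvent-exposed residues with any heavy atom within the cutoff of an
    active residue's heavy atoms; actives themselves are excluded."""
    from scipy.spatial import cKDTree

    heavy = structure.heavy_mask()
    active_set = {(c, int(n)) for c, n in actives}
    active_mask = np.zeros(structure.n_atoms, dtype=bool)
    for c, n in active_set:
        active_mask |= structure.select_mask(chain=c, residue_number=n)
    active_mask &= heavy
    if not active_mask.any():
        return []
    tree = cKDTree(structure.positions[active_mask])
    exposure = solvent_exposure(structure)
    passives = []
    for key in structure.residues():
        ref = (key[0], key[1])
        if ref in active_set:
            continue
        if exposure.get(ref, 0.0) < rsa_threshold:
            continue
        rmask = structure.residue_mask(key) & heavy
        if not rmask.any():
            continue
        d, _ = tree.query(structure.positions[rmask], k=1)
        if np.min(d) <= neighbor_cutoff:
            passives.append(ref)
    return passives


def define_airs(
    receptor_actives: Sequence[ResidueRef],
    ligand_actives: Sequence[ResidueRef],
    receptor: StructureModel,
    ligand: StructureModel,
    rsa_threshold: float = PASSIVE_RSA_THRESHOLD,
    neighbor_cutoff: float = PASSIVE_NEIGHBOR_CUTOFF,
    crosslinks: Sequence[CrosslinkRestraint] = (),
    air_upper_bound: float = AIR_UPPER_BOUND,
) -> RestraintSet:
    """Build the AIR set: one restraint per active residue on either side,
    each paired with the actives plus passives of the opposite molecule.

    Passives approximate the "automatic" convention of data-driven docking:
    solvent-exposed surface neighbours of the actives.  When no passive
    exists the partner set degenerates to the actives alone.
    """
    receptor_actives = [(c, int(n)) for c, n in receptor_actives]
    ligand_actives = [(c, int(n)) for c, n in ligand_actives]
    if not receptor_actives or not ligand_actives:
        raise ValueError("need at least one active residue on each molecule")
    rec_pass = find_passives(receptor, receptor_actives, rsa_threshold, neighbor_cutoff)
    lig_pass = find_passives(ligand, ligand_actives, rsa_threshold, neighbor_cutoff)
    airs = [
        AmbiguousRestraint(active=a, active_molecule="receptor",
                           partners=tuple(ligand_actives + lig_pass),
                           upper_bound=air_upper_bound)
        for a in receptor_actives
    ] + [
        AmbiguousRestraint(active=a, active_molecule="ligand",
                           partners=tuple(receptor_actives + rec_pass),
                           upper_bound=air_upper_bound)
        for a in ligand_actives
    ]
    return RestraintSet(airs=airs, crosslinks=list(crosslinks))


# ----------------------------------------------------------------- evaluation

def _residue_heavy_indices(structure: StructureModel, ref: ResidueRef) -> np.ndarray:
    mask = structure.select_mask(chain=ref[0], residue_number=ref[1]) & structure.heavy_mask()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise KeyError(f"residue {ref} has no heavy atoms in structure")
    return idx


def _effective_from_d2(d2: np.ndarray) -> float:
    return float(np.sum(d2 ** -3) ** (-1.0 / 6.0))


def effective_distance(
    air: AmbiguousRestraint, receptor: StructureModel, ligand: StructureModel
) -> float:
    """r^-6-summed effective distance of one AIR on the current geometry."""
    if air.active_molecule == "receptor":
        own, other = receptor, ligand
    else:
        own, other = ligand, receptor
    a = own.positions[_residue_heavy_indices(own, air.active)]
    parts = [other.positions[_residue_heavy_indices(other, p)] for p in air.partners]
    b = np.concatenate(parts, axis=0)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    return _effective_from_d2(d2)


SOFT_SQUARE_SWITCH = 2.0  # A beyond the bound where the wall turns linear


def _flat_bottom(d: float, bound: float, k: float, switch: float = SOFT_SQUARE_SWITCH) -> float:
    """Soft-square penalty: flat to the bound, quadratic wall for ``switch``
    Angstrom, then a linear continuation (continuous in value and slope).

    The linear tail caps the force of restraints that are far from
    satisfiable, so a handful of false-positive restraints cannot drag the
    pose away from a basin where the consistent majority is satisfied.
    """
    if d <= bound:
        return 0.0
    x = d - bound
    if x <= switch:
        return k * x * x
    return k * switch * switch + 2.0 * k * switch * (x - switch)


def restraint_energy(
    restraints: RestraintSet,
    receptor: StructureModel,
    ligand: StructureModel,
    exclusion_seed: int | None = None,
) -> tuple[float, dict]:
    """Total flat-bottom restraint energy and per-restraint violations.

    With ``random_exclusion_fraction`` > 0, ``ceil(frac * n)`` AIRs are
    excluded by a seeded draw (reproducible); with the default fraction of 0
    the energy is fully deterministic.
    """
    airs = list(restraints.airs)
    included = np.arange(len(airs))
    if restraints.random_exclusion_fraction > 0 and airs:
        n_excl = int(np.ceil(restraints.random_exclusion_fraction * len(airs)))
        rng = np.random.default_rng(exclusion_seed)
        excluded = set(rng.choice(len(airs), size=n_excl, replace=False).tolist())
        included = np.array([i for i in range(len(airs)) if i not in excluded], dtype=int)
    violations = {"airs": [], "crosslinks": []}
    total = 0.0
    for i in included:
        air = airs[i]
        d = effective_distance(air, receptor, ligand)
        e = _flat_bottom(d, air.upper_bound, air.force_constant)
        total += e
        violations["airs"].append(
            {"active": air.active, "d_eff": d, "energy": e, "included": True}
        )
    for x in restraints.crosslinks:
        pa = receptor.atom_position(*x.atom_receptor)
        pb = ligand.atom_position(*x.atom_ligand)
        d = float(np.linalg.norm(pa - pb))
        e = _flat_bottom(d, x.upper_bound, x.force_constant)
        total += e
        violations["crosslinks"].append({"pair": (x.atom_receptor, x.atom_ligand), "d": d, "energy": e})
    return total, violations


class RestraintEvaluator:
    """Precomputed index form of a restraint set for fast repeated scoring.

    Caches, per AIR, the heavy-atom indices of the active residue and of the
    flattened partner set, split by which molecule moves; ``energy`` then
    only needs the transformed ligand coordinates.
    """

    def __init__(self, restraints: RestraintSet, receptor: StructureModel, ligand: StructureModel):
        self.restraints = restraints
        self.rec_pos = receptor.positions
        # flatten all AIR atom pairs into parallel index arrays; bincount on
        # the segment ids then gives every AIR's r^-6 sum in one shot
        rp, lp, seg = [], [], []
        bounds, ks = [], []
        for n_air, air in enumerate(restraints.airs):
            if air.active_molecule == "receptor":
                rec_idx = _residue_heavy_indices(receptor, air.active)
                lig_idx = np.concatenate(
                    [_residue_heavy_indices(ligand, p) for p in air.partners]
                )
            else:
                lig_idx = _residue_heavy_indices(ligand, air.active)
                rec_idx = np.concatenate(
                    [_residue_heavy_indices(receptor, p) for p in air.partners]
                )
            ri, li = np.meshgrid(rec_idx, lig_idx, indexing="ij")
            rp.append(ri.ravel())
            lp.append(li.ravel())
            seg.append(np.full(ri.size, n_air))
            bounds.append(air.upper_bound)
            ks.append(air.force_constant)
        self.n_airs = len(restraints.airs)
        if self.n_airs:
            self._rp = np.concatenate(rp)
            self._lp = np.concatenate(lp)
            self._seg = np.concatenate(seg)
            self._bounds = np.asarray(bounds)
            self._ks = np.asarray(ks)
            self._rec_pair_pos = self.rec_pos[self._rp]
        self._xl_terms = [
            (
                receptor.atom_index(*x.atom_receptor),
                ligand.atom_index(*x.atom_ligand),
                x.upper_bound,
                x.force_constant,
            )
            for x in restraints.crosslinks
        ]

    def effective_distances(self, ligand_pos: np.ndarray) -> np.ndarray:
        """Per-AIR effective distances at the given ligand coordinates."""
        if not self.n_airs:
            return np.empty(0)
        diff = self._rec_pair_pos - ligand_pos[self._lp]
        d2 = np.einsum("ij,ij->i", diff, diff)
        sums = np.bincount(self._seg, weights=d2 ** -3, minlength=self.n_airs)
        return sums ** (-1.0 / 6.0)

    def energy(self, ligand_pos: np.ndarray, air_mask: np.ndarray | None = None) -> tuple[float, float]:
        """(AIR energy, crosslink energy) at the given ligand coordinates."""
        e_air = 0.0
        if self.n_airs:
            d_eff = self.effective_distances(ligand_pos)
            x = d_eff - self._bounds
            quad = np.minimum(np.maximum(x, 0.0), SOFT_SQUARE_SWITCH)
            lin = np.maximum(x - SOFT_SQUARE_SWITCH, 0.0)
            e_per = self._ks * quad ** 2 + 2.0 * self._ks * SOFT_SQUARE_SWITCH * lin
            if air_mask is not None:
                e_per = e_per[air_mask]
            e_air = float(e_per.sum())
        e_xl = 0.0
        for ia, ib, bound, k in self._xl_terms:
            d = float(np.linalg.norm(self.rec_pos[ia] - ligand_pos[ib]))
            e_xl += _flat_bottom(d, bound, k)
        return e_air, e_xl
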