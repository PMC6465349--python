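"""Atomic structure container, PDB/mmCIF input-output, selection and superposition.

The pipeline operates on rigid bodies, so structures are stored as flat,
numpy-backed atom tables (:class:`StructureModel`) rather than hierarchical
objects.  Reading and writing of the standard formats is delegated to gemmi;
every atom is assigned a united-atom radius from a small embedded table at
read time so that accessibility grids and clash scoring treat experimental
structures and synthetic toy systems identically.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "UNITED_ATOM_RADII",
    "DEFAULT_RADIUS",
    "AtomRecord",
    "StructureModel",
    "read_structure",
    "write_structure",
    "superpose",
    "NumberingScheme",
    "get_scheme",
    "map_residue",
    "UnmappedResidueError",
]

# United-atom radii (Angstrom).  SASD is grid-dominated, so a coarse table
# suffices; values are a config item, not a fitted quantity.
UNITED_ATOM_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "ZN": 1.39,
}
DEFAULT_RADIUS = 1.70

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


def element_radius(element: str, warn_unknown: bool = False) -> float:
    el = element.strip().upper()
    if el in UNITED_ATOM_RADII:
        return UNITED_ATOM_RADII[el]
    if warn_unknown and el:
        warnings.warn(f"unknown element {el!r}; using default radius {DEFAULT_RADIUS} A")
    return DEFAULT_RADIUS


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """A single atom with author residue numbering and an assigned radius."""

    chain_id: str
    residue_number: int
    icode: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.element.strip().upper() != "H" and self.radius <= 0:
            raise ValueError("non-hydrogen atoms need a positive radius")


class StructureModel:
    """Flat atom table for one model, with chain-role labels.

    Parameters
    ----------
    chain_ids, residue_numbers, icodes, residue_names, atom_names, elements
        Per-atom identity fields (author numbering; insertion codes are part
        of residue identity).
    positions
        (n, 3) coordinates in Angstrom.
    radii
        Optional per-atom radii; assigned from the embedded table if omitted.
    model_id
        1-based model number.
    entity_labels
        chain_id -> molecule role ("H2A", "H2B", "H3", "H4", "DNA", "E3",
        "E2", "other").  Used to partition the complex into molecules.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        positions: np.ndarray,
        icodes: Sequence[str] | None = None,
        radii: Sequence[float] | None = None,
        model_id: int = 1,
        entity_labels: dict[str, str] | None = None,
    ):
        n = len(atom_names)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.icodes = (
            np.asarray(icodes, dtype=object)
            if icodes is not None
            else np.full(n, "", dtype=object)
        )
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if radii is None:
            self.radii = np.array([element_radius(e) for e in self.elements])
        else:
            self.radii = np.asarray(radii, dtype=float)
        self.model_id = int(model_id)
        self.entity_labels: dict[str, str] = dict(entity_labels or {})
        for field in (
            self.chain_ids,
            self.residue_numbers,
            self.icodes,
            self.residue_names,
            self.atom_names,
            self.elements,
            self.radii,
        ):
            if len(field) != n:
                raise ValueError("atom field length mismatch")
        for ch in self.entity_labels:
            if not np.any(self.chain_ids == ch):
                raise ValueError(f"labelled chain {ch!r} is empty")

    # ------------------------------------------------------------------ basics
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        chains = ",".join(sorted(set(self.chain_ids)))
        return f"<StructureModel model={self.model_id} atoms={self.n_atoms} chains={chains}>"

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            chain_id=self.chain_ids[i],
            residue_number=int(self.residue_numbers[i]),
            icode=self.icodes[i],
            residue_name=self.residue_names[i],
            atom_name=self.atom_names[i],
            element=self.elements[i],
            position=self.positions[i].copy(),
            radius=float(self.radii[i]),
        )

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.chain_ids.copy(),
            self.residue_numbers.copy(),
            self.residue_names.copy(),
            self.atom_names.copy(),
            self.elements.copy(),
            self.positions.copy(),
            icodes=self.icodes.copy(),
            radii=self.radii.copy(),
            model_id=self.model_id,
            entity_labels=dict(self.entity_labels),
        )

    def subset(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask)
        labels = {
            ch: role
            for ch, role in self.entity_labels.items()
            if np.any(self.chain_ids[mask] == ch)
        }
        return StructureModel(
            self.chain_ids[mask],
            self.residue_numbers[mask],
            self.residue_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.positions[mask],
            icodes=self.icodes[mask],
            radii=self.radii[mask],
            model_id=self.model_id,
            entity_labels=labels,
        )

    def select_mask(
        self,
        chain: str | None = None,
        residue_number: int | None = None,
        atom_name: str | None = None,
        icode: str | None = None,
    ) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_ids == chain
        if residue_number is not None:
            mask &= self.residue_numbers == residue_number
        if icode is not None:
            mask &= self.icodes == icode
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return mask

    def select(self, **kwargs) -> "StructureModel":
        return self.subset(self.select_mask(**kwargs))

    def atom_index(self, chain: str, residue_number: int, atom_name: str, icode: str = "") -> int:
        idx = np.flatnonzero(
            self.select_mask(
                chain=chain, residue_number=residue_number, atom_name=atom_name, icode=icode
            )
        )
        if len(idx) == 0:
            raise KeyError(f"atom {chain}:{residue_number}{icode}:{atom_name} not found")
        return int(idx[0])

    def atom_position(self, chain: str, residue_number: int, atom_name: str, icode: str = "") -> np.ndarray:
        return self.positions[self.atom_index(chain, residue_number, atom_name, icode)]

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_number, icode) keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for ch, num, ic in zip(self.chain_ids, self.residue_numbers, self.icodes):
            seen.setdefault((ch, int(num), ic), None)
        return list(seen)

    def residue_mask(self, key: tuple) -> np.ndarray:
        ch, num = key[0], key[1]
        ic = key[2] if len(key) > 2 else ""
        return self.select_mask(chain=ch, residue_number=int(num), icode=ic)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.strip().upper() != "H" for e in self.elements])

    def chain_roles(self) -> np.ndarray:
        """Per-atom molecule role; unlabelled chains map to 'other'."""
        return np.array(
            [self.entity_labels.get(ch, "other") for ch in self.chain_ids], dtype=object
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = self.copy()
        out.positions = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions.min(axis=0), self.positions.max(axis=0)

    def validate_unique_atoms(self) -> None:
        keys = set()
        for i in range(self.n_atoms):
            k = (self.chain_ids[i], int(self.residue_numbers[i]), self.icodes[i], self.atom_names[i])
            if k in keys:
                raise ValueError(f"duplicate atom identity {k}")
            keys.add(k)


def merge(models: Iterable[StructureModel], model_id: int | None = None) -> StructureModel:
    """Concatenate structures into one model; chain labels must not conflict."""
    models = list(models)
    labels: dict[str, str] = {}
    for m in models:
        for ch, role in m.entity_labels.items():
            if labels.get(ch, role) != role:
                raise ValueError(f"conflicting role for chain {ch!r}")
            labels[ch] = role
    return StructureModel(
        np.concatenate([m.chain_ids for m in models]),
        np.concatenate([m.residue_numbers for m in models]),
        np.concatenate([m.residue_names for m in models]),
        np.concatenate([m.atom_names for m in models]),
        np.concatenate([m.elements for m in models]),
        np.concatenate([m.positions for m in models]),
        icodes=np.concatenate([m.icodes for m in models]),
        radii=np.concatenate([m.radii for m in models]),
        model_id=model_id if model_id is not None else models[0].model_id,
        entity_labels=labels,
    )


# --------------------------------------------------------------------- file IO

def read_structure(
    path: str | Path,
    fmt: str = "auto",
    entity_labels: dict[str, str] | None = None,
) -> list[StructureModel]:
    """Read a PDB or mmCIF file into one :class:`StructureModel` per model.

    Alternate locations are reduced to the highest-occupancy conformer;
    hydrogens are retained; insertion codes are preserved as part of the
    residue identity.  Unknown elements get the default radius with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    models: list[StructureModel] = []
    for model in st:
        chains, nums, ics, rnames, anames, elems, pos = [], [], [], [], [], [], []
        best_occ: dict[tuple, int] = {}  # altloc resolution: highest occupancy wins
        occs: list[float] = []
        for chain in model:
            for res in chain:
                for atom in res:
                    key = (chain.name, res.seqid.num,
                           (res.seqid.icode or " ").strip(), atom.name)
                    occ = atom.occ if atom.occ is not None else 1.0
                    if key in best_occ:
                        i = best_occ[key]
                        if occ > occs[i]:
                            occs[i] = occ
                            pos[i] = [atom.pos.x, atom.pos.y, atom.pos.z]
                        continue
                    best_occ[key] = len(pos)
                    occs.append(occ)
                    chains.append(chain.name)
                    nums.append(res.seqid.num)
                    ics.append((res.seqid.icode or " ").strip())
                    rnames.append(res.name)
                    anames.append(atom.name)
                    el = atom.element.name if atom.element else ""
                    elems.append(el)
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
        radii = [element_radius(e, warn_unknown=True) for e in elems]
        models.append(
            StructureModel(
                chains, nums, rnames, anames, elems, np.asarray(pos, dtype=float),
                icodes=ics, radii=radii,
                model_id=int(model.num) if str(model.num).isdigit() else len(models) + 1,
                entity_labels=entity_labels,
            )
        )
    if not models:
        raise ValueError(f"{path.name}: no models found")
    return models


def write_structure(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or more models as a (multi-model) PDB or mmCIF file.

    Format is chosen from the suffix (.cif/.mmcif vs anything else -> PDB).
    """
    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    st.name = "ringdock"
    for i, m in enumerate(models):
        gm = gemmi.Model(i + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple, gemmi.Residue] = {}
        for j in range(m.n_atoms):
            ch = m.chain_ids[j]
            if ch not in chain_map:
                chain_map[ch] = gemmi.Chain(ch)
            rkey = (ch, int(m.residue_numbers[j]), m.icodes[j])
            if rkey not in res_map:
                res = gemmi.Residue()
                res.name = m.residue_names[j]
                res.seqid = gemmi.SeqId(int(m.residue_numbers[j]), m.icodes[j] or " ")
                chain_map[ch].add_residue(res)
                res_map[rkey] = chain_map[ch][-1]
            atom = gemmi.Atom()
            atom.name = m.atom_names[j]
            atom.element = gemmi.Element(m.elements[j] or "X")
            atom.pos = gemmi.Position(*m.positions[j])
            atom.occ = 1.0
            res_map[rkey].add_atom(atom)
        for chain in chain_map.values():
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ----------------------------------------------------------------- superposition

def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.

    Raises
    ------
    ValueError
        For fewer than 3 point pairs or (near-)collinear sets, where the
        rotation is not uniquely determined.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - mc, ref - rc
    # collinearity check: second singular value of either centred set ~ 0
    for pts in (a, b):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise ValueError("degenerate (collinear) coordinate set")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    diff = mob @ rot.T + trans - ref
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return rot, trans, rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum() / len(a)))


# ------------------------------------------------------- histone numbering maps

class UnmappedResidueError(KeyError):
    """Residue falls outside the alignment domain of a numbering map."""


@dataclasses.dataclass(frozen=True)
class NumberingScheme:
    """Author-numbering convention of one histone in one species.

    ``species`` is Dm (*D. melanogaster*), Xl (*X. laevis*) or Hs (human).
    Conversions go through offsets to the human convention, derived from the
    canonical-core pairwise alignments of the mature histone sequences.
    """

    species: str
    histone: str

    _SPECIES = ("Dm", "Xl", "Hs")
    _HISTONES = ("H2A", "H2B", "H3", "H4")

    def __post_init__(self):
        if self.species not in self._SPECIES:
            raise ValueError(f"species must be one of {self._SPECIES}")
        if self.histone not in self._HISTONES:
            raise ValueError(f"histone must be one of {self._HISTONES}")


# (species, histone) -> (offset_to_Hs, valid author-number range in that species).
# The core alignments are gap-free, so each map is a single offset over the
# structured core.  Anchors: fly H2A E60/D89/E91 are the human acidic-patch
# triad E61/D90/E92 (offset +1); fly and frog H2B E110 is human E113, K105 is
# human K108 (offset +3); H3/H4 cores align without offset.
_OFFSET_TO_HS: dict[tuple[str, str], tuple[int, tuple[int, int]]] = {
    ("Dm", "H2A"): (1, (4, 123)),
    ("Xl", "H2A"): (0, (4, 128)),
    ("Hs", "H2A"): (0, (1, 129)),
    ("Dm", "H2B"): (3, (3, 122)),
    ("Xl", "H2B"): (3, (3, 122)),
    ("Hs", "H2B"): (0, (1, 125)),
    ("Dm", "H3"): (0, (1, 135)),
    ("Xl", "H3"): (0, (1, 135)),
    ("Hs", "H3"): (0, (1, 135)),
    ("Dm", "H4"): (0, (1, 102)),
    ("Xl", "H4"): (0, (1, 102)),
    ("Hs", "H4"): (0, (1, 102)),
}


def get_scheme(species: str, histone: str) -> NumberingScheme:
    return NumberingScheme(species, histone)


def map_residue(
    residue: tuple[str, int],
    from_scheme: NumberingScheme,
    to_scheme: NumberingScheme,
) -> tuple[str, int]:
    """Convert a (histone, author_number) residue between species conventions.

    Identity when the schemes are equal; raises :class:`UnmappedResidueError`
    for residues outside the alignment domain (tail residues absent in the
    target species) rather than passing numbers through silently.
    """
    histone, number = residue
    if histone != from_scheme.histone or histone != to_scheme.histone:
        raise ValueError("residue histone does not match the schemes")
    if from_scheme == to_scheme:
        return (histone, number)
    off_a, dom_a = _OFFSET_TO_HS[(from_scheme.species, histone)]
    off_b, dom_b = _OFFSET_TO_HS[(to_scheme.species, histone)]
    if not (dom_a[0] <= number <= dom_a[1]):
        raise UnmappedResidueError(
            f"{histone} {number} outside {from_scheme.species} alignment domain {dom_a}"
        )
    hs_number = number + off_a
    target = hs_number - off_b
    if not (dom_b[0] <= target <= dom_b[1]):
        raise UnmappedResidueError(
            f"{histone} {number} ({from_scheme.species}) has no counterpart in "
            f"{to_scheme.species} (maps to {target}, domain {dom_b})"
        )
    return (histone, target)
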