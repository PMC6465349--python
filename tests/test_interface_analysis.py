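"""Hydrogen bonds, catalytic geometry, crosslink reports, conserved contacts."""

import numpy as np
import pytest

from ringdock import interface_analysis as ia
from ringdock.restraints import CrosslinkRestraint
from ringdock.structure_io import StructureModel


def arg_glu_pair(distance, with_hydrogen=False, linear=True):
    """A guanidinium NH1 donor facing a carboxylate OE1 acceptor."""
    chains = ["E", "E", "A", "A"]
    nums = [63, 63, 60, 60]
    names = ["CZ", "NH1", "CD", "OE1"]
    rnames = ["ARG", "ARG", "GLU", "GLU"]
    elems = ["C", "N", "C", "O"]
    pos = [[-1.3, 0.0, 0.0], [0.0, 0.0, 0.0],
           [distance + 1.2, 0.0, 0.0], [distance, 0.0, 0.0]]
    if with_hydrogen:
        chains.append("E"); nums.append(63); names.append("HH11")
        rnames.append("ARG"); elems.append("H")
        if linear:
            pos.append([1.0, 0.0, 0.0])
        else:
            pos.append([0.0, 1.0, 0.0])  # points away from the acceptor
    return StructureModel(chains, nums, rnames, names, elems,
                          np.asarray(pos, dtype=float),
                          entity_labels={"E": "E3", "A": "H2A"})


class TestHydrogenBonds:
    def test_distant_molecules_no_bonds(self):
        model = arg_glu_pair(15.0)
        assert ia.hydrogen_bonds(model, ["E"], ["A"]) == []

    def test_arg_glu_salt_bridge_detected(self):
        model = arg_glu_pair(2.9)
        bonds = ia.hydrogen_bonds(model, ["E"], ["A"])
        assert len(bonds) == 1
        b = bonds[0]
        assert b.donor == ("E", 63, "NH1")
        assert b.acceptor == ("A", 60, "OE1")
        assert b.distance == pytest.approx(2.9)
        assert b.angle is None  # no hydrogens present

    def test_angle_criterion_applied_only_with_hydrogens(self):
        linear = arg_glu_pair(2.9, with_hydrogen=True, linear=True)
        bent = arg_glu_pair(2.9, with_hydrogen=True, linear=False)
        assert len(ia.hydrogen_bonds(linear, ["E"], ["A"])) == 1
        assert ia.hydrogen_bonds(bent, ["E"], ["A"]) == []

    def test_backbone_donor_and_acceptor_recognized(self):
        model = StructureModel(
            ["E", "A"], [1, 2], ["GLY", "GLY"], ["N", "O"], ["N", "O"],
            np.array([[0.0, 0, 0], [3.0, 0, 0]]),
            entity_labels={"E": "E3", "A": "H2A"},
        )
        bonds = ia.hydrogen_bonds(model, ["E"], ["A"])
        assert [(b.donor[2], b.acceptor[2]) for b in bonds] == [("N", "O")]


def ternary_toy(sg_to_k15, sg_to_k120, sg_to_k125):
    """E2 catalytic cysteine plus three candidate lysine NZ atoms."""
    chains = ["E", "C", "D", "D"]
    nums = [85, 15, 120, 125]
    rnames = ["CYS", "LYS", "LYS", "LYS"]
    names = ["SG", "NZ", "NZ", "NZ"]
    elems = ["S", "N", "N", "N"]
    pos = [[0.0, 0.0, 0.0], [sg_to_k15, 0.0, 0.0],
           [0.0, sg_to_k120, 0.0], [0.0, 0.0, sg_to_k125]]
    return StructureModel(chains, nums, rnames, names, elems,
                          np.asarray(pos, dtype=float),
                          entity_labels={"E": "E2", "C": "H2A", "D": "H2B"})


class TestCatalyticGeometry:
    def test_coincident_atoms_give_zero(self):
        model = ternary_toy(0.0, 5.0, 6.0)
        geom = ia.catalytic_geometry([model], "E", [("C", 15)])
        assert geom.ensemble_min(("C", 15)) == 0.0

    def test_planted_distances_recovered_exactly(self):
        model = ternary_toy(4.2, 15.7, 14.8)
        geom = ia.catalytic_geometry(
            [model], "E", [("C", 15), ("D", 120), ("D", 125)])
        assert geom.ensemble_min(("C", 15)) == pytest.approx(4.2, abs=1e-6)
        assert geom.ensemble_min(("D", 120)) == pytest.approx(15.7, abs=1e-6)
        assert geom.ensemble_min(("D", 125)) == pytest.approx(14.8, abs=1e-6)

    def test_ensemble_min_not_above_mean(self):
        models = [ternary_toy(4.2 + i, 15.7, 14.8) for i in range(5)]
        geom = ia.catalytic_geometry(models, "E", [("C", 15)])
        assert geom.ensemble_min(("C", 15)) <= geom.ensemble_mean(("C", 15))
        assert geom.ensemble_min(("C", 15)) == pytest.approx(4.2)

    def test_missing_side_chain_falls_back_to_calpha_with_flag(self):
        model = StructureModel(
            ["E", "C"], [85, 13], ["CYS", "LYS"], ["SG", "CA"], ["S", "C"],
            np.array([[0.0, 0, 0], [7.0, 0, 0]]),
            entity_labels={"E": "E2", "C": "H2A"},
        )
        geom = ia.catalytic_geometry([model], "E", [("C", 13)])
        entry = geom.per_model[0][("C", 13)]
        assert entry["endpoint"] == "CA"
        assert entry["flagged"] is True


class TestCrosslinkCompatibility:
    def test_empty_observed_list_gives_empty_report(self, toy):
        report = ia.crosslink_compatibility([toy.complex_model()], [])
        assert report["observed"] == []
        assert report["satisfied_fraction"] is None

    def test_satisfied_and_violated_links_partitioned(self, toy, toy_links):
        links, manifest = toy_links
        # one true link (inside the window) plus one decoy built from a
        # violating candidate
        violating = [c for c in manifest["candidates"] if not c["in_window"]][0]
        decoy = CrosslinkRestraint(
            atom_receptor=(violating["receptor"][0], violating["receptor"][1], "CA"),
            atom_ligand=(violating["ligand"][0], violating["ligand"][1], "CA"),
        )
        report = ia.crosslink_compatibility(
            [toy.complex_model()], list(links) + [decoy], max_sasd=30.0, voxel=2.0)
        flags = [o["satisfied"] for o in report["observed"]]
        assert flags == [True, False]
        assert report["satisfied_fraction"] == pytest.approx(0.5)

    def test_unresolvable_endpoint_flagged_not_scored(self, toy):
        ghost = CrosslinkRestraint(atom_receptor=("A", 42, "CA"),
                                   atom_ligand=("B", 999, "CA"))
        report = ia.crosslink_compatibility([toy.complex_model()], [ghost], voxel=2.0)
        assert report["observed"][0]["flagged_unresolvable"] is True


class TestConservedContacts:
    def base_complex(self, rng, jitter=0.0):
        n = 8
        rec_pos = np.column_stack([np.arange(n) * 3.0, np.zeros(n), np.zeros(n)])
        lig_pos = rec_pos + [0.0, 4.0, 0.0]
        pos = np.vstack([rec_pos, lig_pos]) + rng.normal(0, jitter, (2 * n, 3))
        return StructureModel(
            ["E"] * n + ["U"] * n, list(range(1, n + 1)) * 2,
            ["ALA"] * 2 * n, ["CA"] * 2 * n, ["C"] * 2 * n, pos,
            entity_labels={"E": "E3", "U": "E2"},
        )

    def test_single_member_all_contacts_fraction_one(self, rng):
        model = self.base_complex(rng)
        result = ia.conserved_contacts([model], ["E"], ["U"])
        assert result.contacts
        assert set(result.contacts.values()) == {1.0}

    def test_conserved_pairs_retained_random_extras_dropped(self, rng):
        members = [self.base_complex(rng, jitter=0.15) for _ in range(10)]
        # one member gets an extra ligand atom creating a one-off contact
        extra = members[0]
        new = StructureModel(
            list(extra.chain_ids) + ["U"],
            list(extra.residue_numbers) + [99],
            list(extra.residue_names) + ["ALA"],
            list(extra.atom_names) + ["CA"],
            list(extra.elements) + ["C"],
            np.vstack([extra.positions, [[21.0, -4.0, 0.0]]]),
            entity_labels=extra.entity_labels,
        )
        members[0] = new
        result = ia.conserved_contacts(members, ["E"], ["U"],
                                       conservation_fraction=0.8)
        retained = result.retained()
        assert (("E", 8), ("U", 99)) not in retained  # present once only
        assert (("E", 3), ("U", 3)) in retained

    def test_threshold_limits_union_and_intersection(self, rng):
        members = [self.base_complex(rng, jitter=0.4) for _ in range(6)]
        union = ia.conserved_contacts(members, ["E"], ["U"],
                                      conservation_fraction=1e-9)
        inter = ia.conserved_contacts(members, ["E"], ["U"],
                                      conservation_fraction=1.0)
        assert set(inter.retained()) <= set(union.retained())
        assert len(union.retained()) == len(union.contacts)

    def test_pair_restraints_emitted(self, rng):
        model = self.base_complex(rng)
        result = ia.conserved_contacts([model], ["E"], ["U"])
        restraints = result.to_pair_restraints(upper_bound=5.0)
        assert restraints
        assert all(r["upper_bound"] == 5.0 for r in restraints)

    def test_residue_maps_translate_numbering(self, rng):
        model = self.base_complex(rng)
        shifted = StructureModel(
            model.chain_ids, model.residue_numbers + 100, model.residue_names,
            model.atom_names, model.elements, model.positions,
            entity_labels=model.entity_labels,
        )
        rmap = {("E", n + 100): ("E", n) for n in range(1, 9)}
        rmap.update({("U", n + 100): ("U", n) for n in range(1, 9)})
        both = ia.conserved_contacts(
            [model, shifted], ["E"], ["U"],
            residue_maps=[None, rmap], conservation_fraction=1.0)
        assert both.retained()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ia.conserved_contacts([], ["E"], ["U"])
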