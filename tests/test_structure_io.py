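"""Structure container, PDB/mmCIF round trips, superposition, numbering maps."""

import numpy as np
import pytest

from ringdock import structure_io as sio


def _quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion-eigenvalue method."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    sxx = mob.T @ ref
    sxy = sxx
    k = np.array([
        [sxy[0, 0] + sxy[1, 1] + sxy[2, 2], sxy[1, 2] - sxy[2, 1],
         sxy[2, 0] - sxy[0, 2], sxy[0, 1] - sxy[1, 0]],
        [sxy[1, 2] - sxy[2, 1], sxy[0, 0] - sxy[1, 1] - sxy[2, 2],
         sxy[0, 1] + sxy[1, 0], sxy[2, 0] + sxy[0, 2]],
        [sxy[2, 0] - sxy[0, 2], sxy[0, 1] + sxy[1, 0],
         -sxy[0, 0] + sxy[1, 1] - sxy[2, 2], sxy[1, 2] + sxy[2, 1]],
        [sxy[0, 1] - sxy[1, 0], sxy[2, 0] + sxy[0, 2],
         sxy[1, 2] + sxy[2, 1], -sxy[0, 0] - sxy[1, 1] + sxy[2, 2]],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = ((mob ** 2).sum() + (ref ** 2).sum() - 2.0 * lam) / len(mob)
    return float(np.sqrt(max(msd, 0.0)))


def _random_model(rng, n=50):
    return sio.StructureModel(
        chain_ids=["A"] * n,
        residue_numbers=list(range(1, n + 1)),
        residue_names=["ALA"] * n,
        atom_names=["CA"] * n,
        elements=["C"] * n,
        positions=rng.normal(0, 10, (n, 3)),
    )


class TestReadWrite:
    def test_minimal_single_atom_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A  12      11.000  22.000  33.000  1.00  0.00"
            "           C\nEND\n"
        )
        models = sio.read_structure(path)
        assert len(models) == 1
        m = models[0]
        assert m.n_atoms == 1
        atom = m.atom(0)
        assert atom.chain_id == "A"
        assert atom.residue_number == 12
        assert atom.atom_name == "CA"
        assert atom.element == "C"
        assert atom.radius == pytest.approx(1.70)
        np.testing.assert_allclose(atom.position, [11.0, 22.0, 33.0])

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        model = _random_model(rng)
        path = tmp_path / "model.pdb"
        sio.write_structure(model, path)
        back = sio.read_structure(path)[0]
        assert back.n_atoms == model.n_atoms
        np.testing.assert_allclose(back.positions, model.positions, atol=1e-3)
        assert list(back.atom_names) == list(model.atom_names)
        assert list(back.residue_numbers) == list(model.residue_numbers)

    def test_mmcif_round_trip(self, tmp_path, rng):
        model = _random_model(rng, n=20)
        path = tmp_path / "model.cif"
        sio.write_structure(model, path)
        back = sio.read_structure(path, fmt="mmcif")[0]
        np.testing.assert_allclose(back.positions, model.positions, atol=1e-3)

    def test_multi_model_file(self, tmp_path, rng):
        models = []
        base = _random_model(rng, n=30)
        for i in range(10):
            shifted = base.copy()
            shifted.positions = base.positions + i
            shifted.model_id = i + 1
            models.append(shifted)
        path = tmp_path / "ensemble.pdb"
        sio.write_structure(models, path)
        back = sio.read_structure(path)
        assert len(back) == 10
        assert len({m.n_atoms for m in back}) == 1

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sio.read_structure(tmp_path / "nope.pdb")

    def test_unknown_element_gets_default_radius_with_warning(self, tmp_path):
        path = tmp_path / "odd.pdb"
        path.write_text(
            "ATOM      1  X1  UNK A   1       0.000   0.000   0.000  1.00  0.00"
            "            \nEND\n"
        )
        with pytest.warns(UserWarning, match="unknown element|radius"):
            m = sio.read_structure(path)[0]
        assert m.radii[0] == pytest.approx(sio.DEFAULT_RADIUS)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.30  0.00"
            "           C\n"
            "ATOM      2  CA BSER A   1       5.000   0.000   0.000  0.70  0.00"
            "           C\nEND\n"
        )
        m = sio.read_structure(path)[0]
        assert m.n_atoms == 1
        assert m.positions[0, 0] == pytest.approx(5.0)


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        rot, trans, rmsd = sio.superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        rot, trans, rmsd = sio.superpose(pts + [5.0, 0.0, 0.0], pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(trans, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_agrees_with_quaternion_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(50):
            ref = rng.normal(0, 5, (20, 3))
            rot = Rotation.random(random_state=rng).as_matrix()
            mob = ref @ rot.T + rng.normal(0, 0.5, (20, 3)) + rng.normal(0, 10, 3)
            _, _, rmsd = sio.superpose(mob, ref)
            assert rmsd == pytest.approx(_quaternion_superpose_rmsd(mob, ref), abs=1e-6)

    def test_invariant_under_prerotation_of_mobile(self, rng):
        from scipy.spatial.transform import Rotation

        ref = rng.normal(0, 5, (15, 3))
        mob = ref + rng.normal(0, 0.3, (15, 3))
        _, _, rmsd0 = sio.superpose(mob, ref)
        for seed in range(5):
            r = Rotation.random(random_state=seed).as_matrix()
            _, _, rmsd = sio.superpose(mob @ r.T + [3.0, -7.0, 1.0], ref)
            assert rmsd == pytest.approx(rmsd0, abs=1e-8)

    def test_transform_reproduces_rmsd(self, rng):
        ref = rng.normal(0, 5, (12, 3))
        mob = ref + rng.normal(0, 0.4, (12, 3))
        rot, trans, rmsd = sio.superpose(mob, ref)
        moved = mob @ rot.T + trans
        assert sio.rmsd_between(moved, ref) == pytest.approx(rmsd, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ])
    def test_degenerate_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            sio.superpose(bad, bad + 1.0)


class TestNumbering:
    def test_fly_h2b_e110_is_human_e113(self):
        dm = sio.get_scheme("Dm", "H2B")
        hs = sio.get_scheme("Hs", "H2B")
        assert sio.map_residue(("H2B", 110), dm, hs) == ("H2B", 113)

    def test_fly_acidic_patch_triad_maps_to_human(self):
        dm = sio.get_scheme("Dm", "H2A")
        hs = sio.get_scheme("Hs", "H2A")
        # fly E60/D89/E91 are the human arginine-anchor triad E61/D90/E92
        assert sio.map_residue(("H2A", 60), dm, hs) == ("H2A", 61)
        assert sio.map_residue(("H2A", 89), dm, hs) == ("H2A", 90)
        assert sio.map_residue(("H2A", 91), dm, hs) == ("H2A", 92)

    def test_identity_on_same_scheme(self):
        hs = sio.get_scheme("Hs", "H2A")
        assert sio.map_residue(("H2A", 15), hs, hs) == ("H2A", 15)

    @pytest.mark.parametrize("species,histone", [
        ("Dm", "H2A"), ("Dm", "H2B"), ("Xl", "H2B"), ("Xl", "H2A"),
    ])
    def test_maps_are_mutually_inverse(self, species, histone):
        a = sio.get_scheme(species, histone)
        b = sio.get_scheme("Hs", histone)
        for num in range(10, 100, 7):
            try:
                there = sio.map_residue((histone, num), a, b)
            except sio.UnmappedResidueError:
                continue
            assert sio.map_residue(there, b, a) == (histone, num)

    def test_out_of_domain_raises_not_passes_through(self):
        dm = sio.get_scheme("Dm", "H2A")
        hs = sio.get_scheme("Hs", "H2A")
        with pytest.raises(sio.UnmappedResidueError):
            sio.map_residue(("H2A", 200), dm, hs)


class TestModelContainer:
    def test_duplicate_atom_identity_rejected(self):
        m = sio.StructureModel(
            ["A", "A"], [1, 1], ["ALA", "ALA"], ["CA", "CA"], ["C", "C"],
            np.zeros((2, 3)),
        )
        with pytest.raises(ValueError, match="duplicate"):
            m.validate_unique_atoms()

    def test_labelled_chain_must_be_nonempty(self):
        with pytest.raises(ValueError, match="empty"):
            sio.StructureModel(
                ["A"], [1], ["ALA"], ["CA"], ["C"], np.zeros((1, 3)),
                entity_labels={"B": "E3"},
            )

    def test_selection_and_transform(self, rng):
        m = _random_model(rng, n=10)
        sel = m.select(chain="A", residue_number=3)
        assert sel.n_atoms == 1
        rot = np.eye(3)
        moved = m.transformed(rot, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(moved.positions, m.positions + [1, 2, 3])
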