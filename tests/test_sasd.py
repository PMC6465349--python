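"""Accessibility grid construction and surface-distance pathfinding."""

import math

import numpy as np
import pytest

from ringdock import sasd
from ringdock.structure_io import StructureModel


def atoms_at(positions, element="C", chain="A", names=None):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    return StructureModel(
        chain_ids=[chain] * n,
        residue_numbers=list(range(1, n + 1)),
        residue_names=["ALA"] * n,
        atom_names=names or ["CA"] * n,
        elements=[element] * n,
        positions=positions,
    )


def scipy_shortest_path(grid, a_idx, b_idx):
    """Exhaustive oracle: Bellman-Ford over the full voxel graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import bellman_ford

    nx, ny, nz = grid.mask.shape
    ids = -np.ones(grid.mask.shape, dtype=int)
    acc = np.argwhere(grid.mask)
    ids[tuple(acc.T)] = np.arange(len(acc))
    rows, cols, vals = [], [], []
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3)]
    for off in offsets:
        d = off - 1
        if not d.any():
            continue
        cost = np.linalg.norm(d) * grid.voxel
        for i, vox in enumerate(acc):
            nb = vox + d
            if np.any(nb < 0) or np.any(nb >= [nx, ny, nz]):
                continue
            j = ids[tuple(nb)]
            if j >= 0:
                rows.append(i)
                cols.append(j)
                vals.append(cost)
    graph = coo_matrix((vals, (rows, cols)), shape=(len(acc), len(acc)))
    start = ids[tuple(a_idx)]
    dist = bellman_ford(graph, directed=True, indices=start)
    return float(dist[ids[tuple(b_idx)]])


class TestBuildGrid:
    def test_empty_structure_all_accessible(self):
        grid = sasd.build_grid(None, voxel=1.0, bounds=(np.zeros(3), np.full(3, 5.0)))
        assert grid.mask.all()

    def test_single_atom_blocking_radius(self):
        model = atoms_at([[0.0, 0.0, 0.0]])
        grid = sasd.build_grid(model, voxel=0.5, probe=1.4)
        centers = np.argwhere(np.ones(grid.mask.shape))
        pts = grid.center_of(centers)
        d = np.linalg.norm(pts, axis=1)
        blocked = ~grid.mask[tuple(centers.T)]
        # blocked iff within r_atom + probe = 1.7 + 1.4 = 3.1 A
        np.testing.assert_array_equal(blocked, d < 3.1)

    def test_blocked_volume_matches_analytic_sphere(self):
        model = atoms_at([[0.0, 0.0, 0.0]])
        grid = sasd.build_grid(model, voxel=0.5, probe=1.4)
        blocked = (~grid.mask).sum() * grid.voxel ** 3
        analytic = 4.0 / 3.0 * math.pi * 3.1 ** 3
        assert blocked == pytest.approx(analytic, rel=0.10)

    def test_probe_monotonicity(self):
        model = atoms_at([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        small = sasd.build_grid(model, voxel=1.0, probe=1.0)
        large = sasd.build_grid(model, voxel=1.0, probe=1.8)
        assert (~small.mask & large.mask).sum() == 0  # blocked set only grows

    @pytest.mark.parametrize("voxel", [0.3, 2.5])
    def test_voxel_range_enforced(self, voxel):
        with pytest.raises(ValueError):
            sasd.build_grid(atoms_at([[0, 0, 0]]), voxel=voxel)

    def test_boundary_voxels_accessible_with_default_padding(self):
        model = atoms_at([[0.0, 0.0, 0.0]])
        grid = sasd.build_grid(model, voxel=1.0)
        assert grid.mask[0].all() and grid.mask[-1].all()
        assert grid.mask[:, 0].all() and grid.mask[:, :, 0].all()


class TestComputeSasd:
    def test_unobstructed_equals_euclidean(self):
        model = atoms_at([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        grid = sasd.build_grid(model, voxel=1.0)
        res = sasd.compute_sasd(grid, model.positions[0], model.positions[1])
        assert res.euclidean == pytest.approx(12.0)
        assert res.sasd == pytest.approx(12.0, abs=2.5)

    def test_symmetry(self):
        model = atoms_at([[0.0, 0.0, 0.0], [9.0, 3.0, 1.0]])
        grid = sasd.build_grid(model, voxel=1.0)
        ab = sasd.compute_sasd(grid, model.positions[0], model.positions[1])
        ba = sasd.compute_sasd(grid, model.positions[1], model.positions[0])
        assert ab.sasd == pytest.approx(ba.sasd, abs=1e-12)

    def test_wall_detour_matches_exhaustive_oracle(self):
        # two endpoints on opposite sides of a blocking wall
        wall = [[x, y, 0.0] for x in np.arange(-10, 10.5, 1.5)
                for y in np.arange(-10, 10.5, 1.5)]
        endpoints = [[0.0, 0.0, -6.0], [0.0, 0.0, 6.0]]
        model = atoms_at(wall + endpoints)
        grid = sasd.build_grid(model.subset(np.arange(len(wall))), voxel=2.0, padding=6.0)
        pa, pb = np.array(endpoints[0]), np.array(endpoints[1])
        va, vb = grid.nearest_accessible(pa), grid.nearest_accessible(pb)
        mine = sasd._dijkstra(grid, va, [vb])[0]
        oracle = scipy_shortest_path(grid, va, vb)
        assert mine == pytest.approx(oracle, abs=1e-9)
        res = sasd.compute_sasd(grid, pa, pb)
        assert res.sasd > res.euclidean + 2.0  # the wall forces a detour

    def test_oracle_equivalence_on_random_grids(self):
        # uniform-cost search equals Bellman-Ford on randomly blocked grids
        rng = np.random.default_rng(99)
        for trial in range(100):
            shape = tuple(rng.integers(5, 9, 3))
            grid = sasd.AccessibilityGrid(
                origin=np.zeros(3), voxel=1.0,
                mask=rng.random(shape) > 0.35, probe=1.4, padding=0.0,
            )
            acc = np.argwhere(grid.mask)
            if len(acc) < 2:
                continue
            a, b = acc[rng.integers(len(acc))], acc[rng.integers(len(acc))]
            mine = sasd._dijkstra(grid, a, [b])[0]
            oracle = scipy_shortest_path(grid, a, b)
            if math.isinf(oracle):
                assert math.isinf(mine)
            else:
                assert mine == pytest.approx(oracle, abs=1e-9)

    def test_lower_bound_property_on_random_pairs(self, rng):
        # SASD >= Euclidean - 2*voxel*sqrt(3) on many random configurations
        model_rng = np.random.default_rng(7)
        slack = 2.0 * 1.0 * math.sqrt(3.0)
        checked = 0
        for _ in range(20):
            pts = model_rng.uniform(0, 25, (40, 3))
            model = atoms_at(pts)
            grid = sasd.build_grid(model, voxel=1.0)
            for _ in range(50):
                i, j = model_rng.integers(0, 40, 2)
                if i == j:
                    continue
                res = sasd.compute_sasd(grid, pts[i], pts[j])
                if math.isfinite(res.sasd):
                    assert res.sasd >= res.euclidean - slack
                    checked += 1
        assert checked >= 500

    def test_refinement_never_lengthens_unobstructed_paths_much(self):
        model = atoms_at([[0.0, 0.0, 0.0], [10.0, 4.0, 2.0]])
        coarse = sasd.build_grid(model, voxel=2.0)
        fine = sasd.build_grid(model, voxel=1.0)
        s_coarse = sasd.compute_sasd(coarse, model.positions[0], model.positions[1]).sasd
        s_fine = sasd.compute_sasd(fine, model.positions[0], model.positions[1]).sasd
        assert s_fine <= s_coarse + 1.0 * math.sqrt(3.0)

    def test_buried_endpoint_is_unreachable_not_an_error(self):
        # a tight cage of atoms around the endpoint blocks every voxel near it
        cage = [[x, y, z] for x in (-3.0, 0.0, 3.0) for y in (-3.0, 0.0, 3.0)
                for z in (-3.0, 0.0, 3.0)]
        model = atoms_at(cage)
        grid = sasd.build_grid(model, voxel=1.0, probe=1.4)
        res = sasd.compute_sasd(grid, np.zeros(3), np.array([20.0, 0.0, 0.0]))
        assert not res.reachable
        assert math.isinf(res.sasd)


class TestPredictCrosslinks:
    def test_no_intermolecular_lysines_empty(self):
        model = atoms_at([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        assert sasd.predict_crosslinks(model) == []

    def test_planted_pairs_filtered_by_bound(self):
        # three lysine pairs across two molecules at increasing separation
        chains = ["A"] * 3 + ["B"] * 3
        pos = [[0, 0, 0], [0, 20, 0], [0, 40, 0],
               [10, 0, 0], [25, 20, 0], [40, 40, 0]]
        model = StructureModel(
            chains, [1, 2, 3, 1, 2, 3], ["LYS"] * 6, ["CA"] * 6, ["C"] * 6,
            np.asarray(pos, dtype=float),
            entity_labels={"A": "nucleosome", "B": "E3"},
        )
        found = sasd.predict_crosslinks(model, max_sasd=30.0)
        pairs = {(r["pair"][0][2], r["pair"][1][2]) for r in found}
        assert (1, 1) in pairs  # 10 A apart
        assert (2, 2) in pairs  # 25 A apart
        assert all(not (a == 3 and b == 3) for a, b in pairs)  # 40 A excluded

    def test_sorted_by_mean_sasd(self, toy, toy_links):
        found = sasd.predict_crosslinks(toy.complex_model(), max_sasd=30.0)
        means = [r["mean_sasd"] for r in found]
        assert means == sorted(means)
        # the generator's in-window candidate pairs are recovered
        _, manifest = toy_links
        expected = {(c["receptor"], c["ligand"]) for c in manifest["candidates"]
                    if c["in_window"]}
        got = {((r["pair"][0][1], r["pair"][0][2]), (r["pair"][1][1], r["pair"][1][2]))
               for r in found}
        got = {((a_ch, a_num), (b_ch, b_num)) for ((a_ch, a_num), (b_ch, b_num)) in got}
        assert {((a[0], a[1]), (b[0], b[1])) for a, b in expected} <= got
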