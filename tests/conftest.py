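import numpy as np
import pytest

from ringdock import synthetic_data as sd


@pytest.fixture(scope="session")
def toy():
    """One deterministic toy complex shared across the suite."""
    return sd.make_toy_complex(seed=1)


@pytest.fixture(scope="session")
def toy_links(toy):
    links, manifest = sd.synthesize_crosslinks(toy, seed=1)
    return links, manifest


@pytest.fixture(scope="session")
def toy_restraints(toy, toy_links):
    """Restraint set built from the classified synthetic footprint (rho=0.1)."""
    from ringdock.nmr_mapping import classify_perturbations
    from ringdock.restraints import define_airs

    links, _ = toy_links
    table = sd.synthesize_perturbation_table(toy, rho=0.1, seed=2)
    actives = classify_perturbations(table).significant("two_sd")
    return define_airs(actives, toy.ligand_actives, toy.receptor, toy.ligand,
                       crosslinks=links, air_upper_bound=5.0)


@pytest.fixture(scope="session")
def small_dock_run(toy, toy_restraints):
    """A reduced docking run reused by docking/clustering/pipeline tests."""
    from ringdock import docking as dk

    cfg = dk.DockingConfig(n_trials=120, n_keep=60, seed=5, final_sasd_voxel=None)
    poses, stats = dk.generate_poses(toy.receptor, toy.ligand, toy_restraints, cfg)
    return poses, stats, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
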