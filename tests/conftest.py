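import pytest

from rnapose import synthetic_data as sd
from rnapose.io_formats import RnaModel, RnaModelSet


@pytest.fixture(scope="session")
def helix20():
    return sd.make_idealized_helix(20, seed=0)[0]


@pytest.fixture(scope="session")
def helix_ensemble(helix20):
    spec = sd.EnsembleSpec(n_residues=20, n_models=5, rotation_sd=6.0,
                           translation_sd=0.25, seed=3)
    ens = sd.perturb_ensemble(helix20, spec)
    return RnaModelSet([helix20] + [RnaModel(m.model_id + 1, m.residues)
                                    for m in ens.models])


@pytest.fixture(scope="session")
def series5():
    return sd.make_congeneric_series(5, seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced planted scenario for unit-level pipeline tests."""
    scenario = sd.PlantedScenario(n_ligands=8, poses_per_ligand=60,
                                  fraction_out_of_range=0.125, seed=7)
    ref = sd.make_idealized_helix(40, seed=7)[0]
    series, scaffold_map = sd.make_congeneric_series(scenario.n_ligands,
                                                     seed=7)
    poses, affinities, truth = sd.plant_pose_set(ref, series, scenario)
    return {"scenario": scenario, "ref": ref, "series": series,
            "scaffold_map": scaffold_map, "poses": poses,
            "affinities": affinities, "truth": truth}


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(rng.normal(size=3))
    shift = rng.normal(scale=10.0, size=3)
    return rot, shift


def transform_model(model: RnaModel, rot, shift) -> RnaModel:
    from rnapose.io_formats import Residue

    return RnaModel(model.model_id, [
        Residue(r.index, r.name, list(r.atom_names), list(r.elements),
                rot.apply(r.coords) + shift)
        for r in model.residues])
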