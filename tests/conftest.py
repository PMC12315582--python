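import numpy as np
import pytest

import qmetric as qm


@pytest.fixture(scope="session")
def isolated_atom_model() -> qm.AtomicModel:
    """One oxygen atom far from any grid boundary."""
    rec = qm.AtomRecord(
        serial=1, name="O", element="O", chain="A", res_name="HOH",
        res_seq=1, coord=np.array([5.0, 5.0, 5.0]),
    )
    return qm.AtomicModel(atoms=[rec], entry_id="isolated")


@pytest.fixture(scope="session")
def ideal_map(isolated_atom_model) -> qm.DensityMap:
    """Noise-free sigma=0.6 A Gaussian peak on a 0.25 A grid."""
    return qm.simulate_map(isolated_atom_model, 0.0, voxel=0.25, margin=4.0)


@pytest.fixture(scope="session")
def helix_scored():
    """Toy helix, a rendered noisy map, and its Q-scores (shared, read-only)."""
    model = qm.make_toy_model(6, kind="helix", seed=2)
    b_true = np.linspace(0.0, 150.0, len(model.atoms))
    dmap = qm.simulate_map(model, b_true, voxel=0.5, noise_rms=0.05, seed=3)
    qres = qm.qscore_model(dmap, model)
    return model, dmap, qres


@pytest.fixture(scope="session")
def synthetic_archive() -> qm.ArchiveTable:
    """Default-condition synthetic archive (n=10,000, seeded)."""
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return qm.simulate_archive(qm.ArchiveSimSpec(n=10_000, seed=1))


@pytest.fixture(scope="session")
def archive_bundle(synthetic_archive) -> qm.RegressionBundle:
    return qm.fit_archive(synthetic_archive)
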