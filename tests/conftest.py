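import numpy as np
import pytest

import spincharge as sc


@pytest.fixture(scope="session")
def template():
    return sc.build_template()


@pytest.fixture(scope="session")
def heme_layout(template):
    return sc.build_layout(template.composition())


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 default-generator frames; enough for wiring/shape tests."""
    return sc.generate_dataset(sc.GeneratorParams(n_frames=12, seed=5))


@pytest.fixture(scope="session")
def small_model(tiny_dataset):
    """Quickly trained model (B=15) shared by prediction/persistence tests."""
    spec = sc.FeaturizerSpec.symmetry_functions(
        tiny_dataset.structures[0].composition()
    )
    return sc.train_all(
        tiny_dataset, spec, sc.ForestConfig(n_trees=15, m_spec=5, seed=2)
    )


def random_structure(rng, n_atoms=None, elements=("H", "C", "N", "O", "Fe")):
    """Random well-separated structure for property tests."""
    n = n_atoms or rng.integers(3, 11)
    while True:
        coords = rng.uniform(-4.0, 4.0, size=(int(n), 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.5:
            break
    els = tuple(rng.choice(elements, size=int(n)))
    return sc.Structure(els, coords, frame_id=0)
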