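import numpy as np
import pytest

from wskreg import (MethodParams, PointCloud, RigidTransform, SceneConfig,
                    generate_scene, make_registration_fixture)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation from a QR decomposition."""
    Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def random_transform(rng, max_translation: float = 5.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng),
                          rng.uniform(-max_translation, max_translation, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform(0, 10, (200, 3)))


@pytest.fixture(scope="session")
def small_scene():
    """A sparse quarter-size plot: fast enough for per-test feature work."""
    cfg = SceneConfig(plot_size=(15.0, 15.0), trees_per_hectare=400,
                      tree_height=16.0, branches_per_tree=3, seed=7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced registration fixture shared by pipeline-level tests."""
    cfg = SceneConfig(plot_size=(18.0, 18.0), trees_per_hectare=430,
                      row_spacing=4.5, tree_spacing=3.6,
                      tree_height=16.0, branches_per_tree=4, seed=11)
    return make_registration_fixture(cfg, max_rotation_deg=10.0, max_translation=3.0)


@pytest.fixture
def default_params():
    return MethodParams()
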