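import numpy as np
import pytest

from lvmotion.synthetic import WorldConfig, make_world


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic study shared across tests: 2.5 s of frames,
    six calibration frames, 2000 shell points."""
    cfg = WorldConfig(
        duration_s=2.5,
        n_cal_frames=6,
        cal_duration_s=1.0,
        shell_points=2000,
    )
    return make_world(cfg, seed=7)


def random_rigid(rng, max_angle_deg=180.0, max_trans=50.0):
    from scipy.spatial.transform import Rotation

    from lvmotion.geometry import HomogeneousTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(angle * axis).as_matrix()
    m[:3, 3] = rng.uniform(-max_trans, max_trans, 3)
    return HomogeneousTransform(m, from_space="a", to_space="b")
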