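import numpy as np
import pytest

import megjoint as mj
from megjoint.simulate import make_noise_cov


@pytest.fixture(scope="session")
def mesh_ico1():
    return mj.build_template_space(1)


@pytest.fixture(scope="session")
def mesh_ico2():
    return mj.build_template_space(2)


@pytest.fixture(scope="session")
def sensors():
    return mj.helmet_sensors(64)


@pytest.fixture(scope="session")
def leadfield_ico2(mesh_ico2, sensors):
    return mj.build_leadfield(mesh_ico2, sensors)


@pytest.fixture(scope="session")
def noise_cov():
    return make_noise_cov(64, seed=0)


@pytest.fixture(scope="session")
def metric_ico1(mesh_ico1):
    return mj.ground_metric(mesh_ico1)


@pytest.fixture(scope="session")
def small_experiment():
    """Three noisy subjects on the ico2 template (default jitters, SNR 2)."""
    cfg = mj.ExperimentConfig(subdivisions=2)
    return mj.simulate_experiment(3, config=cfg, master_seed=7)
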