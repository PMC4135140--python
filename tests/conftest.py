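import numpy as np
import pytest

from otosim import build_scene
from otosim import fem, procedures


@pytest.fixture(scope="session")
def scene():
    """Default synthetic middle-ear scene (shared, treated as read-only)."""
    return build_scene()


@pytest.fixture(scope="session")
def settings():
    return fem.SolverSettings()


@pytest.fixture(scope="session")
def crimp_pair(scene, settings):
    """Paired scripted crimp runs: single tool vs identical script with the
    blocking rod against the incus long process."""
    traj = procedures.make_crimp_trajectory(scene, seed=1)
    block = procedures.make_blocking_trajectory(scene, traj)
    single = procedures.run_stapedioplasty(scene, traj, None, settings, seed=1)
    dual = procedures.run_stapedioplasty(scene, traj, block, settings, seed=1)
    return single, dual


@pytest.fixture(scope="session")
def stapedotomy_report(settings):
    """Straight scripted drill plunge through the footplate at the target."""
    sc = build_scene()
    traj = procedures.make_plunge_trajectory(sc)
    return procedures.run_stapedotomy(sc, traj, settings, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
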