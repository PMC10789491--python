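import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cryptsim import initialize_world, make_fixture, mini_config  # noqa: E402
from cryptsim.scenarios import (branch, run_burn_in, run_cdk1, run_fu5,  # noqa: E402
                                run_homeostasis, run_stem_ablation)

ACCEPTANCE_SEEDS = (1, 2, 3)

_cache: dict = {}


def _burned(seed):
    key = ("burn", seed)
    if key not in _cache:
        _cache[key] = run_burn_in(seed)
    return branch(_cache[key])


@pytest.fixture(scope="session")
def homeostasis_runs():
    key = "homeo"
    if key not in _cache:
        _cache[key] = [run_homeostasis(s, world=_burned(s))
                       for s in ACCEPTANCE_SEEDS]
    return _cache[key]


@pytest.fixture(scope="session")
def ablation_runs():
    key = "ablation"
    if key not in _cache:
        _cache[key] = [run_stem_ablation(s, world=_burned(s))
                       for s in ACCEPTANCE_SEEDS]
    return _cache[key]


@pytest.fixture(scope="session")
def cdk1_run():
    if "cdk1" not in _cache:
        _cache["cdk1"] = run_cdk1(1, world=_burned(1))
    return _cache["cdk1"]


@pytest.fixture(scope="session")
def fu_runs():
    if "fu" not in _cache:
        _cache["fu"] = {dose: run_fu5(1, dose, world=_burned(1))
                        for dose in (50.0, 20.0)}
    return _cache["fu"]


@pytest.fixture()
def mini_world():
    return make_fixture("mini_crypt", seed=3)


@pytest.fixture()
def checkerboard():
    return make_fixture("checkerboard_niche", seed=0)


@pytest.fixture()
def overlap_pair():
    return make_fixture("overlap_pair", seed=0)
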