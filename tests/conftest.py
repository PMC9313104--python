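import pytest

from ppiface.pose_filter import cavity_center
from ppiface.synthetic_fixtures import FixtureSpec, build_ensemble, make_receptor


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def scaffold(spec):
    return make_receptor(spec)


@pytest.fixture(scope="session")
def ensemble(spec):
    """(scaffold, models, plan) for the default 3x15 synthetic ensemble."""
    return build_ensemble(spec)


@pytest.fixture(scope="session")
def cavity(scaffold, ensemble):
    _, models, _ = ensemble
    return cavity_center(models[0], scaffold.planted_segments)
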