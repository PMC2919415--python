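import pytest

from ccsbuild.synthetic import FixtureSpec, make_unit


@pytest.fixture(scope="session")
def globule():
    return make_unit(FixtureSpec(seed=1, n_residues=100, shape="globule"))


@pytest.fixture(scope="session")
def dumbbell():
    return make_unit(FixtureSpec(seed=2, n_residues=120, shape="dumbbell"))


@pytest.fixture(scope="session")
def trilobe():
    return make_unit(FixtureSpec(seed=3, n_residues=120, shape="trilobe"))
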