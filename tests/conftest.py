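import pytest

from odmcda import FixtureSpec, generate_cda_fixture, generate_odm_fixture


@pytest.fixture
def small_study():
    """A deterministic 3-form synthetic study."""
    return generate_odm_fixture(FixtureSpec(seed=11, n_forms=3))


@pytest.fixture
def cda_doc():
    """A deterministic synthetic clinical document (with raw tree)."""
    return generate_cda_fixture(FixtureSpec(seed=11))


def odm_specs(n, start=0, **overrides):
    return [FixtureSpec(seed=start + i, **overrides) for i in range(n)]


@pytest.fixture
def study_family():
    """Callable producing n seeded studies."""

    def make(n, **overrides):
        return [generate_odm_fixture(s) for s in odm_specs(n, **overrides)]

    return make


@pytest.fixture
def cda_family():
    """Callable producing n seeded clinical documents."""

    def make(n, **overrides):
        return [generate_cda_fixture(s) for s in odm_specs(n, **overrides)]

    return make
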