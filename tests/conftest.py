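import pytest
from hypothesis import settings

from oncovis.schema import VariantStore
from oncovis import synth

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def store() -> VariantStore:
    s = VariantStore()
    s.initialize()
    return s


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """The canonical single-record release, generated once per session."""
    out = tmp_path_factory.mktemp("we")
    return synth.generate_worked_example(out)


@pytest.fixture(scope="session")
def we_store(worked_example):
    """A store with the worked example fully ingested and mapped."""
    s = VariantStore()
    s.initialize()
    reports = synth.integrate_release(s, worked_example)
    assert all(not r.skipped for r in reports.values())
    return s


@pytest.fixture(scope="session")
def small_release(tmp_path_factory):
    """A modest seeded three-dialect release for mapping/staging tests."""
    out = tmp_path_factory.mktemp("synth")
    cfg = synth.GeneratorConfig(seed=7, n_variants=60)
    return synth.generate_source_release(cfg, out)
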