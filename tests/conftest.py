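import pytest

from beescreen import pipeline


@pytest.fixture(scope="session")
def run():
    """The bundled three-surfactant example study."""
    return pipeline.builtin_run()


@pytest.fixture(scope="session")
def default_reports(run):
    return {r.chemical_id: r for r in pipeline.run_default_mode(run)}


@pytest.fixture(scope="session")
def empirical_reports(run):
    return {r.chemical_id: r for r in pipeline.run_empirical_mode(run)}
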