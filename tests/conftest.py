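import pytest

from metabokg.integrate import build_graph
from metabokg.source_io import FixtureSpec, generate_fixture
from metabokg.synthetic import glucokinase_example


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Seed-42 synthetic source directory plus its ground truth."""
    out = tmp_path_factory.mktemp("fixture42")
    truth = generate_fixture(FixtureSpec(seed=42), out)
    return out, truth


@pytest.fixture(scope="session")
def built(fixture_dir):
    """Graph built from the seed-42 fixture, with merge report and log."""
    src, truth = fixture_dir
    graph, report, log = build_graph(src)
    return graph, report, log, truth


@pytest.fixture()
def glucokinase_graph():
    return glucokinase_example()
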