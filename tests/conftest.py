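import pytest

from fusionbench.core import Panel
from fusionbench.io import build_fixtures, load_fixture_cohort


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    build_fixtures(d)
    return d


@pytest.fixture(scope="session")
def sarcoma_cohort(fixture_dir):
    return load_fixture_cohort(fixture_dir, Panel.SARCOMA)


@pytest.fixture(scope="session")
def lung_cohort(fixture_dir):
    return load_fixture_cohort(fixture_dir, Panel.LUNG)
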