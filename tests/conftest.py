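import pytest

from telmap import generate_study, small_config, write_fixture


@pytest.fixture(scope="session")
def small_study():
    """One scaled-down synthetic study shared by read-only tests."""
    return generate_study(small_config(seed=7))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_study):
    d = tmp_path_factory.mktemp("study_fixture")
    write_fixture(small_study, d)
    return d
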