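import pytest

from striatnet.synthetic_data import default_study_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """Small study-shaped bundle shared by read-only tests."""
    return default_study_fixture(scale=0.05, seed=11)


@pytest.fixture(scope="session")
def study_bundle_dir(tmp_path_factory):
    """The same bundle written to disk for file-driven tests."""
    out = tmp_path_factory.mktemp("bundle")
    fx = default_study_fixture(scale=0.05, seed=11, out_dir=out)
    return fx, out
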