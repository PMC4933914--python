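from pathlib import Path

import pytest

from cnvscreen.simulate import default_config, simulate_cohort, tiny_config

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def tiny_sim():
    """40-sample, 2-chromosome cohort with planted artifacts."""
    return simulate_cohort(tiny_config(FIXTURE_SEED))


@pytest.fixture(scope="session")
def default_sim():
    """The full study cohort: 2 populations x (200 males + 200 females)."""
    return simulate_cohort(default_config(1))


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    """Directory of the committed tiny fixture files."""
    assert FIXTURE_DIR.exists(), "committed fixture missing"
    return FIXTURE_DIR
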