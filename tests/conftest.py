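import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles importable

from kdrevo.domain import default_catalog
from kdrevo.study import simulate_study
from kdrevo.pipeline import analyze
from kdrevo.simulate import roundtrip_config, simulate


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def compact_dataset():
    """Compact multi-population simulation with a planted crossover child."""
    return simulate(roundtrip_config(recombination=True), seed=1)


@pytest.fixture(scope="session")
def compact_result(compact_dataset):
    ds = compact_dataset
    return analyze(ds.sequences, ds.aspcr, ds.metadata)


@pytest.fixture(scope="session")
def study_dataset():
    """Full 26-collection study-condition dataset (synthetic stand-in)."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def study_result(study_dataset):
    ds = study_dataset
    return analyze(ds.sequences, ds.aspcr, ds.metadata)
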