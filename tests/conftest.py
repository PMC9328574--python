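import numpy as np
import pytest

from dnnprs.fixtures import make_fixtures
from dnnprs.simulate import GeneSpec, SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk fixture file set (PLINK, VCF, regions, phenotype, spec)."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = make_fixtures(out, seed=42)
    return paths


@pytest.fixture(scope="session")
def null_dataset():
    """A single null gene, continuous outcome: pure noise phenotype."""
    spec = SimulationSpec(
        n=500,
        genes=(GeneSpec("nullA", 20, "null"),),
        switches=(0, 0, 0, 0),
        seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def signal_dataset():
    """One strongly predictive additive gene plus one null gene."""
    spec = SimulationSpec(
        n=2000,
        genes=(GeneSpec("sig", 20, "linear90"), GeneSpec("nul", 20, "null")),
        signal_fraction=0.3,
        seed=13,
    )
    return simulate_dataset(spec)
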