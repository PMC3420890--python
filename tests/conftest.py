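import numpy as np
import pytest

from plasmidseq.model import AnalysisConfig, Feature, PlasmidRef
from plasmidseq.simulate import DEFAULT_ADAPTER

BASES = np.array(list("ACGT"))


def random_sequence(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def toy_ref() -> PlasmidRef:
    """A 300-nt random circular plasmid with one sense feature."""
    return PlasmidRef(
        name="pToy",
        sequence=random_sequence(300, seed=42),
        features=(Feature("toyCDS", 0, 30, "sense", "CDS"),),
    )


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig(adapter=DEFAULT_ADAPTER)
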