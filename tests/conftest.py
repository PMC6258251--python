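import numpy as np
import pytest

from replichrom.genome import Anchor, AnchorSet, DyadMap, GenomeSpec
from replichrom import synthetic


@pytest.fixture(scope="session")
def genome_300kb() -> GenomeSpec:
    return GenomeSpec.single(300_000)


@pytest.fixture(scope="session")
def origins_300kb(genome_300kb) -> AnchorSet:
    origins, _ = synthetic.gen_annotation(
        genome_300kb, n_origins=30, n_tss=0, min_gap=3000, seed=11
    )
    return origins


@pytest.fixture()
def small_dyads() -> DyadMap:
    return DyadMap({"chrI": np.array([1000, 1200, 1400, 3000])})


@pytest.fixture()
def three_minus_tss() -> AnchorSet:
    return AnchorSet(
        [Anchor("chrI", p, "-") for p in (2000, 5000, 8000)], kind="tss"
    )
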