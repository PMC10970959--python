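import numpy as np
import pytest

from fragcnv.core import GenomicRegion
from fragcnv.simulate import SyntheticGenome, build_genome


@pytest.fixture(scope="session")
def small_region() -> GenomicRegion:
    return GenomicRegion("chrS", 0, 1_000_000)


@pytest.fixture(scope="session")
def small_genome(small_region) -> SyntheticGenome:
    """200 bins of 5 kb with the default GC/weight structure."""
    return build_genome(small_region, bin_width=5000, gc_period_bp=200_000, seed=101)


@pytest.fixture(scope="session")
def flat_genome(small_region) -> SyntheticGenome:
    """Uniform emission weights and constant GC: a null landscape."""
    n = 200
    return SyntheticGenome(
        region=small_region,
        bin_width=5000,
        weights=np.ones(n),
        gc=np.full(n, 0.4),
    )
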