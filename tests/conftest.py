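import numpy as np
import pytest

from shoxdel.region import SampleSpec, build_region_model


@pytest.fixture(scope="session")
def model():
    """Default 300 kb region: Del1 170 kb central, Del2 70 kb right-nested."""
    return build_region_model(seed=11)


@pytest.fixture
def wt_pool():
    """21-member wild-type control pool at 56X, as in the sequencing design."""
    return SampleSpec(
        sample_id="pool",
        mean_coverage=56.0,
        is_pool=True,
        pool_members=tuple([("WT", "WT")] * 21),
    )


def make_case(sample_id, haplotypes, coverage=7.0):
    return SampleSpec(sample_id=sample_id, mean_coverage=coverage, haplotypes=haplotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
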