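import numpy as np
import pytest

from betavote import SimSpec, VoteMatrix, simulate_correlated_votes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_vote_matrix() -> VoteMatrix:
    """200-compound, 9-submodel correlated vote matrix (balanced)."""
    return simulate_correlated_votes(SimSpec(n=200, K=9, seed=7))


@pytest.fixture
def pool_vote_matrix() -> VoteMatrix:
    """2000-compound, 33-submodel training pool at the default conditions."""
    return simulate_correlated_votes(SimSpec(n=2000, seed=11))
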