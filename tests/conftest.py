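import numpy as np
import pytest

from calvingmc import STATE_LABELS, TransitionMatrix, fixtures

COWS = ("ID2", "ID11", "ID27")


@pytest.fixture(params=COWS)
def cow(request):
    return request.param


@pytest.fixture
def printed_P(cow):
    """Published transition matrix at 3-decimal precision."""
    return fixtures.load_transition(cow)


@pytest.fixture
def chain_P(cow):
    """Published transition matrix, rows rescaled to exact stochasticity."""
    return fixtures.load_transition(cow, renormalize=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20210928)


def random_substochastic_q(rng, m=4, min_leak=0.01):
    """Random m x m substochastic matrix with spectral radius < 1: every
    row leaks at least ``min_leak`` probability out of the transient set."""
    Q = rng.random((m, m))
    rowsum = Q.sum(axis=1)
    scale = (1.0 - rng.uniform(min_leak, 0.5, size=m)) / rowsum
    return Q * scale[:, None]


def fold_calving_hazard(P):
    """Remove absorption from a canonical chain by folding each transient
    row's calving probability back into its self-transition. The result is
    a recurrent 4-state dynamic (CALVE unreachable), useful for generating
    arbitrarily long paths."""
    probs = P.probs.copy()
    for i in range(4):
        probs[i, i] += probs[i, 4]
        probs[i, 4] = 0.0
    return TransitionMatrix(probs)


def random_stochastic(rng, n=5):
    M = rng.random((n, n)) + 0.05
    return TransitionMatrix(M / M.sum(axis=1, keepdims=True),
                            tuple(STATE_LABELS[:n]))


def absorbing_chain_from_q(Q, labels=STATE_LABELS):
    """Embed a substochastic Q as the transient block of a single-absorbing
    chain on the canonical alphabet."""
    m = Q.shape[0]
    P = np.zeros((m + 1, m + 1))
    P[:m, :m] = Q
    P[:m, m] = 1.0 - Q.sum(axis=1)
    P[m, m] = 1.0
    return TransitionMatrix(P, tuple(labels[:m]) + ("CALVE",))
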