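import pytest

from pamsens import chain3, toy_pam


@pytest.fixture
def chain3_pam():
    return chain3()


@pytest.fixture(scope="session")
def toy():
    return toy_pam()


def random_cases(n, start=0):
    """Deterministic (seed, n_rxns, n_enz) triples for property tests."""
    import numpy as np

    cases = []
    for seed in range(start, start + n):
        rng = np.random.default_rng(10_000 + seed)
        n_rxns = int(rng.integers(10, 41))
        n_enz = int(rng.integers(3, min(16, n_rxns - 1)))
        cases.append((seed, n_rxns, n_enz))
    return cases
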