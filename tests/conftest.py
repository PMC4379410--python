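import numpy as np
import pytest

from coalabc import (
    CoalescentConfig,
    CodingAlignment,
    SubstitutionParams,
    evolve_alignment,
    simulate_arg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_alignment(rows: list[str], labels=None) -> CodingAlignment:
    """Build a small alignment from nucleotide strings."""
    return CodingAlignment.from_strings(rows, labels)


@pytest.fixture
def small_simulated_alignment():
    """One simulated alignment with recombination and intermediate diversity."""
    rng = np.random.default_rng(77)
    gen = simulate_arg(CoalescentConfig(n_samples=8, l_nt=150, rho=8.0), rng)
    params = SubstitutionParams(theta=40.0, omega=0.6, kappa=1.5, n_codons=50)
    return evolve_alignment(gen, params, rng)
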