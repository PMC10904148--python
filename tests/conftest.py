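import numpy as np
import pytest

from graphannot import (
    SyntheticSpec,
    build_kernel_bank,
    build_transition_matrix,
    enhance_closed_form,
    generate_dataset,
    simlr_optimize,
    split_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 cells / 40 genes / 3 types, moderately separated."""
    spec = SyntheticSpec(
        m=60, n=40, c=3, proportions=(0.5, 0.3, 0.2), separation=1.0,
        dispersion=0.3, dropout_rate=0.2, seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_chain(tiny_dataset):
    """Similarity, denoised similarity and split for the tiny dataset."""
    X, truth = tiny_dataset
    bank = build_kernel_bank(X, k_values=(5, 10), sigma_values=(1.0, 2.0))
    simlr = simlr_optimize(bank, d=3, max_iter=25)
    T = build_transition_matrix(simlr.similarity, K=10)
    denoised = enhance_closed_form(T, alpha=0.5)
    split = split_dataset(truth, 0.1, seed=3)
    return {
        "X": X,
        "truth": truth,
        "bank": bank,
        "simlr": simlr,
        "T": T,
        "denoised": denoised,
        "split": split,
    }


def random_transition(m: int, K: int, seed: int):
    """A valid NE transition matrix from a random positive similarity."""
    rng = np.random.default_rng(seed)
    S = rng.random((m, m)) + 0.05
    S = (S + S.T) / 2.0
    return build_transition_matrix(S, K)
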