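import numpy as np
import pytest

import directpca as dp


@pytest.fixture(scope="session")
def tagc() -> dp.AlignedSequences:
    """The two-sample worked micro-example {TAGC, GAGC}."""
    return dp.AlignedSequences(["s1", "s2"], ["TAGC", "GAGC"])


@pytest.fixture(scope="session")
def tagc_matrix(tagc) -> dp.SequenceMatrix:
    return dp.encode_one_hot(tagc)


@pytest.fixture(scope="session")
def tagc_result(tagc_matrix) -> dp.PcaResult:
    m = dp.compute_center(tagc_matrix)
    return dp.run_direct_pca(dp.center_matrix(tagc_matrix, m))


def random_alignment(
    rng: np.random.Generator, n: int, l: int, alphabet: dp.Alphabet = dp.DNA
) -> dp.AlignedSequences:
    """Uniform random (unambiguous) alignment over the alphabet's symbols."""
    symbols = np.array(alphabet.symbols)
    rows = ["".join(rng.choice(symbols, size=l)) for _ in range(n)]
    return dp.AlignedSequences([f"r{i}" for i in range(n)], rows, alphabet)


@pytest.fixture(scope="session")
def clustered_fixture():
    """Default 3x30 clustered population with its labels and PCA result."""
    aligned, labels = dp.simulate_clustered_population(seed=11)
    X = dp.encode_one_hot(aligned)
    result = dp.run_direct_pca(dp.center_matrix(X, dp.compute_center(X)))
    return aligned, labels, X, result
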