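import numpy as np
import pytest

from ddicmf import InteractionMatrix, SimilarityMatrix, generate_synthetic


@pytest.fixture(scope="session")
def planted():
    """Noiseless planted low-rank dataset used across recovery tests."""
    return generate_synthetic(n=60, m=40, k_true=4, density=0.05, noise=0.0, seed=1)


@pytest.fixture()
def small_random():
    """Small random binary problem with benign similarity matrices."""
    rng = np.random.default_rng(0)
    n, m = 20, 15
    Y = (rng.random((n, m)) < 0.2).astype(float)
    Y[0, 0] = 1.0  # guarantee at least one interaction on each side
    Y[1, 1] = 1.0

    def sim(size, base):
        S = base * np.ones((size, size))
        S += 0.1 * rng.random((size, size))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        return np.clip(S, 0, 1)

    im = InteractionMatrix(
        [f"drug_{i}" for i in range(n)], [f"disease_{j}" for j in range(m)], Y
    )
    s_drug = SimilarityMatrix(list(im.drug_ids), sim(n, 0.3))
    s_dis = SimilarityMatrix(list(im.disease_ids), sim(m, 0.25))
    return im, s_drug, s_dis
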