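import numpy as np
import pandas as pd
import pytest

from copydist import simulate, similarity, spatial


@pytest.fixture(scope="session")
def default_cohort():
    """The neutral synthetic cohort (30 groups x 10, spatial decay only)."""
    return simulate.simulate_cohort(simulate.default_scenario(seed=0))


@pytest.fixture(scope="session")
def default_sim_internal(default_cohort):
    return similarity.similarity_matrix(default_cohort.internal)


@pytest.fixture(scope="session")
def default_sim_external(default_cohort):
    return similarity.similarity_matrix(default_cohort.external)


@pytest.fixture(scope="session")
def default_pairs(default_sim_internal, default_cohort):
    return spatial.cohort_pairs(default_sim_internal, default_cohort.metadata)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for permutation-heavy tests (10 groups x 6)."""
    return simulate.simulate_cohort(
        simulate.default_scenario(seed=11, n_groups=10, n_per_group=6)
    )


@pytest.fixture(scope="session")
def small_sim(small_cohort):
    return similarity.similarity_matrix(small_cohort.internal)


def random_similarity_matrix(rng: np.random.Generator, ids) -> similarity.SimilarityMatrix:
    """Structureless similarity matrix: iid symmetric noise around 0.5."""
    n = len(ids)
    vals = rng.uniform(0.3, 0.7, size=(n, n))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return similarity.SimilarityMatrix(list(ids), vals)


def iid_profile_similarity(rng: np.random.Generator, n: int, concentration: float = 5.0,
                           k: int = 6) -> similarity.SimilarityMatrix:
    """Similarity among n exchangeable individuals (iid Dirichlet profiles)."""
    profiles = rng.dirichlet(np.full(k, concentration), size=n)
    df = pd.DataFrame(profiles, index=[f"i{j:03d}" for j in range(n)])
    df.columns = [f"D{c}" for c in df.columns]
    return similarity.similarity_matrix(df, panel="internal")
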