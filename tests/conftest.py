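import numpy as np
import pytest

from corecollect import MISSING, GenotypeMatrix

CLASS_POOL = ["AA", "AG", "GG", "CC", "AC"]


def random_matrix(rng, n_samples=None, n_markers=None, missing_rate=0.2, n_classes=3):
    """A small random genotype matrix for oracle comparisons."""
    n = n_samples or int(rng.integers(2, 11))
    m = n_markers or int(rng.integers(1, 13))
    k = int(rng.integers(2, n_classes + 1))
    calls = rng.choice(CLASS_POOL[:k], size=(n, m)).astype(object)
    drop = rng.random((n, m)) < missing_rate
    calls[drop] = MISSING
    # keep every sample scoreable: at least one non-missing call per row
    for j in range(n):
        if (calls[j] == MISSING).all():
            calls[j, rng.integers(m)] = CLASS_POOL[0]
    return GenotypeMatrix(
        [f"S{j}" for j in range(n)], [f"M{i}" for i in range(m)], calls
    )


def random_mask(rng, T):
    """An arbitrary CoverageState with ~30% of class slots covered."""
    from corecollect import CoverageState

    S = CoverageState.empty(T)
    S.covered[:-1] = rng.random(T.n_slots) < 0.3
    return S


@pytest.fixture
def two_marker_matrix():
    """The hand-computable 2x2 example: one het mis-ordered, one missing."""
    calls = np.array([["AA", "AG"], ["AA", MISSING]], dtype=object)
    return GenotypeMatrix(["s1", "s2"], ["m1", "m2"], calls)


@pytest.fixture
def triplicated_matrix():
    """3 distinct genotype rows each duplicated 5x: 15 samples, no missing."""
    rows = [
        ["AA", "AA", "GG", "AG", "CC"],
        ["AG", "AA", "AA", "GG", "CC"],
        ["GG", "AG", "AA", "AA", "AC"],
    ]
    calls = np.array([row for row in rows for _ in range(5)], dtype=object)
    ids = [f"S{r}_{c}" for r in range(3) for c in range(5)]
    return GenotypeMatrix(ids, [f"M{i}" for i in range(5)], calls)
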