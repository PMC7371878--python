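import numpy as np
import pytest

from fnnm import NeighborhoodTable


@pytest.fixture
def toy_table():
    """Three subjects with neighbor sets {a,b,c}, {a,b}, {a,c}."""
    return NeighborhoodTable(
        subject_ids=["s1", "s2", "s3"],
        candidate_nodes=["a", "b", "c"],
        membership=np.array([[1, 1, 1], [1, 1, 0], [1, 0, 1]], dtype=bool),
    )


def random_table(rng, n_subjects=None, n_candidates=None, density=None):
    """A random membership table for property tests."""
    n = n_subjects or int(rng.integers(1, 31))
    c = n_candidates or int(rng.integers(1, 13))
    p = density if density is not None else rng.uniform(0.1, 0.95)
    membership = rng.random((n, c)) < p
    names = [f"n{j:02d}" for j in range(c)]
    return NeighborhoodTable([f"s{i}" for i in range(n)], names, membership)
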