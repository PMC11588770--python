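import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from mptrecall.models import (
    PersonCounts,
    build_pair_clustering_model,
    build_storage_retrieval_model,
    category_probabilities_matrix,
)


@pytest.fixture(scope="session")
def pair_model():
    return build_pair_clustering_model()


@pytest.fixture(scope="session")
def sr_model():
    return build_storage_retrieval_model()


def make_person_counts(model, group_theta, n_persons, items_per_tree, sd=0.4,
                       seed=0):
    """Probit-normal population -> per-person multinomial counts (plus truth)."""
    rng = np.random.default_rng(seed)
    mu = ndtri(np.asarray(group_theta, dtype=float))
    eta = mu + sd * rng.standard_normal((n_persons, len(mu)))
    theta = ndtr(eta)
    probs = category_probabilities_matrix(model, theta)
    tables = {
        t: np.stack([rng.multinomial(items_per_tree[t], p) for p in probs[t]])
        for t in model.tree_names
    }
    pc = PersonCounts(tuple(f"p{i}" for i in range(n_persons)), tables)
    return pc, eta
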