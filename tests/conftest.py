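import numpy as np
import pandas as pd
import pytest

from egobp import synthetic_cohort as sc
from egobp import ego_network as en


@pytest.fixture(scope="session")
def small_study():
    """A 60-participant default-configuration study shared across tests."""
    return sc.generate_study(sc.GeneratorConfig(n_participants=60, seed=7))


def ratings_from_edges(edges, n_alters=30, tie_rating=5, no_tie_rating=1):
    """Full 435-row tie table realizing a given edge set."""
    edges = {tuple(sorted(e)) for e in edges}
    iu, ju = np.triu_indices(n_alters, k=1)
    rating = [tie_rating if (i, j) in edges else no_tie_rating
              for i, j in zip(iu, ju)]
    return pd.DataFrame({"alter_i": iu, "alter_j": ju, "rating": rating})


def graph_from_edges(edges, n_alters=30, family=None, ego_id="ego"):
    family = [False] * n_alters if family is None else family
    return en.EgoGraph(ego_id=ego_id, n_nodes=n_alters,
                       edges=frozenset(tuple(sorted(e)) for e in edges),
                       family_flags=tuple(family))
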