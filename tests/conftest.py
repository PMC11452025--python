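import numpy as np
import pytest
from hypothesis import settings

from triplocall.clustering import ClusterModel

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


def model_from_groups(groups_x, groups_y=None, P=None, marker_id="M"):
    """Build a ClusterModel directly from per-cluster member coordinates.

    ``groups_x`` is a list of per-cluster contrast arrays; ``groups_y``
    matches it (defaults to 1.0 everywhere).  ``P`` defaults to one-hot
    membership.
    """
    groups_x = [np.asarray(g, float) for g in groups_x]
    if groups_y is None:
        groups_y = [np.ones_like(g) for g in groups_x]
    groups_y = [np.asarray(g, float) for g in groups_y]
    x = np.concatenate(groups_x)
    y = np.concatenate(groups_y)
    K = len(groups_x)
    assignment = np.concatenate([np.full(len(g), k, dtype=int)
                                 for k, g in enumerate(groups_x)])
    if P is None:
        P = np.zeros((len(x), K))
        P[np.arange(len(x)), assignment] = 1.0
    else:
        P = np.asarray(P, float)
    n_members = np.array([len(g) for g in groups_x])
    mean_x = np.array([g.mean() for g in groups_x])
    mean_y = np.array([g.mean() for g in groups_y])
    sd_x = np.array([g.std(ddof=1) if len(g) > 1 else 0.0 for g in groups_x])
    weight = n_members / len(x)
    return ClusterModel(marker_id, x, y, mean_x, mean_y, sd_x, weight,
                        n_members, P, assignment)


@pytest.fixture
def four_cloud_points():
    """A clean triploid marker: four genotype clouds at the canonical
    contrast centres."""
    rng = np.random.default_rng(42)
    centres = [-1.5, -0.5, 0.5, 1.5]
    x = np.concatenate([rng.normal(c, 0.12, 50) for c in centres])
    y = rng.normal(1.0, 0.1, 200)
    truth = np.repeat(np.arange(4), 50)
    return np.round(x, 3), np.round(y, 3), truth
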