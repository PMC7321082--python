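import numpy as np
import pytest

from kedge.structures import AtomSite, AtomicCluster


def random_cluster(rng, n_atoms=None, label="test", box=4.0, min_sep=1.0):
    """A random cluster with an Fe absorber at the origin."""
    n_atoms = n_atoms or int(rng.integers(5, 31))
    sites = [AtomSite(26, np.zeros(3))]
    positions = [np.zeros(3)]
    while len(sites) < n_atoms:
        pos = rng.uniform(-box, box, size=3)
        if all(np.linalg.norm(pos - p) >= min_sep for p in positions):
            z = int(rng.choice([1, 6, 8, 9, 16, 26]))
            sites.append(AtomSite(z, pos))
            positions.append(pos)
    return AtomicCluster(sites, 0, label)


def random_rotation(rng):
    """A uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_cluster(cluster, rotation, translation, permutation):
    """Rigidly transform and reindex a cluster."""
    sites = [
        AtomSite(
            cluster.sites[i].z,
            rotation @ cluster.sites[i].position + translation,
        )
        for i in permutation
    ]
    absorber = list(permutation).index(cluster.absorber_index)
    return AtomicCluster(sites, absorber, cluster.label)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def cluster(rng):
    return random_cluster(rng, n_atoms=12)
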