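import numpy as np
import pytest

import ddmotion as dm

HASH = ["3", "4", "8", "9"]
BUNDLE = ["1a", "1b", "2", "6a", "6b", "7"]


@pytest.fixture(scope="session")
def scheme():
    """14-segment LeuT-fold-style scheme, 8 residues per segment."""
    return dm.default_scheme(8)


@pytest.fixture(scope="session")
def toy(scheme):
    """Clash-free toy protein: one ideal helix per segment."""
    return dm.make_toy_protein(scheme)


@pytest.fixture(scope="session")
def sparse_mixture():
    """22 hb-DDMs mixed from 3 disjoint-support components + noise (σ=0.05 Å)."""
    k = 14
    supports = [
        [(0, i) for i in range(1, 8)],
        [(5, i) for i in range(6, 12)],
        [(12, 12), (12, 13), (13, 13), (2, 12), (2, 13)],
    ]
    components = dm.make_sparse_components(k, supports, magnitude=2.0)
    rng = np.random.default_rng(7)
    weights = rng.uniform(0.2, 1.5, size=(22, 3))
    dataset = dm.make_hbddm_dataset(components, weights, noise_sd=0.05, seed=11)
    return components, weights, dataset


def random_trace(rng, n=20, protein_id="p", structure_id="S1"):
    return dm.CaTrace(
        protein_id, structure_id, "A",
        np.arange(1, n + 1),
        rng.uniform(-20, 20, size=(n, 3)),
    )


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-30, 30, size=3)
    return Q, t
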