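import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from decoyclust import (Conformation, DecoyEnsemble, EnsembleSpec,
                        generate_decoy_ensemble, pairwise_distances)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def straight_chain():
    """Three CAs along x at the canonical 3.8 A spacing."""
    return Conformation("straight", [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])


@pytest.fixture
def small_labeled():
    """A 60-member, 3-cluster, L=40 labeled ensemble (well separated)."""
    spec = EnsembleSpec(n_residues=40, cluster_sizes=(30, 20, 10), seed=7)
    return generate_decoy_ensemble(spec)


@pytest.fixture
def small_rmsd_matrix(small_labeled):
    return pairwise_distances(small_labeled.ensemble, "rmsd")


def random_conformation(rng, L, scale=3.0):
    """Unstructured random coordinates; fine for metric algebra tests."""
    return Conformation(f"rand{L}", rng.normal(size=(L, 3)) * scale)


def random_proper_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.linalg.det(q))
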