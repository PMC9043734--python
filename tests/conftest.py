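"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from yartsa import synthdata
from yartsa.trees import parse_newick


@pytest.fixture(scope="session")
def default_bundle():
    """One full default-scale simulated study (90 samples, 14 loci)."""
    return synthdata.simulate_bundle(synthdata.SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """A light bundle for fast end-to-end checks."""
    return synthdata.simulate_bundle(
        synthdata.SimConfig(seed=7, n_samples=12, n_loci=4, locus_length=300)
    )


@pytest.fixture()
def five_tip_tree():
    return parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")


def random_distance_matrix(n, rng, labels=None):
    from yartsa.containers import DistanceMatrix

    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    labels = labels or [f"x{i}" for i in range(n)]
    return DistanceMatrix(labels, d)
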