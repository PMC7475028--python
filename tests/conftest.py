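from __future__ import annotations

import numpy as np
import pytest

from dupfate.io import read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


def random_gene_tree(rng, n_leaves=12, n_species=4, with_supports=True):
    """Random rooted bifurcating gene tree over a small species set."""
    species = [f"sp{k}" for k in range(n_species)]
    labels = [
        f"{species[int(rng.integers(n_species))]}_g{i}" for i in range(n_leaves)
    ]
    nodes = [f"{lab}:1.0" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        support = f"{rng.uniform(0.5, 1.0):.3f}" if with_supports else ""
        merged = f"({a},{b}){support}:1.0"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return read_newick(nodes[0] + ";")


@pytest.fixture
def make_random_tree(rng):
    def _make(n_leaves=12, n_species=4):
        return random_gene_tree(rng, n_leaves, n_species)

    return _make
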