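"""Shared fixtures: one canonical synthetic screen and small toy objects."""

import numpy as np
import pytest

from syncom_screen.design import DesignSpec, StrainPool, assemble_communities
from syncom_screen.metrics import StrainTree
from syncom_screen.simulate import GeneratorConfig, generate_screen

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def canonical_screen():
    """One default synthetic screen (train, test, truth), reused read-only."""
    return generate_screen(GeneratorConfig(), seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture
def small_pool():
    return StrainPool.numbered(6)


@pytest.fixture
def star_tree():
    return StrainTree.from_newick("(A:1,B:2,C:3);")


def random_tree(n_leaves: int, rng: np.random.Generator) -> StrainTree:
    """Random binary tree with uniform branch lengths, for oracle tests."""
    nodes = [f"L{i}:{rng.uniform(0.1, 2.0):.4f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return StrainTree.from_newick(f"({nodes[0]},{nodes[1]});")
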