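"""Shared fixtures: small trees, the reference chronogram, random-tree helper."""

from __future__ import annotations

import numpy as np
import pytest

from vestmorph import datasets, parse_newick
from vestmorph.trees import PhyloTree


@pytest.fixture(scope="session")
def anthropoid_tree() -> PhyloTree:
    return datasets.anthropoid_tree()


@pytest.fixture(scope="session")
def anthropoid_cov(anthropoid_tree):
    return anthropoid_tree.covariance()


@pytest.fixture()
def three_tip_tree() -> PhyloTree:
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random binary tree by sequential pairwise joins, branch lengths U(0.2, 2)."""
    subtrees = [f"T{i}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la, lb = rng.uniform(0.2, 2.0, size=2)
        subtrees.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return parse_newick(subtrees[0] + ";")
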