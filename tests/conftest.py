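import numpy as np
import pandas as pd
import pytest

from nhejevo.trees import Phylogeny


def star_tree(n: int, branch: float = 1.0, prefix: str = "s") -> Phylogeny:
    parent = [-1] + [0] * n
    blen = [0.0] + [branch] * n
    labels = [None] + [f"{prefix}{i}" for i in range(n)]
    return Phylogeny(parent, blen, labels)


def random_tree(n_tips: int, seed: int, height: float | None = None) -> Phylogeny:
    from nhejevo.simulate import simulate_tree

    tree = simulate_tree(n_tips, seed=seed)
    if height is not None:
        tree = tree.scale(height / tree.height())
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


@pytest.fixture
def cherry():
    return Phylogeny.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")
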