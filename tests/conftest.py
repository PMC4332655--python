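"""Shared fixtures: seeded random trees, multrees, and small repositories."""

import numpy as np
import pytest

from treequery.synth import make_multree, random_binary_tree


def random_multree(seed: int):
    """Seeded random duplication multree with 4-7 distinct labels.

    Mixes concordant and discordant duplication, with an occasional
    second discordant round for messier conflict structure.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4, 8))
    labels = [chr(65 + i) for i in range(k)]
    tree = random_binary_tree(labels, rng)
    n_dup = int(rng.integers(1, 4))
    dups = [str(x) for x in rng.choice(labels, size=min(n_dup, k), replace=False)]
    mode = "concordant" if rng.random() < 0.5 else "discordant"
    m = make_multree(tree, dups, mode, rng)
    if rng.random() < 0.3:
        m = make_multree(m, [str(rng.choice(labels))], "discordant", rng)
    return m


@pytest.fixture
def multree_factory():
    return random_multree


@pytest.fixture
def quartet_tree():
    """The canonical 4-leaf tree ((A,B),(C,D))."""
    from treequery.trees import parse_newick

    return parse_newick("((A,B),(C,D));")
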