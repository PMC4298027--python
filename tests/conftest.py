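import numpy as np
import pytest

import phylolat as pl


@pytest.fixture(scope="session")
def tree():
    return pl.bundled_tree()


@pytest.fixture(scope="session")
def table(tree):
    return pl.bundled_trait_table().loc[tree.tips]


def random_tree_newick(seed: int, n_tips: int = 8, ultrametric: bool = False) -> str:
    """A random rooted bifurcating tree with positive branch lengths.

    Built by random sequential joining; with ``ultrametric=True`` every tip
    sits at the same depth (a coalescent-style chronogram).
    """
    rng = np.random.default_rng(seed)
    if ultrametric:
        # (newick fragment without trailing length, node height)
        nodes = [(f"T{i}", 0.0) for i in range(n_tips)]
        while len(nodes) > 1:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            (na, ha), (nb, hb) = nodes[i], nodes[j]
            h = max(ha, hb) + float(rng.uniform(0.5, 3.0))
            merged = (f"({na}:{h - ha!r},{nb}:{h - hb!r})", h)
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        return nodes[0][0] + ";"
    frags = [f"T{i}:{rng.uniform(0.3, 3.0)!r}" for i in range(n_tips)]
    while len(frags) > 1:
        i, j = rng.choice(len(frags), size=2, replace=False)
        joined = f"({frags[i]},{frags[j]})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        if frags:
            joined += f":{rng.uniform(0.3, 3.0)!r}"
        frags.append(joined)
    return frags[0] + ";"


@pytest.fixture
def random_tree():
    return lambda seed, n_tips=8, ultrametric=False: pl.read_newick(
        random_tree_newick(seed, n_tips, ultrametric)
    )
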