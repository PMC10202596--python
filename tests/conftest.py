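import numpy as np
import pytest

try:  # small-matrix linear algebra is faster without BLAS thread fan-out
    import threadpoolctl

    threadpoolctl.threadpool_limits(1)
except ImportError:  # pragma: no cover
    pass

import relict
from relict.synthetic_data import pick_foreground_clade
from relict.trees import Phylogeny


@pytest.fixture(scope="session")
def small_tree() -> Phylogeny:
    """Fixed 4-tip tree with distinct branch lengths."""
    return Phylogeny.from_newick("((A:0.1,B:0.3):0.15,(C:0.2,D:0.05):0.25);")


@pytest.fixture(scope="session")
def uniform_freqs() -> np.ndarray:
    return np.full(61, 1.0 / 61.0)


@pytest.fixture(scope="session")
def two_class_dataset():
    """Simulated alignment with a relaxed foreground clade (truth 0.2 / 0.8)."""
    tree = relict.generate_yule_tree(8, seed=11).with_height(0.4)
    fg = pick_foreground_clade(tree, 0.4)
    tree = tree.tag_clade(fg, "fg")
    cfg = relict.SimConfig(
        seed=5, n_tips=8, n_codons=300, omega_by_class={"bg": 0.2, "fg": 0.8}
    )
    return tree, relict.simulate_codon_alignment(tree, cfg)


def star_tree(n: int, length: float = 1.0) -> Phylogeny:
    parent = [-1] + [0] * n
    lengths = [0.0] + [length] * n
    labels = [None] + [f"t{i:02d}" for i in range(n)]
    return Phylogeny(parent, lengths, labels)


@pytest.fixture(scope="session")
def star40() -> Phylogeny:
    return star_tree(40)
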