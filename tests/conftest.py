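import numpy as np
import pytest

from orthotx.simulate import PhylogenyModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_tree():
    """Five-leaf rooted tree with the focal lineage on a short branch."""
    nwk = "((focal:0.05,near:0.05):0.05,((sp1:0.08,sp2:0.08):0.04,sp3:0.12):0.02);"
    return PhylogenyModel(nwk, focal_species="focal")


def star_tree(n_others: int, focal_len: float = 0.1, other_len: float = 0.1) -> PhylogenyModel:
    parts = [f"focal:{focal_len}"] + [f"o{i:02d}:{other_len}" for i in range(n_others)]
    return PhylogenyModel("(" + ",".join(parts) + ");", focal_species="focal")
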