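import dendropy
import numpy as np
import pytest

from otuaudit.io_formats import MultipleAlignment, OTUCluster, PhyloTree, Sequence


@pytest.fixture
def three_leaf_tree() -> PhyloTree:
    tree = dendropy.Tree.get(data="((A:0.1,B:0.2):0.05,C:0.3);", schema="newick",
                             suppress_internal_node_taxa=True)
    return PhyloTree(tree)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160420)


def random_msa(rng: np.random.Generator, n_rows: int, n_cols: int,
               p_gap: float = 0.1, p_n: float = 0.05) -> MultipleAlignment:
    """Random gapped MSA over ACGTN- with unique row ids."""
    alphabet = np.array(list("ACGT"))
    rows = []
    for i in range(n_rows):
        chars = alphabet[rng.integers(0, 4, size=n_cols)]
        mask = rng.random(n_cols)
        chars[mask < p_gap] = "-"
        chars[(mask >= p_gap) & (mask < p_gap + p_n)] = "N"
        rows.append(Sequence(f"r{i}", "".join(chars)))
    return MultipleAlignment(rows)


def random_cluster(otu_id: str, rep: str, members: list[str]) -> OTUCluster:
    return OTUCluster(otu_id, rep, frozenset(members))
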