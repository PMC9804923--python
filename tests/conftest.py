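import dendropy
import numpy as np
import pytest

from darrmeta.effects import GroupStat
from darrmeta.phylo import grafen_lengths, phylo_correlation
from darrmeta.simulate import SimTruth, simulate_dataset, simulate_tree


def make_group(study="s1", species="sp", T=20.0, ht=38.0, **kw):
    return GroupStat(study_id=study, species=species, temperature=T,
                     mean_ht=ht, **kw)


@pytest.fixture
def balanced_tree():
    t = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture
def pectinate_tree():
    t = dendropy.Tree.get(data="(a,(b,(c,d)));", schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture(scope="session")
def small_system():
    """A modest synthetic study system shared by slower tests."""
    truth = SimTruth(n_species=12, studies_per_species=(2, 3), seed=11,
                     frac_tdt=0.0, frac_missing_sd=0.0)
    groups, truth_df, A = simulate_dataset(truth)
    return truth, groups, truth_df, A


@pytest.fixture(scope="session")
def small_correlation():
    tree = simulate_tree(8, seed=5)
    return phylo_correlation(grafen_lengths(tree))
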