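import dendropy
import pytest

from cophylodate.trees import Chronogram, Phylogeny, TipAssociation


def tree_from_newick(newick: str) -> Phylogeny:
    return Phylogeny(
        dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    )


def chronogram_from_newick(newick: str, tolerance=None) -> Chronogram:
    return Chronogram(
        dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        ),
        tolerance=tolerance,
    )


def association_from_pairs(pairs, erv=()):
    """pairs: iterable of (virus_tip, host) tuples."""
    erv = set(erv)
    return TipAssociation({v: (h, v in erv) for v, h in pairs})


@pytest.fixture
def mirrored_pair():
    """A 4-host chronogram and a virus tree with identical topology,
    one virus per host, all supports 1.0."""
    host = chronogram_from_newick("(((H1:10,H2:10):20,H3:30):15,H4:45);")
    virus = tree_from_newick(
        "(((V1:0.1,V2:0.12)1.0:0.2,V3:0.31)1.0:0.15,V4:0.5)1.0;"
    )
    assoc = association_from_pairs(
        [("V1", "H1"), ("V2", "H2"), ("V3", "H3"), ("V4", "H4")]
    )
    return virus, host, assoc
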