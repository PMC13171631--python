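import dendropy
import pandas as pd
import pytest

from microcensus import SyntheticWorld, compute_red, simulate_census


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def balanced_tree():
    """Balanced depth-2 tree with unit branches (root children RED = 0.5)."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture(scope="session")
def balanced_red(balanced_tree):
    return compute_red(balanced_tree)


@pytest.fixture(scope="session")
def small_world():
    """A compact census world shared by table-level tests."""
    return SyntheticWorld(
        n_species=200,
        n_samples_per_habitat={"human gut": 30, "soil": 30},
        occupancy_params={"mu": -2.0, "sigma": 1.0},
        n_markers=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_census(small_world):
    return simulate_census(small_world)


def records(rows):
    """Build a census DataFrame from (seq, marker, cluster, source, sample,
    contig, habitat) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "marker_gene",
            "cluster_id",
            "source",
            "sample_id",
            "contig_id",
            "habitat",
        ],
    )
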