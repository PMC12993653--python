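import io as _stdio

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizosignal.io import RANKS, CountTable, SampleMetadata, TaxonomyTable
from rhizosignal.simulate import simulate_study


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(_stdio.StringIO(newick))


@pytest.fixture
def cherry_tree():
    # ((A:1,B:1):1,C:2) — classic hand-checkable BM covariance fixture
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def six_tip_tree():
    return tree_from_newick(
        "(((A:0.2,B:0.3):0.5,(C:0.4,D:0.1):0.6):0.3,(E:0.7,F:0.2):0.8);"
    )


@pytest.fixture
def small_table():
    counts = np.array([[5, 0, 2], [1, 3, 0], [0, 7, 4]])
    return CountTable(["zotu1", "zotu2", "zotu3"], ["s1", "s2", "s3"], counts)


@pytest.fixture
def small_taxonomy():
    rows = {
        "zotu1": ["bacteria", "pA", "cA", "oA", "fA", "gA"],
        "zotu2": ["bacteria", "pA", "cB", "oB", "fB", "unassigned"],
        "zotu3": ["bacteria", "pB", "cC", "unassigned", "unassigned", "unassigned"],
    }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


@pytest.fixture
def tiny_metadata():
    rows = []
    for treatment in ("ambient", "severe"):
        for r in range(1, 4):
            rows.append((f"{treatment}{r}", treatment, "T2", "rhizosphere", r))
    df = pd.DataFrame(
        rows, columns=["sample_id", "treatment", "timepoint", "microhabitat", "replicate"]
    ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def synthetic_study():
    """One moderate synthetic study shared across tests (40 taxa, 60 samples,
    strong phylogenetic signal and one planted positive responder clade)."""
    return simulate_study(n_tips=40, lambda_true=0.9, effect_sd=1.0,
                          responder_deltas=(2.0,), seed=11)
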