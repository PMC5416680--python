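import numpy as np
import pandas as pd
import pytest

from degnet.io import AnnotationTable, CountMatrix
from degnet.simulate import make_paper_scale_fixture


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=["g1", "g2"],
        sample_ids=["s1", "s2"],
        counts=np.array([[0, 5], [3, 7]]),
        groups={"s1": "case", "s2": "control"},
    )


@pytest.fixture
def annotation_small() -> AnnotationTable:
    return AnnotationTable(
        pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "symbol": ["A1", "B2", "C3", "D4"],
                "locus_group": ["protein_coding", "ncRNA", "pseudogene", "other"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down but structurally complete synthetic study bundle."""
    return make_paper_scale_fixture(
        seed=11, n_genes=4000, interactome_nodes=1200, module_edge_prob=0.2
    )
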