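import numpy as np
import pytest

import rumiconn as rc


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    return rc.generate_cohort(n_subjects=60, n_rois=12, planted_edges=4, seed=11)


@pytest.fixture(scope="session")
def small_edge_table(small_cohort):
    return rc.CohortEdgeTable.from_matrices(small_cohort.fc, small_cohort.table)


@pytest.fixture
def toy_parcellation():
    """3 ROIs: two DMN, one SMN."""
    import pandas as pd

    return rc.Parcellation(
        data=pd.DataFrame(
            {
                "roi_id": [0, 1, 2],
                "roi_name": ["L_DMN_0", "R_DMN_1", "L_SMN_0"],
                "network": ["DMN", "DMN", "SMN"],
                "hemisphere": ["L", "R", "L"],
            }
        )
    )


def noiseless_single_edge_cohort(n=50):
    """Cohort where one edge determines the score exactly (no noise).

    Edge 0 varies across subjects, all other edges are constant; the score
    is an exact affine function of edge 0 with positive slope, so the
    positive network recovers it and predicts perfectly.
    """
    n_rois = 6
    p = rc.n_edges(n_rois)
    edges = np.full((n, p), 0.25)
    edge_vals = np.linspace(0.1, 0.9, n)
    edges[:, 0] = edge_vals
    scores = 2.0 * edge_vals + 1.0
    return rc.CohortEdgeTable(edges=edges, scores=scores, n_rois=n_rois)
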