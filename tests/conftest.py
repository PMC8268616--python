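import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from phenosig.sc_io import SingleCellMatrix
from phenosig.synthetic_data import simulate_single_cell, simulate_study


def make_matrix(counts, genes=None, cells=None, subclusters=None,
                cell_types=None, patients=None):
    """Hand-build a SingleCellMatrix from a dense count array."""
    counts = np.asarray(counts)
    G, C = counts.shape
    genes = genes or [f"G{i}" for i in range(G)]
    cells = cells or [f"c{i}" for i in range(C)]
    subclusters = subclusters or ["S1"] * C
    meta = pd.DataFrame({
        "patient_id": patients or ["P1"] * C,
        "sample_id": ["P1T"] * C if patients is None else [p + "T" for p in patients],
        "tissue_type": ["tumour"] * C,
        "site": ["ovary"] * C,
        "major_cell_type": cell_types or ["CT"] * C,
        "subcluster": subclusters,
    }, index=cells)
    return SingleCellMatrix(sp.csr_matrix(counts), np.array(genes, dtype=object),
                            np.array(cells, dtype=object), meta)


@pytest.fixture(scope="session")
def small_sim():
    """Planted-marker single-cell data, small but large enough for detection
    statistics (4 subclusters x 300 cells, 400 genes, 10 markers each)."""
    return simulate_single_cell(n_subclusters=4, cells_per_subcluster=300,
                                n_genes=400, markers_per_subcluster=10,
                                marker_detection_target=0.8,
                                background_detection=0.02, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """End-to-end synthetic study: single cells, 3 bulk cohorts, survival with
    one prognostic subcluster (HR 1.5 per SD of its fraction)."""
    return simulate_study(n_subclusters=4, cells_per_subcluster=300,
                          n_genes=400, markers_per_subcluster=10,
                          n_cohorts=3, samples_per_cohort=150, noise_sd=0.1,
                          beta_per_subcluster={"SC1": float(np.log(1.5))},
                          seed=7)
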