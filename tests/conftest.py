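import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crestatlas.containers import CellAccessibilityMatrix
from crestatlas.simulate import LineageSpec, simulate_atlas


def small_spec(**overrides) -> LineageSpec:
    """A down-scaled atlas spec for fast unit tests."""
    kwargs = dict(
        tissues=[f"tissue{i:02d}" for i in range(4)],
        timepoints=["T0", "T1", "T2"],
        cells_per_timepoint=300,
        peaks_per_tissue=40,
        background_peaks=400,
        effect_size=3.0,
        n_priming_pairs=2,
        n_decoy_motifs=30,
        seed=0,
    )
    kwargs.update(overrides)
    return LineageSpec(**kwargs)


@pytest.fixture(scope="session")
def small_atlas():
    return simulate_atlas(small_spec())


@pytest.fixture()
def toy_matrix():
    """Hand-built 4-peak x 6-cell matrix with known per-cell metadata."""
    counts = sp.csr_matrix(
        np.array(
            [
                [2, 1, 0, 3, 5, 1],
                [0, 1, 1, 0, 2, 0],
                [1, 0, 0, 2, 1, 2],
                [0, 0, 1, 1, 0, 1],
            ]
        )
    )
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "start": [0, 1000, 2000, 3000],
            "end": [500, 1500, 2500, 3500],
            "gc": [0.4, 0.5, 0.6, 0.45],
        }
    )
    cells = pd.DataFrame(
        {
            "frip": [0.2, 0.5, 0.6, 0.9, 0.7, 0.55],
            "fragments_in_peaks": [1500, 1500, 500, 1500, 25000, 1500],
        },
        index=pd.Index([f"bc{i}" for i in range(6)], name="barcode"),
    )
    return CellAccessibilityMatrix(
        counts=counts, peaks=peaks, cells=cells, timepoint="T0"
    )
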