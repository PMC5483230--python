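import numpy as np
import pandas as pd
import pytest

from burstvar.cloud import CloudConfig, simulate_cloud
from burstvar.preprocess import CountMatrix
from burstvar.synthetic import SyntheticDesign, generate_dataset


@pytest.fixture(scope="session")
def small_cloud():
    """A 50:50 variance-split cloud, small enough for fast pair sampling."""
    cfg = CloudConfig.from_scenario("iii", n_genes=600, n_cells=80, seed=123)
    return simulate_cloud(cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Frequency-mode synthetic dataset with all three time points."""
    design = SyntheticDesign(
        n_genes=600,
        cells_per_timepoint=((0, 36), (3, 36), (6, 36)),
        seed=42,
    )
    return generate_dataset(design)


def make_count_matrix(counts, time_point=0, replicate=1, prefix="c"):
    """CountMatrix from a plain array with uniform metadata."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    cells = [f"{prefix}{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"time_point": time_point, "replicate": replicate},
        index=pd.Index(cells, name="cell_id"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cells), cell_meta=meta
    )
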