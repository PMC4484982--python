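import numpy as np
import pandas as pd
import pytest

from refstab import CtMatrix, aggregate_replicates
from refstab.datasets import load_candidate_fpkm
from refstab.synthetic_data import simulate_ct, stress_design


@pytest.fixture(scope="session")
def fpkm():
    """Bundled 12-gene x 4-condition FPKM screening matrix."""
    return load_candidate_fpkm()


@pytest.fixture(scope="session")
def sim_ct():
    """Aggregated Ct matrix from the default simulated stress design (seed 7)."""
    return aggregate_replicates(simulate_ct(stress_design(seed=7)))


def random_q(seed: int, n_genes: int = 6, n_samples: int = 8) -> pd.DataFrame:
    """A random anchored relative-quantity matrix (genes x samples) in (0, 1]."""
    rng = np.random.default_rng(seed)
    ct = rng.uniform(18, 30, size=(n_genes, 1)) + rng.normal(0, 1.2, size=(n_genes, n_samples))
    q = 2.0 ** -(ct - ct.min(axis=1, keepdims=True))
    return pd.DataFrame(
        q,
        index=[f"g{i + 1}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )


def ct_matrix_from_frame(df: pd.DataFrame, groups=None) -> CtMatrix:
    if groups is None:
        groups = {s: "all" for s in df.columns}
    return CtMatrix(df, groups)
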