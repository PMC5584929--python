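import numpy as np
import pandas as pd
import pytest

import phagestate as ps


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset (8 samples, 20 phage genes)."""
    cfg = ps.SimConfig(
        n_samples=8,
        n_phage_genes=20,
        n_host_genes=3,
        library_size_range=(2000, 3000),
        seq_error_rate=0.0,
        seed=7,
    )
    models, truth, counts = ps.simulate_dataset(cfg)
    return cfg, models, truth, counts


@pytest.fixture(scope="session")
def study_scale_dataset():
    """Study-scale synthetic data: 33 samples, 184 phage genes, fold change 10."""
    cfg = ps.SimConfig(
        n_samples=33, library_size_range=(200_000, 200_000), seed=11
    )
    models, truth, counts = ps.simulate_dataset(cfg)
    return cfg, models, truth, counts


def expression_from_array(x: np.ndarray, prefix: str = "g") -> ps.ExpressionMatrix:
    """Wrap a genes x samples array as an ExpressionMatrix."""
    return ps.ExpressionMatrix(
        values=pd.DataFrame(
            x,
            index=[f"{prefix}{i:03d}" for i in range(x.shape[0])],
            columns=[f"s{j}" for j in range(x.shape[1])],
        )
    )
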