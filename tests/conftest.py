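import numpy as np
import pandas as pd
import pytest

import grndriver as gd


@pytest.fixture(scope="session")
def sc_cohort():
    """Default-scale synthetic single-cell cohort, shared across tests."""
    return gd.generate_single_cell_cohort(seed=11)


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default-scale synthetic bulk cohort (3 planted clusters)."""
    return gd.generate_bulk_cohort(n_samples=150, seed=5)


@pytest.fixture(scope="session")
def inferred_regulons(sc_cohort):
    expr, _, truth = sc_cohort
    return gd.infer_grn_correlation(expr, [r.tf for r in truth.regulons])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_expr():
    """Tiny deterministic genes x samples matrix for hand-checkable cases."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{j}" for j in range(6)]
    return pd.DataFrame(
        rng.integers(1, 100, size=(10, 6)).astype(float), index=genes, columns=samples
    )
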