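import numpy as np
import pandas as pd
import pytest

from gfabric.io_model import ExpressionSet

CHAMBERS = ("LA", "RA", "LV", "RV")
REPLICAS = ("1", "2", "3", "4")


def build_expression_set(gene_arrays, chambers=CHAMBERS, replicas=REPLICAS):
    """Construct an ExpressionSet directly from per-gene value arrays.

    ``gene_arrays[gene][chamber]`` is an (R x n_replicas) array of
    positive values; every gene must supply every chamber with the same R.
    """
    rows, index = [], []
    for gene, per_chamber in gene_arrays.items():
        r = np.atleast_2d(np.asarray(per_chamber[chambers[0]], dtype=float)).shape[0]
        for k in range(r):
            index.append((gene, f"{gene}_s{k + 1}"))
            rows.append(
                np.concatenate(
                    [
                        np.atleast_2d(np.asarray(per_chamber[c], dtype=float))[k]
                        for c in chambers
                    ]
                )
            )
    columns = pd.MultiIndex.from_tuples(
        [(c, r) for c in chambers for r in replicas], names=["chamber", "replica"]
    )
    values = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene", "spot_id"]),
        columns=columns,
    )
    return ExpressionSet(values, list(chambers), list(replicas))


@pytest.fixture
def expr_factory():
    return build_expression_set


@pytest.fixture(scope="session")
def random_fixture_expr():
    """20 genes, mixed spot redundancy 1-3, positive lognormal values."""
    rng = np.random.default_rng(20240)
    gene_arrays = {}
    for i in range(20):
        r = int(rng.integers(1, 4))
        gene_arrays[f"g{i:02d}"] = {
            c: np.exp(rng.normal(0.0, 0.6, size=(r, 4))) for c in CHAMBERS
        }
    return build_expression_set(gene_arrays)


@pytest.fixture
def toy_measurements():
    """One spot, one gene, 4 chamber:replica samples (2 chambers x 2 replicas)."""
    return pd.DataFrame(
        {
            "spot_id": ["s1"] * 4,
            "gene": ["Actc1"] * 4,
            "chamber": ["LA", "LA", "RA", "RA"],
            "replica": ["1", "2", "1", "2"],
            "foreground": [100.0, 110.0, 120.0, 130.0],
            "background": [10.0, 11.0, 12.0, 13.0],
            "corrupted": [False] * 4,
        }
    )
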