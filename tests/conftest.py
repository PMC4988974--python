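import numpy as np
import pandas as pd
import pytest

from conetdiff import harmonize_orthologs
from conetdiff.data import ExpressionDataset
from conetdiff.simulate import demo_config, generate_paired_datasets


def make_dataset(values, gene_ids=None, samples=None, tag="x") -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(pd.DataFrame(values, index=gene_ids, columns=samples), tag)


@pytest.fixture(scope="session")
def demo_run():
    """One harmonized demo-scale dataset pair with ground truth, shared
    across tests that only read from it."""
    cfg = demo_config(seed=7)
    a, b, map_a, map_b, truth = generate_paired_datasets(cfg)
    ha, hb = harmonize_orthologs(a, b, map_a, map_b)
    return {"config": cfg, "raw_a": a, "raw_b": b, "map_a": map_a,
            "map_b": map_b, "truth": truth, "a": ha, "b": hb}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
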