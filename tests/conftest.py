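import numpy as np
import pandas as pd
import pytest

from xsub import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample, 800-gene cohort with the default four subtype blocks."""
    cfg = synthetic.CohortSimConfig(
        n_samples=200, n_genes=800, genes_per_subtype_block=100, seed=11
    )
    expr, clin = synthetic.simulate_cohort(cfg)
    return cfg, expr, clin


@pytest.fixture(scope="session")
def subtype_de(small_cohort):
    """One-vs-rest Welch DE tables for every subtype of the small cohort."""
    from xsub import signatures

    cfg, expr, clin = small_cohort
    return {
        label: signatures.welch_de(
            expr,
            list(clin.index[clin["cms"] == label]),
            list(clin.index[clin["cms"] != label]),
        )
        for label in cfg.subtype_labels
    }


@pytest.fixture
def random_de(rng):
    """Random valid DE table for oracle comparisons."""
    n = 400
    genes = [f"g{i:04d}" for i in range(n)]
    p = rng.uniform(0, 1, n)
    return pd.DataFrame(
        {
            "log_fc": rng.normal(0, 1.5, n),
            "p_value": p,
            "p_adj": np.minimum(p * rng.uniform(1, 3, n), 1.0),
        },
        index=pd.Index(genes, name="gene"),
    )
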