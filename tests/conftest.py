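import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from locuspipe import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def ld_block():
    """A small LD block with one moderate-effect causal variant."""
    cfg = sd.SimConfig(
        seed=5,
        n_individuals=2000,
        n_variants=40,
        ld_decay=0.8,
        causal_index=20,
        causal_beta=0.6,
    )
    dosages, ld = sd.simulate_ld_genotypes(cfg)
    return cfg, dosages, ld


@pytest.fixture
def small_counts():
    """Deterministic 300-gene x 5-sample count matrix with library-size
    offsets and a handful of sample-1-specific genes (used for TMM)."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4, 1, size=300)
    counts = np.vstack([rng.poisson(mu * f) for f in [1.0, 2.0, 0.5, 1.5, 0.8]]).T
    counts[:15, 1] = rng.poisson(mu[:15] * 2.0 * 6)
    return pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(300)],
        columns=[f"s{j}" for j in range(5)],
    )
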