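import numpy as np
import pandas as pd
import pytest

import methmed as mm


@pytest.fixture(scope="session")
def mixed_dataset():
    """A moderately sized dataset with all four planted architectures.

    n=500 so trio-level statistics are stable; shared across tests that
    only read it.
    """
    cfg = mm.SimConfig(
        seed=42,
        n_samples=500,
        n_snps=300,
        n_cpgs=150,
        n_genes=60,
        trio_specs=(
            mm.TrioSpec("mediation", 12),
            mm.TrioSpec("common_cause", 8),
            mm.TrioSpec("reverse", 6),
            mm.TrioSpec("null", 6),
        ),
    )
    return mm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-size cohort (43 samples) for cheap structural checks."""
    return mm.simulate_dataset(mm.SimConfig(seed=7))


@pytest.fixture()
def covariates_30():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(30)],
            "age": rng.uniform(30, 70, 30).round(1),
            "disease_status": rng.integers(0, 2, 30),
        }
    )


def isolated_trio_config(architecture, count, seed, n_samples=500, **effects):
    """Config planting `count` trios of one architecture with no LD between them."""
    return mm.SimConfig(
        seed=seed,
        n_samples=n_samples,
        n_chromosomes=4,
        chrom_length_bp=200_000_000,
        n_snps=count,
        n_cpgs=count,
        n_genes=count,
        ld_block_size=1,
        trio_specs=(mm.TrioSpec(architecture, count, **effects),),
    )
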