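from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dosagecomp import SimConfig, simulate_counts, simulate_genome

settings.register_profile("suite", deadline=None, max_examples=60,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, fully featured study: biased and sex-specific genes present."""
    return SimConfig(genes_per_arm=120, scaffolds_per_arm=3,
                     lib_size_mean=1e6, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    genes, scaffold_truth = simulate_genome(small_config)
    cm, truth = simulate_counts(small_config, genes)
    lengths = genes.set_index("gene_id")["exonic_length"]
    return {"config": small_config, "genes": genes,
            "scaffold_truth": scaffold_truth, "cm": cm, "truth": truth,
            "lengths": lengths,
            "arms": truth.set_index("gene_id")["true_arm"]}


def expression_for(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate and normalize in one go; returns (expr, true arm labels)."""
    from dosagecomp import sex_expression

    genes, _ = simulate_genome(config)
    cm, truth = simulate_counts(config, genes)
    lengths = genes.set_index("gene_id")["exonic_length"]
    expr = sex_expression(cm, lengths)
    return expr, truth.set_index("gene_id")["true_arm"]


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same fresh stream
    return np.random.default_rng(20150616)
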