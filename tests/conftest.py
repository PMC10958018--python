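import numpy as np
import pytest

from nsclc_profiling.cohort import AD, SCC
from nsclc_profiling.synthetic import (
    DriverGene,
    SimulationConfig,
    default_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """120 lung + 120 non-lung samples, 40 genes, default-style drivers."""
    cfg = default_config(seed=7, n_samples_per_group=60, n_genes=40,
                         n_informative_expression_genes=10)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def lung_only_config():
    """Factory for NSCLC-only simulation configs."""

    def make(n_per_group=100, n_genes=30, drivers=None, background=0.02,
             effect=2.0, n_informative=10, mixed=0.0, seed=0, **kw):
        if drivers is None:
            drivers = [DriverGene(0, AD, 0.4, 0.03), DriverGene(1, SCC, 0.4, 0.03)]
        return SimulationConfig(
            n_samples_per_group=n_per_group,
            n_genes=n_genes,
            driver_spec=drivers,
            background_mutation_rate=background,
            expression_effect_size=effect,
            n_informative_expression_genes=n_informative,
            mixed_driver_fraction=mixed,
            tissue_labels=["lung"],
            seed=seed,
            **kw,
        )

    return make
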