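import numpy as np
import pandas as pd
import pytest

from subtypex.io import (
    AlterationMatrix,
    ExpressionMatrix,
    build_gene_matrix,
    filter_min_carriers,
    filter_nonsilent,
)
from subtypex.simulate import SimConfig, SubtypeSpec, default_config, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """Small cohort with planted ME/CO pairs and a triple (seed fixed)."""
    return simulate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def gene_matrix(default_bundle):
    b = default_bundle
    m = build_gene_matrix(
        filter_nonsilent(b.mutations), b.driver_genes, b.expression.sample_ids
    )
    return filter_min_carriers(m, 15)


@pytest.fixture(scope="session")
def single_gene_bundle():
    """One driver gene with two clean expression subtypes; minimal cross-talk."""
    cfg = SimConfig(
        n_samples=150,
        n_genes_expr=800,
        n_driver_genes=4,
        carrier_rate_range=(0.08, 0.12),
        load_sigma=0.3,
        seed=5,
    )
    cfg.carrier_rates = {"DRV01": 0.5}
    cfg.subtype_specs["DRV01"] = SubtypeSpec(
        k=2, proportions=(0.5, 0.5), de_block_size=120, log2_effect=2.0
    )
    return simulate_cohort(cfg)


def toy_matrix(rows: dict[str, list[int]], samples: list[str] | None = None) -> AlterationMatrix:
    n = len(next(iter(rows.values())))
    samples = samples or [f"S{j + 1}" for j in range(n)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return AlterationMatrix(values=df)


def toy_expression(values: np.ndarray, scale: str = "raw_counts") -> ExpressionMatrix:
    g, n = values.shape
    df = pd.DataFrame(
        values, index=[f"G{i + 1}" for i in range(g)], columns=[f"S{j + 1}" for j in range(n)]
    )
    return ExpressionMatrix(values=df, scale=scale)
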