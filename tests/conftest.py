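import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import txeffort as tx

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_matrix(values, unit=tx.RAW_COUNTS, partial=False):
    """Build a matrix from {sample: {gene: value}} (missing entries -> 0)."""
    return tx.matrix_from_mapping(values, unit=unit, partial=partial)


def per_million_from_counts(values):
    return tx.normalize_per_million(make_matrix(values))


@pytest.fixture(scope="session")
def planted_config():
    return tx.SyntheticConfig(
        seed=11, planted_outliers=(tx.PlantedOutlier(pair=("WPG", "WPGY"), fold=4.0),)
    )


@pytest.fixture(scope="session")
def bundle(planted_config):
    return tx.generate(planted_config)


@pytest.fixture(scope="session")
def bundle_pm(bundle):
    return tx.normalize_per_million(bundle.matrix)


@pytest.fixture()
def small_pm():
    """4 genes x 2 samples, hand-checkable per-million values."""
    df = pd.DataFrame(
        {
            "s1": [500_000.0, 300_000.0, 150_000.0, 50_000.0],
            "s2": [250_000.0, 250_000.0, 250_000.0, 250_000.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
    return tx.ExpressionMatrix(df, unit=tx.PER_MILLION)
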