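import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from boolgba import (
    ExpressionMatrix,
    NormalizationResult,
    simulate_attributes,
    simulate_expression,
)
from boolgba.profiles import ATTRIBUTES, BooleanProfile


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes x 8 samples over 4 conditions, fixed values."""
    rng = np.random.default_rng(42)
    values = rng.normal(8.0, 1.0, size=(3, 8))
    sample_ids = [f"s{i}" for i in range(1, 9)]
    conditions = ["Normal", "Normal", "Adenoma", "Adenoma",
                  "Carcinoma", "Carcinoma", "Inflammation", "Inflammation"]
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=sample_ids,
        values=values,
        condition_of=dict(zip(sample_ids, conditions)),
    )


def norm_from_means(means, conditions=("Normal", "Adenoma", "Carcinoma", "Inflammation")):
    """Wrap a gene x condition mean matrix as a NormalizationResult."""
    means = np.asarray(means, dtype=float)
    genes = [f"g{i}" for i in range(means.shape[0])]
    return NormalizationResult(
        gene_ids=genes,
        conditions=list(conditions),
        hybridization_effects={},
        gene_effects={g: 0.0 for g in genes},
        gene_condition_means=means,
        residuals=np.zeros((means.shape[0], 0)),
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """Default-parameter synthetic expression dataset (seeded)."""
    return simulate_expression(seed=0)


@pytest.fixture(scope="session")
def default_attributes():
    """Default-parameter synthetic attribute dataset (seeded)."""
    return simulate_attributes(seed=0)


def attribute_profiles(attrs):
    """13-bit profiles with all expression bits false (attribute-only)."""
    return {
        g: BooleanProfile((False,) * 7 + tuple(attrs.flags[g][a] for a in ATTRIBUTES))
        for g in attrs.gene_ids
    }
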