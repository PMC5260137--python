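import numpy as np
import pytest

from gfscore import ExpressionMatrix, SampleAnnotation


def random_matrix(
    rng: np.random.Generator,
    n_genes: int = 30,
    n_samples: int = 6,
    positive: bool = True,
) -> ExpressionMatrix:
    values = rng.lognormal(3.0, 1.0, (n_genes, n_samples)) if positive else rng.normal(
        0.0, 1.0, (n_genes, n_samples)
    )
    return ExpressionMatrix.from_arrays(
        [f"g{i:03d}" for i in range(n_genes)],
        [f"s{j:02d}" for j in range(n_samples)],
        values,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix.from_arrays(
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
    )


@pytest.fixture
def small_annotation() -> SampleAnnotation:
    return SampleAnnotation.from_mapping(
        {
            "s1": ("healthy", "b1"),
            "s2": ("disease", "b1"),
            "s3": ("healthy", "b2"),
            "s4": ("disease", "b2"),
        }
    )
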