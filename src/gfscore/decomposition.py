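"""High-variance gene selection and sample-space PCA.

In merged multi-batch expression data the first principal component is
typically dominated by batch effects, so downstream scoring either uses
the first three components (heterogeneous, batch-free data) or drops PC1
and keeps PC2/PC3 (batch-ridden data). :class:`ComponentSpec` names
those two conventions so every evaluation states explicitly which one it
uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ParameterError
from .io import ExpressionMatrix

__all__ = [
    "PcaResult",
    "ComponentSpec",
    "select_high_variance_genes",
    "reduce_to_genes",
    "pca_transform",
    "coords_excluding",
    "nonzero_loading_genes",
]

#: loadings with absolute value at or below this are treated as structural
#: zeros (constant genes); generic PCA loadings are never exactly zero.
DEFAULT_EPSILON = 1e-12


@dataclass(frozen=True)
class PcaResult:
    """PCA of samples (observations) over genes (features).

    Features are mean-centered but not scaled to unit variance — the
    pipeline deliberately selects genes *by* variance, which scaling
    would erase. Per-component sign is fixed so the largest-magnitude
    gene loading is positive, making results reproducible across linear
    algebra backends.
    """

    sample_coords: np.ndarray  # samples x components
    gene_loadings: np.ndarray  # genes x components
    explained_variance_ratio: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.sample_coords.shape[1]


@dataclass(frozen=True)
class ComponentSpec:
    """Which principal components downstream scoring uses.

    ``first3`` keeps PC1-PC3 (batch-free, heterogeneous data); ``pc23``
    drops the batch-enriched PC1 and keeps PC2/PC3. ``components`` are
    the 1-based indices used both for coordinates and for the non-zero
    loading gene filter.
    """

    name: str
    components: tuple[int, ...]

    @classmethod
    def parse(cls, name: str) -> "ComponentSpec":
        specs = {"first3": (1, 2, 3), "pc23": (2, 3)}
        if name not in specs:
            raise ParameterError(f"unknown component spec {name!r}; valid: {sorted(specs)}")
        return cls(name, specs[name])

    @property
    def n_components_needed(self) -> int:
        return max(self.components)

    def coords(self, result: PcaResult) -> np.ndarray:
        drop = [i for i in range(1, self.n_components_needed + 1) if i not in self.components]
        return coords_excluding(result, drop, keep=len(self.components))


def select_high_variance_genes(m: ExpressionMatrix, fraction: float) -> frozenset[str]:
    """Top ``ceil(fraction * G)`` genes by across-sample variance.

    Ties broken deterministically by gene id (lexicographic).
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must be in (0,1], got {fraction}")
    k = math.ceil(fraction * m.n_genes)
    variances = m.values.var(axis=1)
    order = sorted(zip(-variances, m.gene_ids))
    return frozenset(g for _, g in order[:k])


def reduce_to_genes(m: ExpressionMatrix, genes: Iterable[str]) -> ExpressionMatrix:
    """Row-subset to ``genes``, preserving matrix gene and sample order."""
    return m.subset_genes(genes)


def pca_transform(m: ExpressionMatrix, n_components: int) -> PcaResult:
    """PCA with samples as observations and genes as mean-centered features."""
    max_comp = min(m.n_samples - 1, m.n_genes)
    if not 1 <= n_components <= max_comp:
        raise ParameterError(
            f"n_components must be in [1, {max_comp}] "
            f"for {m.n_samples} samples x {m.n_genes} genes, got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(m.values.T)
    loadings = pca.components_.T  # genes x components
    # sign convention: largest-|loading| gene positive in every component
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    return PcaResult(
        sample_coords=coords,
        gene_loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        gene_ids=tuple(m.gene_ids),
        sample_ids=tuple(m.sample_ids),
    )


def coords_excluding(
    result: PcaResult, drop: Sequence[int], keep: int
) -> np.ndarray:
    """Sample coordinates of the first ``keep`` components after dropping.

    ``drop`` holds 1-based component indices (e.g. ``[1]`` excludes the
    batch-enriched PC1, so ``keep=2`` returns PC2 and PC3).
    """
    drop_set = set(drop)
    for i in drop_set:
        if not 1 <= i <= result.n_components:
            raise ParameterError(f"component index {i} out of range")
    kept = [i for i in range(1, result.n_components + 1) if i not in drop_set]
    if keep < 1 or keep > len(kept):
        raise ParameterError(
            f"cannot keep {keep} components after dropping {sorted(drop_set)} "
            f"from {result.n_components}"
        )
    cols = [i - 1 for i in kept[:keep]]
    return result.sample_coords[:, cols]


def nonzero_loading_genes(
    result: PcaResult,
    components: Sequence[int],
    epsilon: float = DEFAULT_EPSILON,
) -> frozenset[str]:
    """Genes with |loading| > epsilon in at least one listed component.

    With the default epsilon only structurally zero loadings (constant
    genes) are removed; dense PCA loadings are otherwise never exactly
    zero.
    """
    for i in components:
        if not 1 <= i <= result.n_components:
            raise ParameterError(f"component index {i} out of range")
    cols = [i - 1 for i in components]
    mask = (np.abs(result.gene_loadings[:, cols]) > epsilon).any(axis=1)
    return frozenset(g for g, keep in zip(result.gene_ids, mask) if keep)
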