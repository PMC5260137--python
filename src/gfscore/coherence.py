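"""Pathway subnetwork coherence of high-variance gene sets.

Genes driving real biological variation tend to be wired together, so a
good preprocessing method should nominate high-variance genes that
induce large connected subnetworks on known pathways. The observed
induced-subnetwork size distribution is compared, size by size, against
a null built from uniformly random gene subsets of the same size; the
p-value at each size is the proportion of null iterations whose count
strictly exceeds the observed count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .decomposition import (
    DEFAULT_EPSILON,
    ComponentSpec,
    nonzero_loading_genes,
    pca_transform,
    select_high_variance_genes,
)
from .errors import ParameterError
from .io import ExpressionMatrix, PathwayCollection
from .normalize import Transform

__all__ = [
    "SubnetworkSizeDistribution",
    "CoherenceReport",
    "induce_subnetworks",
    "coherence_null",
    "size_pvalues",
    "coherence_pipeline",
]


@dataclass(frozen=True)
class SubnetworkSizeDistribution:
    """Counts of induced connected components (size >= 2) by size.

    Components are enumerated per pathway and aggregated across
    pathways; a gene present in two pathways can contribute to two
    components. Singletons are never counted.
    """

    counts: dict[int, int]

    @property
    def total_components(self) -> int:
        return sum(self.counts.values())

    @property
    def percentage_frequency(self) -> dict[int, float]:
        total = self.total_components
        if total == 0:
            return {}
        return {s: c / total for s, c in sorted(self.counts.items())}

    def count(self, size: int) -> int:
        return self.counts.get(size, 0)

    def to_dict(self) -> dict:
        return {
            "counts": {str(s): c for s, c in sorted(self.counts.items())},
            "percentage_frequency": {
                str(s): f for s, f in self.percentage_frequency.items()
            },
            "total_components": self.total_components,
        }


@dataclass(frozen=True)
class CoherenceReport:
    """Observed size distribution with per-size permutation p-values."""

    observed: SubnetworkSizeDistribution
    p_values: dict[int, float]
    null_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.to_dict(),
            "p_values": {str(s): p for s, p in sorted(self.p_values.items())},
            "null_iterations": self.null_iterations,
            "seed": self.seed,
        }


def induce_subnetworks(
    genes: Iterable[str], pathways: PathwayCollection
) -> SubnetworkSizeDistribution:
    """Size distribution of connected components induced by a gene set.

    For each pathway independently, take the subgraph induced by the
    genes, enumerate connected components, and count those of size >= 2;
    counts are aggregated across pathways by size.
    """
    genes = set(genes)
    counts: dict[int, int] = {}
    for pid in pathways.pathway_ids:
        sub = pathways.graphs[pid].subgraph(genes)
        for component in nx.connected_components(sub):
            if len(component) >= 2:
                counts[len(component)] = counts.get(len(component), 0) + 1
    return SubnetworkSizeDistribution(counts=counts)


def coherence_null(
    pathways: PathwayCollection,
    gene_universe: Sequence[str],
    gene_fraction: float = 0.15,
    n_iterations: int = 1000,
    seed: int = 0,
) -> list[SubnetworkSizeDistribution]:
    """Null size distributions from uniform random gene subsets.

    Each iteration draws ``ceil(gene_fraction * |universe|)`` genes
    uniformly without replacement from the expression matrix's gene
    universe (not the pathway universe) and induces subnetworks.
    """
    if not 0.0 < gene_fraction <= 1.0:
        raise ParameterError(f"gene fraction must be in (0,1], got {gene_fraction}")
    universe = np.array(sorted(gene_universe))
    if universe.size == 0:
        raise ParameterError("empty gene universe")
    k = math.ceil(gene_fraction * universe.size)
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_iterations):
        rng = np.random.default_rng(child)
        subset = rng.choice(universe, size=k, replace=False)
        out.append(induce_subnetworks(subset, pathways))
    return out


def size_pvalues(
    observed: SubnetworkSizeDistribution,
    null: Sequence[SubnetworkSizeDistribution],
    smoothing: bool = False,
) -> dict[int, float]:
    """Per-size permutation p-values against the null distributions.

    p(s) = #{iterations with count(s) > observed count(s)} / n. The
    strictly-greater rule makes p = 0 attainable; ``smoothing=True``
    applies add-one smoothing ((x+1)/(n+1)) for users wanting
    conservative nonzero p-values.
    """
    if len(null) == 0:
        raise ParameterError("null model needs at least one iteration")
    n = len(null)
    p_values: dict[int, float] = {}
    for size, obs_count in observed.counts.items():
        exceed = sum(1 for dist in null if dist.count(size) > obs_count)
        p_values[size] = (exceed + 1) / (n + 1) if smoothing else exceed / n
    return p_values


def coherence_pipeline(
    m: ExpressionMatrix,
    method: Transform | str,
    pathways: PathwayCollection,
    gene_fraction: float = 0.15,
    components: ComponentSpec | str = "first3",
    epsilon: float = DEFAULT_EPSILON,
    n_iterations: int = 1000,
    seed: int = 0,
    smoothing: bool = False,
) -> CoherenceReport:
    """Full coherence evaluation of one preprocessing method.

    Chain: normalize -> top-fraction variance genes -> reduce -> PCA ->
    keep genes with non-zero loadings on the specified components ->
    induce subnetworks. The null replaces the variance selection with
    uniform random gene subsets of the same size.
    """
    from .cluster_eval import _resolve_transform  # shared resolver

    spec = components if isinstance(components, ComponentSpec) else ComponentSpec.parse(components)
    transform = _resolve_transform(method)
    processed = transform(m)
    top = select_high_variance_genes(processed, gene_fraction)
    reduced = processed.subset_genes(top)
    needed = spec.n_components_needed
    n_comp = min(needed, reduced.n_samples - 1, reduced.n_genes)
    result = pca_transform(reduced, n_comp)
    usable = [c for c in spec.components if c <= n_comp]
    gene_list = top & nonzero_loading_genes(result, usable, epsilon)
    observed = induce_subnetworks(gene_list, pathways)
    null = coherence_null(
        pathways,
        gene_universe=m.gene_ids,
        gene_fraction=gene_fraction,
        n_iterations=n_iterations,
        seed=seed,
    )
    return CoherenceReport(
        observed=observed,
        p_values=size_pvalues(observed, null, smoothing=smoothing),
        null_iterations=n_iterations,
        seed=seed,
    )
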