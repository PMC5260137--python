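"""Phenotype-separation quality, split-half consistency, sample-size curves.

Quality is scored as the silhouette of the known phenotype labels over
PCA coordinates of a processed matrix — computed clusters are never
used; the question is how well the transform separates phenotypes. The
observed score (top-variance genes) is judged against a null
distribution built from random gene subsets of the same size.

Consistency asks whether two independently processed halves of a
dataset nominate the same high-variance genes, measured by the Jaccard
coefficient of the two gene lists over repeated stratified splits.

All randomized procedures derive one sub-seed per iteration from a
single master seed, so individual iterations are independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .decomposition import (
    DEFAULT_EPSILON,
    ComponentSpec,
    nonzero_loading_genes,
    pca_transform,
    select_high_variance_genes,
)
from .errors import EvaluationError, ParameterError, SplitError
from .io import ExpressionMatrix, SampleAnnotation
from .normalize import Transform

__all__ = [
    "SilhouetteReport",
    "ConsistencyReport",
    "SubsampleReport",
    "silhouette",
    "silhouette_null",
    "stratified_split",
    "consistency_jaccard",
    "subsample_performance",
    "jaccard",
]


@dataclass(frozen=True)
class SilhouetteReport:
    """Observed silhouette (top-variance genes) vs a random-gene null."""

    observed: float
    null_scores: np.ndarray
    n_iterations: int
    components_used: str

    @property
    def quartiles(self) -> tuple[float, float, float]:
        return tuple(np.percentile(self.null_scores, [25, 50, 75]))

    def to_dict(self) -> dict:
        q25, q50, q75 = self.quartiles
        return {
            "observed": self.observed,
            "null_quartiles": {"q25": q25, "median": q50, "q75": q75},
            "null_scores": self.null_scores.tolist(),
            "n_iterations": self.n_iterations,
            "components_used": self.components_used,
        }


@dataclass(frozen=True)
class ConsistencyReport:
    """Jaccard coefficients of top-variance gene lists across splits."""

    jaccard_values: np.ndarray
    n_splits: int

    def to_dict(self) -> dict:
        return {
            "jaccard_values": self.jaccard_values.tolist(),
            "median": float(np.median(self.jaccard_values)),
            "n_splits": self.n_splits,
        }


@dataclass(frozen=True)
class SubsampleReport:
    """Silhouette score vectors per subsampling fraction."""

    scores: dict[float, np.ndarray] = field(default_factory=dict)
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "scores": {str(f): v.tolist() for f, v in self.scores.items()},
            "medians": {str(f): float(np.median(v)) for f, v in self.scores.items()},
            "n_iterations": self.n_iterations,
        }


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 for two empty sets."""
    union = len(a | b)
    return 1.0 if union == 0 else len(a & b) / union


def silhouette(coords: np.ndarray, labels: Sequence) -> float:
    """Mean silhouette (b - a) / max(a, b) over samples, Euclidean distance.

    ``a`` is the mean intra-cluster distance, ``b`` the mean distance to
    the nearest other cluster; singleton-cluster samples contribute 0.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("silhouette needs at least 2 distinct labels")
    try:
        return float(silhouette_score(np.asarray(coords, dtype=float), labels))
    except ValueError as exc:
        raise EvaluationError(f"silhouette failed: {exc}") from exc


def _resolve_transform(method: Transform | str) -> Transform:
    if callable(method):
        return method
    from .normalize import get_transform

    return get_transform(method)


def _gene_count(n_genes: int, fraction: float) -> int:
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"gene fraction must be in (0,1], got {fraction}")
    return math.ceil(fraction * n_genes)


def _silhouette_for_genes(
    m: ExpressionMatrix,
    genes: frozenset[str],
    spec: ComponentSpec,
    labels: np.ndarray,
) -> float:
    reduced = m.subset_genes(genes)
    needed = spec.n_components_needed
    if needed > min(reduced.n_samples - 1, reduced.n_genes):
        raise EvaluationError(
            f"need {needed} principal components but matrix is "
            f"{reduced.n_genes} genes x {reduced.n_samples} samples"
        )
    result = pca_transform(reduced, needed)
    return silhouette(spec.coords(result), labels)


def silhouette_null(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    gene_fraction: float = 0.15,
    n_iterations: int = 1000,
    components: ComponentSpec | str = "first3",
    seed: int = 0,
) -> SilhouetteReport:
    """Observed vs null phenotype-silhouette for a processed matrix.

    ``m`` is an already-transformed matrix aligned with ``ann``. The
    observed score uses the top ``gene_fraction`` variance genes; each
    null iteration uses a uniform random gene subset of the same size.
    """
    spec = components if isinstance(components, ComponentSpec) else ComponentSpec.parse(components)
    labels = ann.phenotypes(m.sample_ids)
    k = _gene_count(m.n_genes, gene_fraction)
    observed = _silhouette_for_genes(
        m, select_high_variance_genes(m, gene_fraction), spec, labels
    )
    gene_ids = np.array(m.gene_ids)
    null_scores = np.empty(n_iterations)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_iterations)):
        rng = np.random.default_rng(child)
        subset = frozenset(rng.choice(gene_ids, size=k, replace=False))
        null_scores[i] = _silhouette_for_genes(m, subset, spec, labels)
    return SilhouetteReport(
        observed=observed,
        null_scores=null_scores,
        n_iterations=n_iterations,
        components_used=spec.name,
    )


def stratified_split(
    ann: SampleAnnotation, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Split samples into two halves with equal phenotype composition.

    Within each phenotype, samples are shuffled and divided as evenly as
    possible; for odd counts the extra sample goes to either half by a
    seeded coin flip. Every phenotype must have at least 2 samples.
    """
    rng = np.random.default_rng(seed)
    half_a: list[str] = []
    half_b: list[str] = []
    df = ann.data
    for phenotype in sorted(df["phenotype"].unique()):
        samples = [str(s) for s in df.index[df["phenotype"] == phenotype]]
        if len(samples) < 2:
            raise SplitError(f"phenotype {phenotype!r} has a single sample")
        rng.shuffle(samples)
        cut = len(samples) // 2
        if len(samples) % 2 == 1 and rng.integers(2) == 1:
            cut += 1
        half_a.extend(samples[:cut])
        half_b.extend(samples[cut:])
    return half_a, half_b


def _split_gene_list(
    m: ExpressionMatrix,
    transform: Transform,
    gene_fraction: float,
    spec: ComponentSpec,
    epsilon: float,
) -> frozenset[str]:
    """Top-variance genes of one half, filtered by non-zero PCA loadings."""
    processed = transform(m)
    top = select_high_variance_genes(processed, gene_fraction)
    reduced = processed.subset_genes(top)
    needed = spec.n_components_needed
    if needed > min(reduced.n_samples - 1, reduced.n_genes):
        raise EvaluationError("too few samples/genes for the component spec")
    result = pca_transform(reduced, needed)
    return top & nonzero_loading_genes(result, spec.components, epsilon)


def consistency_jaccard(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    method: Transform | str,
    gene_fraction: float = 0.15,
    n_splits: int = 100,
    components: ComponentSpec | str = "first3",
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
) -> ConsistencyReport:
    """Split-half consistency of the high-variance gene lists.

    Each repetition splits the samples stratified by phenotype,
    normalizes each half independently, extracts each half's
    top-variance genes with non-zero loadings on the specified
    components, and records the Jaccard coefficient of the two lists.
    """
    spec = components if isinstance(components, ComponentSpec) else ComponentSpec.parse(components)
    transform = _resolve_transform(method)
    values = np.empty(n_splits)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_splits)):
        half_a, half_b = stratified_split(ann, seed=child)
        genes_a = _split_gene_list(
            m.subset_samples(half_a), transform, gene_fraction, spec, epsilon
        )
        genes_b = _split_gene_list(
            m.subset_samples(half_b), transform, gene_fraction, spec, epsilon
        )
        values[i] = jaccard(genes_a, genes_b)
    return ConsistencyReport(jaccard_values=values, n_splits=n_splits)


def subsample_performance(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    method: Transform | str,
    fractions: Sequence[float] = (0.25, 0.5, 0.75),
    n_iterations: int = 100,
    gene_fraction: float = 0.15,
    components: ComponentSpec | str = "first3",
    seed: int = 0,
) -> SubsampleReport:
    """Silhouette of phenotype labels at reduced sample sizes.

    Per fraction and iteration: draw a phenotype-stratified subsample,
    normalize it, select top-variance genes, run PCA, and score the
    silhouette on the specified components.
    """
    spec = components if isinstance(components, ComponentSpec) else ComponentSpec.parse(components)
    transform = _resolve_transform(method)
    df = ann.data
    pheno_samples = {
        p: [str(s) for s in df.index[df["phenotype"] == p]]
        for p in sorted(df["phenotype"].unique())
    }
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ParameterError(f"fraction must be in (0,1], got {frac}")
        for p, samples in pheno_samples.items():
            if math.floor(frac * len(samples) + 0.5) < 2:
                raise ParameterError(
                    f"fraction {frac} leaves <2 samples of phenotype {p!r}"
                )
    scores: dict[float, np.ndarray] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(fractions))
    for frac, frac_seed in zip(fractions, seeds):
        vec = np.empty(n_iterations)
        for i, child in enumerate(frac_seed.spawn(n_iterations)):
            rng = np.random.default_rng(child)
            chosen: list[str] = []
            for p, samples in pheno_samples.items():
                k = math.floor(frac * len(samples) + 0.5)
                chosen.extend(rng.choice(samples, size=k, replace=False))
            sub = m.subset_samples([s for s in m.sample_ids if s in set(chosen)])
            processed = transform(sub)
            labels = ann.phenotypes(sub.sample_ids)
            vec[i] = _silhouette_for_genes(
                processed,
                select_high_variance_genes(processed, gene_fraction),
                spec,
                labels,
            )
        scores[frac] = vec
    return SubsampleReport(scores=scores, n_iterations=n_iterations)
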