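"""Within-sample preprocessing transforms.

The Gene Fuzzy Score (GFS) maps each gene's within-sample expression rank
to [0, 1] via two upper-quantile thresholds theta1 < theta2: genes ranked
in the top theta1 fraction score 1, genes below the top theta2 fraction
score 0, and ranks in between are linearly interpolated. Because only
ranks enter, the transform is invariant under any strictly increasing
distortion of a sample's intensities — the property that makes it robust
to batch- and platform-scale shifts.

Four standard comparator normalizations are provided: mean scaling,
median scaling, z-score standardization and quantile normalization,
plus a ``raw`` identity passthrough so evaluation pipelines can score
unprocessed data under the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import partial
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateSampleError, ParameterError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GfsParams",
    "rank_within_sample",
    "quantile_rank",
    "gfs_transform",
    "mean_scale",
    "median_scale",
    "zscore_normalize",
    "quantile_normalize",
    "raw_passthrough",
    "TRANSFORMS",
    "get_transform",
]

Transform = Callable[[ExpressionMatrix], ExpressionMatrix]


@dataclass(frozen=True)
class GfsParams:
    """Upper-quantile thresholds of the fuzzy score.

    theta1 : fraction of top-ranked genes scoring exactly 1 (default 0.05)
    theta2 : fraction below which the score is 0 (default 0.15)

    Requires 0 < theta1 < theta2 < 1.
    """

    theta1: float = 0.05
    theta2: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.theta1 < self.theta2 < 1.0):
            raise ParameterError(
                f"need 0 < theta1 < theta2 < 1, got {self.theta1}, {self.theta2}"
            )


def rank_within_sample(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks of one sample (rank G = highest value).

    Ties receive the mean of the ranks they span, so the rank sum is
    always G(G+1)/2 and the result is permutation-equivariant.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot rank an empty sample")
    return rankdata(values, method="average")


def quantile_rank(n_genes: int, theta: float) -> float:
    """Rank threshold of the upper ``theta`` quantile: (1 - theta) * G.

    Kept real-valued (never rounded) so the interpolation in the fuzzy
    score is exact and independent of any rounding convention.
    """
    if not 0.0 < theta < 1.0:
        raise ParameterError(f"theta must be in (0,1), got {theta}")
    if n_genes < 1:
        raise ParameterError(f"need at least one gene, got {n_genes}")
    return (1.0 - theta) * n_genes


def _gfs_scores(ranks: np.ndarray, n_genes: int, params: GfsParams) -> np.ndarray:
    q1 = quantile_rank(n_genes, params.theta1)
    q2 = quantile_rank(n_genes, params.theta2)
    # clip reproduces all three branches: >=1 iff r >= q1, <=0 iff r <= q2.
    return np.clip((ranks - q2) / (q1 - q2), 0.0, 1.0)


def gfs_transform(
    m: ExpressionMatrix, params: GfsParams | None = None
) -> ExpressionMatrix:
    """Apply the Gene Fuzzy Score sample by sample.

    Each sample's values are replaced by scores in [0, 1] computed from
    the within-sample ascending ranks r and the quantile boundary ranks
    q(theta) = (1 - theta) * G:

    * score 1        where r >= q(theta1),
    * (r - q(theta2)) / (q(theta1) - q(theta2))
                     where q(theta2) <= r < q(theta1),
    * score 0        where r < q(theta2).

    A constant sample (all intensities tied) is transformed literally —
    all genes share the tied mid-rank and hence one score — with a
    logged warning.
    """
    params = params or GfsParams()
    if m.n_genes < 2:
        raise ParameterError("GFS needs at least 2 genes per sample")
    values = m.values
    constant = np.ptp(values, axis=0) == 0
    if constant.any():
        names = [s for s, c in zip(m.sample_ids, constant) if c]
        logger.warning("constant sample(s), all scores equal: %s", names[:5])
    ranks = rankdata(values, method="average", axis=0)
    return m.with_values(_gfs_scores(ranks, m.n_genes, params))


def mean_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so its mean equals the grand mean of sample means."""
    values = m.values
    means = values.mean(axis=0)
    if np.any(means == 0):
        bad = [s for s, mu in zip(m.sample_ids, means) if mu == 0]
        raise DegenerateSampleError(f"zero-mean sample(s): {bad[:5]}")
    grand = means.mean()
    return m.with_values(values * (grand / means))


def median_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift-free scaling equalizing sample medians to their grand mean."""
    values = m.values
    medians = np.median(values, axis=0)
    if np.any(medians == 0):
        bad = [s for s, md in zip(m.sample_ids, medians) if md == 0]
        raise DegenerateSampleError(f"zero-median sample(s): {bad[:5]}")
    grand = medians.mean()
    return m.with_values(values * (grand / medians))


def zscore_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each sample to mean 0 and (population) sd 1."""
    values = m.values
    means = values.mean(axis=0)
    sds = values.std(axis=0)  # population (divide-by-n) sd, pinned by tests
    if np.any(sds == 0):
        bad = [s for s, sd in zip(m.sample_ids, sds) if sd == 0]
        raise DegenerateSampleError(f"constant sample(s): {bad[:5]}")
    return m.with_values((values - means) / sds)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples onto the cross-sample rank-mean distribution.

    Samples are sorted; the reference distribution is the mean across
    samples at each sorted position; each value is then replaced by the
    reference value at its within-sample rank. Ties receive the mean of
    the reference values their tied ranks span.
    """
    values = m.values
    n_genes = m.n_genes
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    rows = np.arange(n_genes)
    for j in range(m.n_samples):
        col = np.empty(n_genes)
        col[order[:, j]] = reference
        # average reference over each tie group (mean over the rank span)
        uniq, inverse, counts = np.unique(
            values[:, j], return_inverse=True, return_counts=True
        )
        if len(uniq) < n_genes:
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, col)
            col = (sums / counts)[inverse]
        out[rows, j] = col
    return m.with_values(out)


def raw_passthrough(m: ExpressionMatrix) -> ExpressionMatrix:
    """Identity transform — lets pipelines score unprocessed expression."""
    return m


TRANSFORMS: dict[str, Transform] = {
    "raw": raw_passthrough,
    "gfs": gfs_transform,
    "mean": mean_scale,
    "median": median_scale,
    "zscore": zscore_normalize,
    "quantile": quantile_normalize,
}


def get_transform(method: str, params: GfsParams | None = None) -> Transform:
    """Look up a transform by name; ``params`` applies to ``gfs`` only."""
    if method not in TRANSFORMS:
        raise ParameterError(
            f"unknown method {method!r}; valid: {sorted(TRANSFORMS)}"
        )
    if method == "gfs":
        return partial(gfs_transform, params=params or GfsParams())
    return TRANSFORMS[method]
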