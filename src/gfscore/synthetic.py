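"""Synthetic expression data with planted phenotype, batch and pathway structure.

The generator emulates the regime the evaluation framework is built for:
multi-phenotype microarray-style intensities with

* log-normal gene baselines (abundances span orders of magnitude),
* a subset of differentially expressed (DE) genes per non-reference
  phenotype, shifted by a multiplicative fold change,
* an independent per-gene multiplicative batch distortion mimicking
  platform-scale systematic biases uncorrelated with biology,
* multiplicative measurement noise whose coefficient of variation is
  larger for low-abundance genes,
* pathway graphs containing connected modules that overlap the DE truth
  set, plus background pathways over non-DE genes.

DE genes are drawn from the mid-abundance band (default 50th-85th
baseline percentile): planted markers are genes moderately expressed in
the reference phenotype that the fold change lifts into the top of the
within-sample ranking — the induced-marker regime. Genes already
saturating the top ranks in every sample, or buried in the noisy
low-abundance tail, are by construction invisible to any rank-based
score and make no sense as planted signal. All randomness derives
from ``SimulationConfig.seed``; identical configs give byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .errors import ParameterError
from .io import ExpressionMatrix, PathwayCollection, SampleAnnotation

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_pathways",
    "simulate",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator (defaults are the reference conditions).

    groups : (phenotype, batch, n_samples) cells of the design. The
        first phenotype to appear is the reference; every other
        phenotype receives its own disjoint DE gene set.
    effect_size : multiplicative fold change of DE genes in their
        phenotype (1.0 = no phenotype signal).
    batch_effect_size : sd of the per-gene log batch factor (0 = none).
    baseline_log_mean / baseline_log_sd : natural-log scale of gene
        baselines.
    noise_log_sd : base sd of the multiplicative log-normal noise for
        the most abundant genes.
    cv_low_expression_multiplier : factor by which the noise sd grows
        toward the lowest-abundance genes (linearly in abundance rank).
    sample_scale_log_sd : sd of the per-array overall intensity scale
        factor (arrays differ in brightness; the obscuring variation
        scaling normalizations exist to remove).
    de_baseline_band : abundance-rank percentile band DE genes are drawn
        from.
    """

    n_genes: int = 1000
    groups: tuple[tuple[str, str, int], ...] = (
        ("control", "b1", 10),
        ("control", "b2", 10),
        ("disease", "b1", 10),
        ("disease", "b2", 10),
    )
    de_fraction: float = 0.10
    effect_size: float = 8.0
    batch_effect_size: float = 1.0
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.25
    cv_low_expression_multiplier: float = 3.0
    sample_scale_log_sd: float = 0.4
    de_baseline_band: tuple[float, float] = (0.50, 0.85)
    n_modules: int = 8
    module_size: int = 10
    module_de_overlap: float = 1.0
    n_background_pathways: int = 12
    background_pathway_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ParameterError("need at least 10 genes")
        if not self.groups:
            raise ParameterError("need at least one design group")
        counts: dict[str, int] = {}
        for phenotype, batch, n in self.groups:
            if n < 1:
                raise ParameterError(f"group ({phenotype},{batch}) has {n} samples")
            counts[phenotype] = counts.get(phenotype, 0) + n
        if any(n < 2 for n in counts.values()):
            raise ParameterError("every phenotype needs at least 2 samples")
        if not 0.0 < self.de_fraction < 1.0:
            raise ParameterError("de_fraction must be in (0,1)")
        if self.effect_size <= 0:
            raise ParameterError("effect_size must be > 0")
        if self.batch_effect_size < 0:
            raise ParameterError("batch_effect_size must be >= 0")
        if self.sample_scale_log_sd < 0:
            raise ParameterError("sample_scale_log_sd must be >= 0")
        if not 0.0 <= self.module_de_overlap <= 1.0:
            raise ParameterError("module_de_overlap must be in [0,1]")
        lo, hi = self.de_baseline_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ParameterError("de_baseline_band must satisfy 0 <= lo < hi <= 1")

    @property
    def phenotype_order(self) -> list[str]:
        seen: list[str] = []
        for phenotype, _, _ in self.groups:
            if phenotype not in seen:
                seen.append(phenotype)
        return seen

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generator."""

    de_genes: dict[str, frozenset[str]]  # phenotype -> DE gene set
    batch_affected: frozenset[str]
    modules: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def all_de_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.de_genes.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: ExpressionMatrix
    annotation: SampleAnnotation
    truth: SyntheticTruth
    pathways: PathwayCollection | None = None


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset from the configured generative model.

    value(g, j) = baseline(g) * fold(g, phenotype(j)) * batch_factor(g,
    batch(j)) * exp(N(0, sigma(g))), with sigma decreasing linearly in
    the gene's abundance rank from ``noise_log_sd * multiplier`` down to
    ``noise_log_sd``. All values are strictly positive.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array(cfg.gene_ids())
    n_genes = cfg.n_genes

    log_baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_genes)
    baseline = np.exp(log_baseline)
    # 0 = least abundant gene, 1 = most abundant
    rank_frac = (rankdata(log_baseline) - 1) / max(n_genes - 1, 1)

    lo, hi = cfg.de_baseline_band
    band = np.flatnonzero((rank_frac >= lo) & (rank_frac < hi))
    n_de = math.ceil(cfg.de_fraction * n_genes)
    case_phenotypes = cfg.phenotype_order[1:]
    if n_de * len(case_phenotypes) > band.size:
        raise ParameterError(
            f"{n_de} DE genes per phenotype x {len(case_phenotypes)} phenotypes "
            f"exceed the {band.size}-gene abundance band"
        )
    pool = rng.permutation(band)
    de_idx = {
        p: np.sort(pool[i * n_de : (i + 1) * n_de])
        for i, p in enumerate(case_phenotypes)
    }

    batches = sorted({batch for _, batch, _ in cfg.groups})
    batch_log = {
        b: (
            rng.normal(0.0, cfg.batch_effect_size, n_genes)
            if cfg.batch_effect_size > 0
            else np.zeros(n_genes)
        )
        for b in batches
    }

    sample_ids: list[str] = []
    phenotype_of: list[str] = []
    batch_of: list[str] = []
    for phenotype, batch, n in cfg.groups:
        for _ in range(n):
            sample_ids.append(f"s{len(sample_ids):03d}")
            phenotype_of.append(phenotype)
            batch_of.append(batch)
    n_samples = len(sample_ids)

    sigma = cfg.noise_log_sd * (
        cfg.cv_low_expression_multiplier
        - (cfg.cv_low_expression_multiplier - 1.0) * rank_frac
    )
    noise = np.exp(rng.normal(0.0, 1.0, (n_genes, n_samples)) * sigma[:, None])
    scale = (
        np.exp(rng.normal(0.0, cfg.sample_scale_log_sd, n_samples))
        if cfg.sample_scale_log_sd > 0
        else np.ones(n_samples)
    )

    values = baseline[:, None] * noise * scale[None, :]
    for j in range(n_samples):
        values[:, j] *= np.exp(batch_log[batch_of[j]])
        idx = de_idx.get(phenotype_of[j])
        if idx is not None and cfg.effect_size != 1.0:
            values[idx, j] *= cfg.effect_size

    matrix = ExpressionMatrix.from_arrays(gene_ids, sample_ids, values)
    annotation = SampleAnnotation.from_mapping(
        {s: (p, b) for s, p, b in zip(sample_ids, phenotype_of, batch_of)}
    )
    truth = SyntheticTruth(
        de_genes={p: frozenset(gene_ids[idx]) for p, idx in de_idx.items()},
        batch_affected=(
            frozenset(gene_ids) if cfg.batch_effect_size > 0 else frozenset()
        ),
    )
    return SyntheticDataset(matrix=matrix, annotation=annotation, truth=truth)


def _connected_module(nodes: Sequence[str], rng: np.random.Generator) -> nx.Graph:
    """Random spanning tree plus len(nodes)//2 extra edges; no self-loops."""
    nodes = list(nodes)
    rng.shuffle(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(1, len(nodes)):
        g.add_edge(nodes[i], nodes[int(rng.integers(i))])
    extra = len(nodes) // 2
    attempts = 0
    while extra > 0 and attempts < 20 * len(nodes):
        a, b = rng.choice(len(nodes), size=2, replace=False)
        if not g.has_edge(nodes[a], nodes[b]):
            g.add_edge(nodes[a], nodes[b])
            extra -= 1
        attempts += 1
    return g


def generate_pathways(
    cfg: SimulationConfig, de_genes: frozenset[str]
) -> tuple[PathwayCollection, dict[str, frozenset[str]]]:
    """Pathway graphs with modules overlapping the DE truth set.

    Each module is a connected graph whose node set overlaps
    ``de_genes`` by ``cfg.module_de_overlap``; module node sets are
    mutually disjoint. Background pathways are drawn from non-DE genes.
    Returns the collection and the module membership map.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    gene_ids = cfg.gene_ids()
    de_sorted = np.array(sorted(de_genes))
    non_de = np.array([g for g in gene_ids if g not in de_genes])

    n_de_nodes = round(cfg.module_de_overlap * cfg.module_size)
    n_other = cfg.module_size - n_de_nodes
    if cfg.n_modules * n_de_nodes > de_sorted.size:
        raise ParameterError(
            f"{cfg.n_modules} modules x {n_de_nodes} DE nodes exceed "
            f"{de_sorted.size} DE genes"
        )
    if cfg.n_modules * n_other > non_de.size:
        raise ParameterError("not enough non-DE genes for module padding")

    de_pool = rng.permutation(de_sorted)
    other_pool = rng.permutation(non_de)
    graphs: dict[str, nx.Graph] = {}
    modules: dict[str, frozenset[str]] = {}
    for m in range(cfg.n_modules):
        nodes = list(de_pool[m * n_de_nodes : (m + 1) * n_de_nodes]) + list(
            other_pool[m * n_other : (m + 1) * n_other]
        )
        pid = f"module{m:02d}"
        graphs[pid] = _connected_module(nodes, rng)
        modules[pid] = frozenset(nodes)

    bg_pool = other_pool[cfg.n_modules * n_other :]
    if cfg.background_pathway_size > bg_pool.size:
        raise ParameterError("not enough non-DE genes for background pathways")
    for b in range(cfg.n_background_pathways):
        nodes = rng.choice(bg_pool, size=cfg.background_pathway_size, replace=False)
        graphs[f"bg{b:02d}"] = _connected_module(list(nodes), rng)

    return PathwayCollection(graphs), modules


def simulate(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a dataset together with its pathway collection."""
    ds = generate_dataset(cfg)
    pathways, modules = generate_pathways(cfg, ds.truth.all_de_genes)
    truth = SyntheticTruth(
        de_genes=ds.truth.de_genes,
        batch_affected=ds.truth.batch_affected,
        modules=modules,
    )
    return SyntheticDataset(
        matrix=ds.matrix, annotation=ds.annotation, truth=truth, pathways=pathways
    )


_PRESETS: dict[str, SimulationConfig] = {
    # two phenotypes crossed with two batches; planted fold change + batch shift
    "two-batch": SimulationConfig(),
    # mirrors a merged two-study muscular dystrophy design (12+12 vs 22+14
    # across two platforms) at reduced gene count
    "dmd-like": SimulationConfig(
        groups=(
            ("DMD", "study1", 12),
            ("control", "study1", 12),
            ("DMD", "study2", 22),
            ("control", "study2", 14),
        ),
    ),
    # several disease subtypes, single batch: the heterogeneous regime
    # where all first three components carry biology
    "heterogeneous": SimulationConfig(
        groups=(
            ("normal", "b1", 8),
            ("subtypeA", "b1", 8),
            ("subtypeB", "b1", 8),
            ("subtypeC", "b1", 8),
        ),
        de_fraction=0.06,
        batch_effect_size=0.0,
    ),
    # calibration control: no phenotype signal, no batch shift
    "no-signal": SimulationConfig(effect_size=1.0, batch_effect_size=0.0),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """A named reference configuration with the given seed."""
    if name not in _PRESETS:
        raise ParameterError(f"unknown preset {name!r}; valid: {sorted(_PRESETS)}")
    return replace(_PRESETS[name], seed=seed)
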