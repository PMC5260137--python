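"""Containers and TSV I/O for expression matrices, annotations and pathways.

Formats (UTF-8, Unix newlines, ``#``-prefixed comment lines skipped):

* expression: ``gene_id<TAB>sample1<TAB>sample2...``, one gene per row;
* annotation: columns ``sample_id``, ``phenotype``, ``batch``;
* pathways:   columns ``pathway_id``, ``gene_a``, ``gene_b`` (undirected
  edge list; duplicate edges collapse, self-loops are dropped with a
  warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError, IdentifierError, ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "PathwayCollection",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "align_annotation",
    "read_pathways",
    "write_pathways",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of finite real intensities.

    ``data`` is indexed by gene id (rows) and sample id (columns). Both
    axes must be unique; values must be finite. The container is treated
    as immutable: transforms return new instances.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample ids: {dupes[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            raise ParseError("expression matrix contains NaN/Inf entries")

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index([str(g) for g in gene_ids], name="gene_id"),
            columns=[str(s) for s in sample_ids],
        )
        return cls(df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same gene/sample ids, new values (shape must match)."""
        if values.shape != self.data.shape:
            raise ValueError(f"shape {values.shape} != {self.data.shape}")
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row subset, preserving this matrix's gene order."""
        wanted = set(gene_ids)
        if not wanted:
            raise IdentifierError("empty gene subset")
        unknown = wanted.difference(self.data.index)
        if unknown:
            raise IdentifierError(f"unknown gene ids: {sorted(unknown)[:5]}")
        keep = [g for g in self.data.index if g in wanted]
        return ExpressionMatrix(self.data.loc[keep])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        """Column subset in the given order."""
        sample_ids = list(sample_ids)
        unknown = set(sample_ids).difference(self.data.columns)
        if unknown:
            raise IdentifierError(f"unknown sample ids: {sorted(unknown)[:5]}")
        return ExpressionMatrix(self.data[sample_ids])


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample phenotype and batch labels, indexed by sample id."""

    data: pd.DataFrame  # index: sample_id; columns: phenotype, batch

    def __post_init__(self) -> None:
        df = self.data
        for col in ("phenotype", "batch"):
            if col not in df.columns:
                raise SchemaError(f"annotation missing column {col!r}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample ids: {dupes[:5]}")
        for col in ("phenotype", "batch"):
            labels = df[col].astype(str)
            if (labels.str.len() == 0).any():
                raise SchemaError(f"empty {col} label")

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[str, str]]
    ) -> "SampleAnnotation":
        df = pd.DataFrame.from_dict(
            {s: {"phenotype": p, "batch": b} for s, (p, b) in mapping.items()},
            orient="index",
        )
        df.index.name = "sample_id"
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def phenotypes(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return self.data.loc[ids, "phenotype"].to_numpy()

    def batches(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return self.data.loc[ids, "batch"].to_numpy()

    def subset(self, sample_ids: Iterable[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class PathwayCollection:
    """Named undirected graphs over gene identifiers."""

    graphs: dict[str, nx.Graph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, g in self.graphs.items():
            if g.number_of_edges() == 0:
                raise ParseError(f"pathway {pid!r} has no edges")
            loops = list(nx.selfloop_edges(g))
            if loops:
                raise ParseError(f"pathway {pid!r} has self-loops: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, str]]
    ) -> "PathwayCollection":
        """Build from (pathway_id, gene_a, gene_b) triples.

        Duplicate edges (in either orientation) collapse; self-loops are
        dropped with a logged warning.
        """
        graphs: dict[str, nx.Graph] = {}
        for pid, a, b in edges:
            if a == b:
                logger.warning("dropping self-loop %s-%s in pathway %s", a, b, pid)
                continue
            graphs.setdefault(pid, nx.Graph()).add_edge(a, b)
        graphs = {pid: g for pid, g in graphs.items() if g.number_of_edges() > 0}
        return cls(graphs)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.graphs)

    @property
    def gene_universe(self) -> frozenset[str]:
        genes: set[str] = set()
        for g in self.graphs.values():
            genes.update(g.nodes)
        return frozenset(genes)

    def edges(self) -> list[tuple[str, str, str]]:
        out = []
        for pid in sorted(self.graphs):
            for a, b in sorted(tuple(sorted(e)) for e in self.graphs[pid].edges):
                out.append((pid, a, b))
        return out


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV, preserving file order."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric expression cell in {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        raise ParseError(f"missing expression cells in {path}")
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path, sig_digits: int = 6) -> None:
    """Write an expression TSV with ``sig_digits`` significant digits."""
    m.data.to_csv(path, sep="\t", float_format=f"%.{sig_digits}g")


def read_annotation(path) -> SampleAnnotation:
    """Read a sample annotation TSV (sample_id, phenotype, batch)."""
    df = _read_tsv(path, dtype=str)
    required = {"sample_id", "phenotype", "batch"}
    missing = required.difference(df.columns)
    if missing:
        raise SchemaError(f"annotation {path} missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    return SampleAnnotation(df[["phenotype", "batch"]])


def write_annotation(a: SampleAnnotation, path) -> None:
    a.data.to_csv(path, sep="\t", index_label="sample_id")


def align_annotation(
    m: ExpressionMatrix, a: SampleAnnotation
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Restrict both to their shared samples, in matrix column order."""
    shared = [s for s in m.sample_ids if s in set(a.sample_ids)]
    if not shared:
        raise AlignmentError("expression matrix and annotation share no samples")
    return m.subset_samples(shared), a.subset(shared)


def read_pathways(path) -> PathwayCollection:
    """Read an undirected pathway edge list TSV."""
    df = _read_tsv(path, dtype=str)
    required = {"pathway_id", "gene_a", "gene_b"}
    missing = required.difference(df.columns)
    if missing:
        raise SchemaError(f"pathway file {path} missing columns: {sorted(missing)}")
    bad = df[df[["pathway_id", "gene_a", "gene_b"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError(f"malformed pathway row at line {bad.index[0] + 2} of {path}")
    return PathwayCollection.from_edges(
        df[["pathway_id", "gene_a", "gene_b"]].itertuples(index=False, name=None)
    )


def write_pathways(p: PathwayCollection, path) -> None:
    pd.DataFrame(p.edges(), columns=["pathway_id", "gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )
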