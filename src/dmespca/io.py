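"""Input/output for expression matrices, gene networks and subtype labels.

All three inputs are plain tab-separated text:

* expression — header row of sample ids, first column gene (probe) ids,
  remaining cells log2 intensities;
* network — SIF (``geneA<TAB>relation<TAB>geneB``) or a two-column edge
  list;
* labels — two columns, ``sample_id<TAB>subtype``.

Gene identifiers are opaque strings (typically probe ids); no probe→symbol
mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SubtypeLabels",
    "GeneNetwork",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_labels",
    "write_labels",
    "filter_low_intensity",
    "reconcile",
]


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix of log2 intensities.

    Rows are genes (probes), columns are samples. Identifiers must be
    unique, the matrix must be at least 2×2 and all values finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        m, n = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (m, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{m} genes x {n} samples"
            )
        if m < 2 or n < 2:
            raise ValueError("expression matrix must be at least 2 genes x 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes``, preserving the current row order."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        if len(idx) < 2:
            raise ValueError("gene subset leaves fewer than 2 genes")
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
        )


@dataclass
class SubtypeLabels:
    """Sample → subtype assignment with a fixed subtype order."""

    assignments: dict[str, str]
    subtype_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subtype_order:
            # first-appearance order is deterministic for a dict
            self.subtype_order = list(dict.fromkeys(self.assignments.values()))
        _check_unique(self.subtype_order, "subtype")
        extra = set(self.assignments.values()) - set(self.subtype_order)
        if extra:
            raise ValueError(f"labels use subtypes missing from subtype_order: {sorted(extra)}")

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_order)

    def samples_of(self, subtype: str) -> list[str]:
        if subtype not in self.subtype_order:
            raise KeyError(f"unknown subtype {subtype!r}")
        return [s for s, p in self.assignments.items() if p == subtype]

    def validate_against(self, X: ExpressionMatrix) -> None:
        missing = [s for s in X.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without a subtype label: {missing[:5]}")
        for p in self.subtype_order:
            n_p = sum(1 for s in X.sample_ids if self.assignments.get(s) == p)
            if n_p < 2:
                raise ValueError(f"subtype {p!r} has fewer than 2 samples")

    def as_array(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.assignments[s] for s in sample_ids], dtype=object)


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """An undirected, simple gene interaction network stored as an edge set."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        canon = sorted({_canonical_edge(a, b) for a, b in self.edges})
        for a, b in canon:
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
        self.edges = canon

    @property
    def vertices(self) -> list[str]:
        vs: set[str] = set()
        for a, b in self.edges:
            vs.add(a)
            vs.add(b)
        return sorted(vs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_index_array(self, gene_ids: list[str]) -> np.ndarray:
        """Edges as an (E, 2) int array of positions into ``gene_ids``.

        Every vertex must be present in ``gene_ids`` (run :func:`reconcile`
        first). Row order matches ``self.edges`` (lexicographic).
        """
        pos = {g: i for i, g in enumerate(gene_ids)}
        try:
            return np.array([(pos[a], pos[b]) for a, b in self.edges], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - guarded by reconcile
            raise ValueError(f"network vertex {exc.args[0]!r} missing from gene ids") from exc


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (header = sample ids, column 1 = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r} in {path}")
    if pd.Index(df.columns).has_duplicates:
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                i = int(np.argmax(bad.isna().to_numpy()))
                raise ValueError(
                    f"non-numeric cell at gene {df.index[i]!r}, sample {col!r} in {path}"
                ) from None
        raise
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(X: ExpressionMatrix, path: str | Path, precision: int = 6) -> None:
    X.to_frame().to_csv(path, sep="\t", float_format=f"%.{precision}g")


def read_network(path: str | Path, dialect: Literal["sif", "two_column"] = "sif") -> GeneNetwork:
    """Read an undirected edge list, deduplicating and dropping self-loops."""
    n_fields = 3 if dialect == "sif" else 2
    raw: list[tuple[str, str]] = []
    n_self = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_fields} tab-separated fields "
                    f"({dialect} dialect), got {len(parts)}"
                )
            a, b = (parts[0], parts[2]) if dialect == "sif" else (parts[0], parts[1])
            if a == b:
                n_self += 1
                continue
            raw.append(_canonical_edge(a, b))
    if not raw:
        raise ValueError(f"{path}: no edges found")
    dedup = sorted(set(raw))
    n_dup = len(raw) - len(dedup)
    if n_self or n_dup:
        logger.info(
            "read_network(%s): dropped %d self-loop(s), collapsed %d duplicate(s)",
            path, n_self, n_dup,
        )
    return GeneNetwork(edges=dedup)


def write_network(G: GeneNetwork, path: str | Path, dialect: Literal["sif", "two_column"] = "two_column") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in G.edges:
            if dialect == "sif":
                fh.write(f"{a}\tinteracts\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_labels(path: str | Path) -> SubtypeLabels:
    """Read a two-column ``sample_id<TAB>subtype`` table (no header)."""
    assignments: dict[str, str] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            sample, subtype = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            assignments[sample] = subtype
            if subtype not in order:
                order.append(subtype)
    if not assignments:
        raise ValueError(f"{path}: no labels found")
    return SubtypeLabels(assignments=assignments, subtype_order=order)


def write_labels(labels: SubtypeLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, subtype in labels.assignments.items():
            fh.write(f"{sample}\t{subtype}\n")


# ---------------------------------------------------------------------------
# preprocessing


def filter_low_intensity(
    X: ExpressionMatrix,
    threshold: float = 4.0,
    aggregator: Literal["max", "mean"] = "max",
) -> ExpressionMatrix:
    """Drop probes whose aggregated log2 intensity is below ``threshold``.

    With the default ``max`` aggregator a probe is removed only if it never
    reaches the threshold in any sample — the least destructive reading of a
    minimum-intensity filter. ``mean`` drops probes on their average level.
    Survivor order is preserved.
    """
    agg = X.values.max(axis=1) if aggregator == "max" else X.values.mean(axis=1)
    keep = agg >= threshold
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"filter_low_intensity removed all {X.n_genes} genes at threshold "
            f"{threshold}; lower the threshold"
        )
    logger.info("filter_low_intensity: removed %d of %d genes", n_removed, X.n_genes)
    if n_removed == 0:
        return X
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        gene_ids=[X.gene_ids[i] for i in idx],
        sample_ids=list(X.sample_ids),
        values=X.values[idx, :],
    )


def reconcile(
    X: ExpressionMatrix,
    G: GeneNetwork,
    strict: bool = True,
) -> tuple[ExpressionMatrix, GeneNetwork]:
    """Restrict expression and network to their common gene set.

    Edges with an endpoint absent from ``X`` are dropped. In strict mode
    (default) genes of ``X`` absent from the surviving network are dropped
    too, since edge-group selection can never pick them; lenient mode keeps
    them. Idempotent.
    """
    genes = set(X.gene_ids)
    kept_edges = [e for e in G.edges if e[0] in genes and e[1] in genes]
    if not kept_edges:
        raise ValueError("expression matrix and network share no usable edges")
    G2 = GeneNetwork(edges=kept_edges)
    if strict:
        X2 = X.subset_genes(G2.vertices)
    else:
        X2 = X
    return X2, G2
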