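"""Per-subtype gene weights and dynamic edge weights.

For each subtype p and gene i a Welch two-sample statistic

    t_pi = (mean_in - mean_out) / sqrt(s_in^2/n_in + s_out^2/n_out)

is computed on the meta-data samples (in-group = subtype p's meta samples,
out-group = every other subtype's meta samples). Its magnitude becomes the
gene's subtype-relevance weight, and an edge e_h = (i, j) of the base
network is weighted

    w_ph(z) = sqrt(t_pi * z_i^2 + t_pj * z_j^2)

where z is the current loading direction during projection. With unit
gene weights this collapses to the static edge weight
sqrt(z_i^2 + z_j^2) of plain edge-group sparse PCA. The gene weights are
computed once per subtype and frozen; the "dynamic" part is the per-z
edge weighting evaluated inside every projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import ExpressionMatrix, GeneNetwork, SubtypeLabels
from .metadata import MetaSelection

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeWeightedNetwork",
    "welch_statistic",
    "gene_weights",
    "edge_weight_static",
    "edge_weight_dynamic",
    "edge_weights_array",
    "build_subtype_networks",
]


def welch_statistic(values_in: Sequence[float], values_out: Sequence[float]) -> float:
    """Welch two-sample t statistic (sample variance, unpooled).

    Antisymmetric under swapping the groups. Both groups need >= 2
    observations. If both groups are constant (zero denominator) the
    statistic is defined as 0 and a warning is logged.
    """
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_statistic needs at least 2 observations per group")
    denom = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if denom == 0.0:
        logger.warning("welch_statistic: both groups constant; returning 0")
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def gene_weights(
    X: ExpressionMatrix,
    labels: SubtypeLabels,
    meta: MetaSelection,
    subtype: str,
    transform: Literal["abs", "square"] = "abs",
) -> dict[str, float]:
    """Nonnegative subtype-relevance weight per gene.

    In-group: the subtype's meta samples; out-group: all other subtypes'
    meta samples. ``transform`` maps the signed statistic to a weight
    (|t| by default, t^2 as a monotone alternative — down-regulation is
    as informative as up-regulation either way).
    """
    if subtype not in labels.subtype_order:
        raise KeyError(f"unknown subtype {subtype!r}")
    in_ids = meta.selected[subtype]
    out_ids = [s for p in labels.subtype_order if p != subtype for s in meta.selected[p]]
    if len(in_ids) < 2 or len(out_ids) < 2:
        raise ValueError("meta selection leaves fewer than 2 samples in a group")
    col = {s: j for j, s in enumerate(X.sample_ids)}
    A = X.values[:, [col[s] for s in in_ids]]
    B = X.values[:, [col[s] for s in out_ids]]
    denom = A.var(axis=1, ddof=1) / A.shape[1] + B.var(axis=1, ddof=1) / B.shape[1]
    diff = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.sqrt(denom), 0.0)
    n_degenerate = int((denom == 0).sum())
    if n_degenerate:
        logger.warning(
            "gene_weights(%s): %d zero-variance gene(s) given weight 0",
            subtype, n_degenerate,
        )
    w = np.abs(t) if transform == "abs" else t**2
    return dict(zip(X.gene_ids, (float(x) for x in w)))


def edge_weight_static(z_i: float, z_j: float) -> float:
    """Static edge weight: Euclidean norm of the two endpoint loadings."""
    return float(np.hypot(z_i, z_j))


def edge_weight_dynamic(t_i: float, t_j: float, z_i: float, z_j: float) -> float:
    """Dynamic edge weight sqrt(t_i z_i^2 + t_j z_j^2); t's must be >= 0."""
    if t_i < 0 or t_j < 0:
        raise ValueError("gene weights must be nonnegative (apply abs/square first)")
    return float(np.sqrt(t_i * z_i**2 + t_j * z_j**2))


def edge_weights_array(
    z: np.ndarray,
    edge_index: np.ndarray,
    t: np.ndarray | None = None,
    edge_norm: Literal["sqrt", "sumsq"] = "sqrt",
) -> np.ndarray:
    """Vectorised edge weights for all edges at the current direction z.

    ``edge_index`` is an (E, 2) int array of gene positions; ``t`` the
    per-gene nonnegative weight vector (None = unit weights, i.e. the
    static weighting). ``sumsq`` skips the final square root — a monotone
    relabelling that leaves static rankings unchanged but interacts with
    nonunit ``t``.
    """
    zi2 = z[edge_index[:, 0]] ** 2
    zj2 = z[edge_index[:, 1]] ** 2
    if t is None:
        s = zi2 + zj2
    else:
        s = t[edge_index[:, 0]] * zi2 + t[edge_index[:, 1]] * zj2
    return np.sqrt(s) if edge_norm == "sqrt" else s


@dataclass
class SubtypeWeightedNetwork:
    """A subtype's frozen gene weights over a shared base network."""

    subtype: str
    gene_weights: dict[str, float]
    base_edges: GeneNetwork
    weight_transform: Literal["abs", "square"] = "abs"
    _t_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for v in self.base_edges.vertices:
            if v not in self.gene_weights:
                raise ValueError(f"network vertex {v!r} has no gene weight")
        for g, w in self.gene_weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"gene weight for {g!r} must be finite and >= 0")

    def t_array(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.gene_weights[g] for g in gene_ids], dtype=float)


def build_subtype_networks(
    X: ExpressionMatrix,
    labels: SubtypeLabels,
    meta: MetaSelection,
    G: GeneNetwork,
    transform: Literal["abs", "square"] = "abs",
) -> list[SubtypeWeightedNetwork]:
    """One weighted network per subtype, in ``labels.subtype_order``."""
    return [
        SubtypeWeightedNetwork(
            subtype=p,
            gene_weights=gene_weights(X, labels, meta, p, transform=transform),
            base_edges=G,
            weight_transform=transform,
        )
        for p in labels.subtype_order
    ]
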