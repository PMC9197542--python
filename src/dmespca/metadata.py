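"""Meta-data selection: pick high-quality samples per subtype.

Noisy or atypical samples distort the subtype-specific gene weights, so
before any weighting we retain, per subtype, only the samples that sit
stably near their subtype's K-means cluster centre:

1. cluster all samples (K-means, K = number of subtypes, all genes);
2. match clusters to subtypes by Hungarian assignment on the contingency
   table, then mark the ``h`` samples of each subtype nearest the matched
   centre;
3. repeat with fresh K-means seeds and keep the samples marked in at least
   ``stability_threshold`` of the repeats (falling back to the ``h`` most
   frequently marked if that set is empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .io import ExpressionMatrix, SubtypeLabels

__all__ = ["MetaSelection", "cluster_samples", "select_meta", "all_samples_selection"]


@dataclass
class MetaSelection:
    """Per-subtype selected sample ids plus the parameters that produced them."""

    selected: dict[str, list[str]]
    h: int
    repeats: int
    stability_threshold: float

    def __post_init__(self) -> None:
        for p, samples in self.selected.items():
            if not 1 <= len(samples) <= self.h:
                raise ValueError(
                    f"subtype {p!r}: {len(samples)} selected samples violates 1..h={self.h}"
                )

    def all_selected(self) -> list[str]:
        out: list[str] = []
        for p in self.selected:
            out.extend(self.selected[p])
        return out


def cluster_samples(
    X: ExpressionMatrix,
    n_clusters: int,
    seed: int,
) -> tuple[dict[str, int], np.ndarray]:
    """K-means over samples (points in gene space).

    Returns the sample→cluster map and the (n_clusters, n_genes) centre
    matrix. Deterministic given ``seed`` (k-means++, 10 restarts).
    """
    if n_clusters > X.n_samples:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds the {X.n_samples} available samples"
        )
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=10,
        tol=1e-6,
        random_state=seed % (2**31),
    )
    assign = km.fit_predict(X.values.T)
    return dict(zip(X.sample_ids, (int(c) for c in assign))), km.cluster_centers_


def _match_clusters_to_subtypes(
    assignment: dict[str, int],
    labels: SubtypeLabels,
    n_clusters: int,
) -> dict[str, int]:
    """Hungarian matching of clusters to subtypes on the contingency table."""
    subtypes = labels.subtype_order
    contingency = np.zeros((len(subtypes), n_clusters), dtype=int)
    s_index = {p: i for i, p in enumerate(subtypes)}
    for sample, cluster in assignment.items():
        contingency[s_index[labels.assignments[sample]], cluster] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return {subtypes[r]: int(c) for r, c in zip(rows, cols)}


def select_meta(
    X: ExpressionMatrix,
    labels: SubtypeLabels,
    h: int,
    repeats: int = 10,
    stability_threshold: float = 1.0,
    seed: int = 0,
) -> MetaSelection:
    """Select up to ``h`` stably-central samples per subtype.

    Each repeat ``r`` reruns K-means with seed ``seed + r``; a sample is
    marked when it is among the ``h`` nearest (Euclidean, full gene space)
    to its subtype's matched centre. The final selection keeps samples
    marked in ``>= stability_threshold * repeats`` repeats; if none
    qualify for a subtype, the ``h`` most frequently marked samples win
    (ties broken by smaller mean distance to the centre, then sample id).
    """
    labels.validate_against(X)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0 < stability_threshold <= 1:
        raise ValueError("stability_threshold must be in (0, 1]")
    subtype_samples = {
        p: [s for s in X.sample_ids if labels.assignments[s] == p]
        for p in labels.subtype_order
    }
    min_size = min(len(v) for v in subtype_samples.values())
    if h > min_size:
        raise ValueError(f"h={h} exceeds the smallest subtype size {min_size}")

    P = labels.n_subtypes
    col = {s: j for j, s in enumerate(X.sample_ids)}
    marks: dict[str, dict[str, int]] = {p: {s: 0 for s in ss} for p, ss in subtype_samples.items()}
    dist_sums: dict[str, dict[str, float]] = {p: {s: 0.0 for s in ss} for p, ss in subtype_samples.items()}

    for r in range(repeats):
        assignment, centers = cluster_samples(X, P, seed=seed + r)
        matched = _match_clusters_to_subtypes(assignment, labels, P)
        for p, samples in subtype_samples.items():
            center = centers[matched[p]]
            dists = np.array(
                [np.linalg.norm(X.values[:, col[s]] - center) for s in samples]
            )
            # h nearest, deterministic tie-break by sample id order
            order = np.lexsort((np.arange(len(samples)), dists))
            for j in order[:h]:
                marks[p][samples[j]] += 1
            for s, d in zip(samples, dists):
                dist_sums[p][s] += float(d)

    need = stability_threshold * repeats
    selected: dict[str, list[str]] = {}
    for p, samples in subtype_samples.items():
        stable = [s for s in samples if marks[p][s] >= need]
        pool = stable if stable else samples
        ranked = sorted(
            pool,
            key=lambda s: (-marks[p][s], dist_sums[p][s] / repeats, s),
        )
        selected[p] = sorted(ranked[:h]) if len(pool) > h else sorted(pool)
    return MetaSelection(
        selected=selected, h=h, repeats=repeats, stability_threshold=stability_threshold
    )


def all_samples_selection(X: ExpressionMatrix, labels: SubtypeLabels) -> MetaSelection:
    """Degenerate selection using every sample (the no-meta ablation)."""
    labels.validate_against(X)
    selected = {
        p: [s for s in X.sample_ids if labels.assignments[s] == p]
        for p in labels.subtype_order
    }
    h = max(len(v) for v in selected.values())
    return MetaSelection(selected=selected, h=h, repeats=1, stability_threshold=1.0)
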