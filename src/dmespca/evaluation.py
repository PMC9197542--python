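"""Evaluation of a selected gene set: clustering, significance, classification.

Three complementary views of how well a screened biomarker set separates
the subtypes:

* K-means on the selected-gene submatrix, scored against the labels by
  clustering accuracy under the optimal one-to-one cluster↔subtype
  matching (Hungarian assignment on the contingency table);
* a two-sided Welch t test per selected gene (target subtype vs the
  rest, all samples) as a per-gene significance readout;
* stratified k-fold cross-validation of four standard classifiers (KNN,
  RBF SVM, logistic regression, random forest) on the selected-gene
  submatrix, macro-averaged and averaged over five seeded CV runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io import ExpressionMatrix, SubtypeLabels
from .metadata import cluster_samples
from .sparse_core import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "clustering_accuracy",
    "cluster_on_selection",
    "selection_pvalues",
    "crossval_classify",
    "evaluate",
]


@dataclass
class EvaluationReport:
    clustering_accuracy: float
    per_gene_pvalues: dict[tuple[str, str], float]
    classification: dict[str, dict[str, float]]
    folds: int = 5
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "clustering_accuracy": self.clustering_accuracy,
            "per_gene_pvalues": {
                f"{p}\t{g}": v for (p, g), v in self.per_gene_pvalues.items()
            },
            "classification": self.classification,
            "folds": self.folds,
            "seed": self.seed,
            **self.extras,
        }


def clustering_accuracy(predicted: dict[str, int], truth: SubtypeLabels) -> float:
    """Accuracy under the best one-to-one cluster→subtype assignment."""
    samples = sorted(predicted)
    if set(samples) != set(truth.assignments):
        raise ValueError("predicted and true label sets cover different samples")
    clusters = sorted(set(predicted.values()))
    subtypes = truth.subtype_order
    size = max(len(clusters), len(subtypes))
    contingency = np.zeros((size, size), dtype=int)
    c_index = {c: i for i, c in enumerate(clusters)}
    s_index = {p: i for i, p in enumerate(subtypes)}
    for s in samples:
        contingency[c_index[predicted[s]], s_index[truth.assignments[s]]] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum()) / len(samples)


def cluster_on_selection(
    X: ExpressionMatrix,
    result: FitResult | list[str],
    labels: SubtypeLabels,
    seed: int = 0,
) -> dict[str, int]:
    """K-means (K = number of subtypes) on the selected-gene submatrix."""
    if isinstance(result, FitResult):
        genes: list[str] = sorted({g for c in result.components for g in c.selected_genes})
    else:
        genes = sorted(set(result))
    if not genes:
        raise ValueError("empty gene selection")
    sub = X.subset_genes(genes)
    assignment, _ = cluster_samples(sub, labels.n_subtypes, seed=seed)
    return assignment


def selection_pvalues(
    X: ExpressionMatrix,
    labels: SubtypeLabels,
    selected: dict[str, list[str]],
) -> dict[tuple[str, str], float]:
    """Two-sided Welch p-value per (subtype, selected gene), on all samples."""
    labels.validate_against(X)
    row = {g: i for i, g in enumerate(X.gene_ids)}
    y = labels.as_array(X.sample_ids)
    out: dict[tuple[str, str], float] = {}
    for p, genes in selected.items():
        mask = y == p
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"subtype {p!r} needs >= 2 samples on both sides")
        for g in genes:
            a = X.values[row[g], mask]
            b = X.values[row[g], ~mask]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                logger.warning("gene %r constant in both groups; p := 1.0", g)
                out[(p, g)] = 1.0
                continue
            out[(p, g)] = float(ttest_ind(a, b, equal_var=False).pvalue)
    return out


def _default_models(seed: int) -> dict[str, object]:
    return {
        "knn": KNeighborsClassifier(n_neighbors=5),
        "svm": SVC(kernel="rbf", C=1.0, random_state=seed),
        "logistic": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


def crossval_classify(
    X: ExpressionMatrix,
    selected_genes: list[str],
    labels: SubtypeLabels,
    folds: int = 5,
    models: list[str] | None = None,
    seed: int = 0,
    n_runs: int = 5,
) -> dict[str, dict[str, float]]:
    """Macro precision/recall/F1 and accuracy per model.

    Stratified ``folds``-fold CV on the selected-gene submatrix, repeated
    ``n_runs`` times with seeds ``seed..seed+n_runs-1`` and averaged.
    """
    labels.validate_against(X)
    sub = X.subset_genes(selected_genes) if selected_genes else X
    data = sub.values.T  # samples x genes
    y = labels.as_array(sub.sample_ids)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; reduce folds"
        )
    wanted = models or ["knn", "svm", "logistic", "random_forest"]
    out: dict[str, dict[str, float]] = {}
    for name in wanted:
        accs, precs, recs, f1s = [], [], [], []
        for run in range(n_runs):
            run_seed = seed + run
            model = _default_models(run_seed)[name]
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=run_seed)
            y_true_all, y_pred_all = [], []
            for train, test in skf.split(data, y):
                model.fit(data[train], y[train])
                y_true_all.extend(y[test])
                y_pred_all.extend(model.predict(data[test]))
            accs.append(accuracy_score(y_true_all, y_pred_all))
            p, r, f1, _ = precision_recall_fscore_support(
                y_true_all, y_pred_all, average="macro", zero_division=0
            )
            precs.append(p)
            recs.append(r)
            f1s.append(f1)
        out[name] = {
            "accuracy": float(np.mean(accs)),
            "precision": float(np.mean(precs)),
            "recall": float(np.mean(recs)),
            "f1": float(np.mean(f1s)),
        }
    return out


def evaluate(
    X: ExpressionMatrix,
    result: FitResult,
    labels: SubtypeLabels,
    folds: int = 5,
    seed: int = 0,
    models: list[str] | None = None,
) -> EvaluationReport:
    """Full report: clustering accuracy, per-gene p-values, CV metrics."""
    predicted = cluster_on_selection(X, result, labels, seed=seed)
    acc = clustering_accuracy(predicted, labels)
    selected: dict[str, list[str]] = {}
    for i, comp in enumerate(result.components):
        key = comp.subtype if comp.subtype is not None else f"component_{i}"
        selected.setdefault(key, [])
        selected[key].extend(g for g in comp.selected_genes if g not in selected[key])
    known = {p: gs for p, gs in selected.items() if p in labels.subtype_order}
    pvals = selection_pvalues(X, labels, known) if known else {}
    union = sorted({g for gs in selected.values() for g in gs})
    classification = crossval_classify(
        X, union, labels, folds=folds, models=models, seed=seed
    )
    return EvaluationReport(
        clustering_accuracy=acc,
        per_gene_pvalues=pvals,
        classification=classification,
        folds=folds,
        seed=seed,
        extras={"n_selected_genes": len(union)},
    )
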