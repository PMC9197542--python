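"""scikit-learn style estimators over the sparse-PCA solver family.

These follow the transformer protocol (``fit``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn pipelines and model selection. ``X`` is the
usual samples × features (samples × genes) matrix; internally the solver
works on its transpose, the genes × samples orientation native to
microarray data.

The gene interaction network is a constructor parameter, either a
:class:`~dmespca.io.GeneNetwork` over feature names or an iterable of
(i, j) edges — integer column positions or feature-name pairs. Features
absent from the network can never be selected by the edge-group modes
but are retained in ``components_`` (with zero loading), so
``transform`` keeps the full feature space.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import sparse_core
from .dynamic_network import build_subtype_networks, SubtypeWeightedNetwork
from .io import ExpressionMatrix, GeneNetwork, SubtypeLabels
from .metadata import all_samples_selection, select_meta
from .sparse_core import FitResult, SolverParams

__all__ = [
    "MetaSampleSelector",
    "L0SparsePCA",
    "EdgeGroupSparsePCA",
    "DynamicMetaESPCA",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    """Coerce samples × genes input; return (array, gene names, sample ids)."""
    if isinstance(X, pd.DataFrame):
        genes = [str(c) for c in X.columns]
        samples = [str(i) for i in X.index]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2d samples x genes matrix, got ndim={arr.ndim}")
        genes = [f"g{j}" for j in range(arr.shape[1])]
        samples = [f"s{i}" for i in range(arr.shape[0])]
    if not np.all(np.isfinite(arr)):
        raise ValueError("input matrix contains non-finite values")
    return arr, genes, samples


def _resolve_network(network, genes: list[str]) -> GeneNetwork:
    if isinstance(network, GeneNetwork):
        known = set(genes)
        edges = [e for e in network.edges if e[0] in known and e[1] in known]
        if not edges:
            raise ValueError("no network edge has both endpoints among the features")
        return GeneNetwork(edges=edges)
    edges = []
    for a, b in network:
        if isinstance(a, (int, np.integer)):
            a, b = genes[int(a)], genes[int(b)]
        edges.append((str(a), str(b)))
    return GeneNetwork(edges=edges)


def _expression_from(arr: np.ndarray, genes: list[str], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=arr.T.copy())


class MetaSampleSelector(BaseEstimator):
    """Select the stably-central "meta" samples of each subtype.

    Repeated K-means over all samples, Hungarian matching of clusters to
    subtype labels, and per-subtype retention of the ``h`` samples
    nearest their matched centre in every (or a ``stability_threshold``
    fraction of) repeats.

    Parameters
    ----------
    h : samples kept per subtype (must not exceed the smallest subtype).
    repeats : independent K-means repetitions.
    stability_threshold : fraction of repeats in which a sample must be
        marked to be retained.
    random_state : root seed; repeat r uses ``random_state + r``.
    """

    def __init__(
        self,
        h: int = 5,
        repeats: int = 10,
        stability_threshold: float = 1.0,
        random_state: int = 0,
    ):
        self.h = h
        self.repeats = repeats
        self.stability_threshold = stability_threshold
        self.random_state = random_state

    def fit(self, X, y):
        arr, genes, samples = _as_matrix(X)
        labels = SubtypeLabels(
            assignments={s: str(lab) for s, lab in zip(samples, y)},
        )
        expr = _expression_from(arr, genes, samples)
        self.selection_ = select_meta(
            expr,
            labels,
            h=self.h,
            repeats=self.repeats,
            stability_threshold=self.stability_threshold,
            seed=self.random_state,
        )
        self.n_features_in_ = arr.shape[1]
        sel = set(self.selection_.all_selected())
        self.support_ = np.array([s in sel for s in samples], dtype=bool)
        return self

    def get_support(self) -> np.ndarray:
        """Boolean mask over samples (rows) retained as meta-data."""
        return self.support_


class _BaseSparsePCA(TransformerMixin, BaseEstimator):
    """Shared fit machinery; subclasses fix the solver mode."""

    _mode: str = "spca"

    def _solver_params(self) -> SolverParams:
        raise NotImplementedError

    def _networks(self, genes, arr, samples, y):
        return None

    def _n_pcs(self, y) -> int:
        n = getattr(self, "n_components", 1)
        return int(n) if n is not None else 1

    def _warm_starts(self, y, samples, n_pcs):
        return None

    def fit(self, X, y=None):
        arr, genes, samples = _as_matrix(X)
        expr = _expression_from(arr, genes, samples)
        params = self._solver_params()
        networks = self._networks(genes, arr, samples, y)
        n_pcs = self._n_pcs(y)
        result = sparse_core.fit(
            expr, params, networks=networks, n_pcs=n_pcs,
            warm_starts=self._warm_starts(y, samples, n_pcs),
        )
        self._store(result, arr.shape[1], genes)
        return self

    def _store(self, result: FitResult, n_features: int, genes: list[str]) -> None:
        self.fit_result_ = result
        self.components_ = np.vstack([c.u for c in result.components])
        self.sample_scores_ = np.vstack([c.v for c in result.components])
        self.objectives_ = np.array([c.objective for c in result.components])
        self.selected_genes_ = [list(c.selected_genes) for c in result.components]
        self.selected_edges_ = [list(c.selected_edges) for c in result.components]
        self.n_iter_ = np.array([c.n_iter for c in result.components])
        self.n_features_in_ = n_features
        self.feature_names_ = list(genes)

    def transform(self, X):
        arr, _, _ = _as_matrix(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {arr.shape[1]} features, expected {self.n_features_in_}"
            )
        return arr @ self.components_.T

    def get_support(self, component: int | None = None) -> np.ndarray:
        """Boolean gene-selection mask (union over components by default)."""
        mask = np.zeros(self.n_features_in_, dtype=bool)
        comps = (
            self.components_ if component is None else self.components_[[component]]
        )
        for u in comps:
            mask |= u != 0
        return mask


class L0SparsePCA(_BaseSparsePCA):
    """Plain L0-constrained sparse PCA (top-s genes per component).

    Alternating power iteration with the exact L0 projection: each
    loading keeps the ``s`` genes of largest |X'v| magnitude. The
    objective trajectory is non-decreasing and the solve is
    deterministic given ``random_state``.
    """

    _mode = "spca"

    def __init__(
        self,
        s: int = 10,
        n_components: int = 1,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_restarts: int = 1,
        svd_init: bool = False,
        center: bool = True,
        random_state: int = 0,
    ):
        self.s = s
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.svd_init = svd_init
        self.center = center
        self.random_state = random_state

    def _solver_params(self) -> SolverParams:
        return SolverParams(
            s=self.s,
            mode="spca",
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            svd_init=self.svd_init,
            center=self.center,
            seed=self.random_state,
        )


class EdgeGroupSparsePCA(_BaseSparsePCA):
    """Edge-group sparse PCA: loadings supported on k network edges.

    The sparsity unit is a network edge (a two-gene group), so every
    selected gene arrives with at least one interaction partner. The
    NP-hard projection is solved by randomised greedy search: candidate
    set of the floor((1+omega)k) heaviest edges, uniform draw of k, and
    omega annealed to 0 by rho per iteration.
    """

    _mode = "espca"

    def __init__(
        self,
        network=None,
        k: int = 10,
        n_components: int = 1,
        omega: float = 0.0,
        rho: float = 0.05,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_restarts: int = 1,
        edge_norm: Literal["sqrt", "sumsq"] = "sqrt",
        svd_init: bool = False,
        center: bool = True,
        random_state: int = 0,
    ):
        self.network = network
        self.k = k
        self.n_components = n_components
        self.omega = omega
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.edge_norm = edge_norm
        self.svd_init = svd_init
        self.center = center
        self.random_state = random_state

    def _solver_params(self) -> SolverParams:
        return SolverParams(
            k=self.k,
            mode="espca",
            omega=self.omega,
            rho=self.rho,
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            edge_norm=self.edge_norm,
            svd_init=self.svd_init,
            center=self.center,
            seed=self.random_state,
        )

    def _networks(self, genes, arr, samples, y):
        if self.network is None:
            raise ValueError("EdgeGroupSparsePCA requires a network")
        return _resolve_network(self.network, genes)


class DynamicMetaESPCA(_BaseSparsePCA):
    """Supervised, network-constrained sparse PCA for subtype biomarkers.

    For each subtype p (in first-appearance order of ``y``) the base
    network is reweighted: each gene carries |t_p| — the Welch statistic
    of its expression in subtype p's meta samples against all other
    subtypes' meta samples — and an edge (i, j) is weighted
    sqrt(t_i z_i^2 + t_j z_j^2) at the current direction z. Component p
    is then an edge-group sparse loading solved on subtype p's network,
    so each component screens biomarkers for one subtype.

    ``use_meta=False`` computes the weights on all samples and
    ``use_dynamic=False`` forces unit gene weights (reducing the model to
    plain edge-group sparse PCA); both exist for ablation studies.

    Parameters mirror :class:`EdgeGroupSparsePCA`, plus the meta-sample
    stage (``meta_h``, ``meta_repeats``, ``meta_stability``) and the
    gene-weight transform (``t_transform``: ``abs`` or ``square``).
    ``n_components=None`` extracts one component per subtype.
    """

    _mode = "dm_espca"

    def __init__(
        self,
        network=None,
        k: int = 10,
        n_components: int | None = None,
        omega: float = 0.2,
        rho: float = 0.05,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_restarts: int = 5,
        edge_norm: Literal["sqrt", "sumsq"] = "sqrt",
        t_transform: Literal["abs", "square"] = "abs",
        meta_h: int | None = None,
        meta_repeats: int = 10,
        meta_stability: float = 1.0,
        use_meta: bool = True,
        use_dynamic: bool = True,
        init: Literal["subtype", "random"] = "subtype",
        svd_init: bool = False,
        center: bool = True,
        random_state: int = 0,
    ):
        self.network = network
        self.k = k
        self.n_components = n_components
        self.omega = omega
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.edge_norm = edge_norm
        self.t_transform = t_transform
        self.meta_h = meta_h
        self.meta_repeats = meta_repeats
        self.meta_stability = meta_stability
        self.use_meta = use_meta
        self.use_dynamic = use_dynamic
        self.init = init
        self.svd_init = svd_init
        self.center = center
        self.random_state = random_state

    def _solver_params(self) -> SolverParams:
        return SolverParams(
            k=self.k,
            mode="dm_espca",
            omega=self.omega,
            rho=self.rho,
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            edge_norm=self.edge_norm,
            svd_init=self.svd_init,
            center=self.center,
            seed=self.random_state,
        )

    def _warm_starts(self, y, samples, n_pcs):
        if self.init != "subtype":
            return None
        order = list(dict.fromkeys(str(lab) for lab in y))
        ys = np.array([str(lab) for lab in y])
        starts = []
        for p in range(n_pcs):
            ind = (ys == order[p]).astype(float)
            starts.append(ind / np.linalg.norm(ind))
        return starts

    def _n_pcs(self, y) -> int:
        if self.n_components is not None:
            return int(self.n_components)
        return len(dict.fromkeys(str(lab) for lab in y))

    def _networks(self, genes, arr, samples, y):
        if self.network is None:
            raise ValueError("DynamicMetaESPCA requires a network")
        if y is None:
            raise ValueError("DynamicMetaESPCA is supervised; pass subtype labels y")
        G = _resolve_network(self.network, genes)
        labels = SubtypeLabels(
            assignments={s: str(lab) for s, lab in zip(samples, y)},
        )
        expr = _expression_from(arr, genes, samples)
        labels.validate_against(expr)
        if self.use_meta:
            h = self.meta_h
            if h is None:
                smallest = min(len(labels.samples_of(p)) for p in labels.subtype_order)
                h = max(2, int(round(0.5 * smallest)))
            meta = select_meta(
                expr,
                labels,
                h=h,
                repeats=self.meta_repeats,
                stability_threshold=self.meta_stability,
                seed=self.random_state,
            )
        else:
            meta = all_samples_selection(expr, labels)
        self.meta_selection_ = meta
        self.subtype_order_ = list(labels.subtype_order)
        nets = build_subtype_networks(expr, labels, meta, G, transform=self.t_transform)
        if not self.use_dynamic:
            nets = [
                SubtypeWeightedNetwork(
                    subtype=net.subtype,
                    gene_weights={g: 1.0 for g in net.gene_weights},
                    base_edges=net.base_edges,
                    weight_transform=net.weight_transform,
                )
                for net in nets
            ]
        self.gene_weights_ = {net.subtype: dict(net.gene_weights) for net in nets}
        return nets
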