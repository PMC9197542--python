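"""Sparse PCA solver family: L0, edge-group, and dynamic edge-group.

All three variants maximise u' X v over unit-norm u (gene loading) and v
(sample score) subject to a sparsity constraint on u, by alternating

    z = X v;  u = P(z) / ||P(z)||;  v = X'u / ||X'u||

where P is the sparse projection:

* ``spca``     — keep the s largest-|z| entries (exact L0 projection);
* ``espca``    — keep the endpoints of k network edges chosen by their
  static weight sqrt(z_i^2 + z_j^2);
* ``dm_espca`` — as espca but with per-subtype dynamic edge weights
  sqrt(t_i z_i^2 + t_j z_j^2) from frozen Welch gene weights t.

Selecting the best k edges by total retained |z| mass is NP-hard because
edges share endpoints, so the edge modes use a randomised greedy
projection: rank edges by weight, keep the floor((1+omega)*k) best as the
candidate set I, draw k of them uniformly, and shrink omega by rho each
outer iteration so the search anneals to the pure greedy rule and the
alternation can converge. Multiple random restarts guard against local
optima; further components are extracted after Hotelling deflation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .dynamic_network import SubtypeWeightedNetwork, edge_weights_array
from .io import ExpressionMatrix, GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SolverParams",
    "SparseComponent",
    "FitResult",
    "l0_project",
    "candidate_edges",
    "sample_edges",
    "decay_omega",
    "dm_project",
    "fit_component",
    "fit",
    "exhaustive_project",
]

Mode = Literal["spca", "espca", "dm_espca"]


@dataclass
class SolverParams:
    """Budgets and knobs for the alternating solver.

    k       — edge budget for the edge-group modes;
    s       — gene budget for plain L0 SPCA;
    omega   — initial random ratio (candidate set size floor((1+omega)k));
    rho     — per-iteration decay of omega (0 = pure greedy throughout);
    tol     — relative objective change declaring convergence (only
              evaluated once omega has reached 0);
    n_restarts — random restarts per component, best objective kept.
    """

    k: int = 10
    s: int = 10
    omega: float = 0.0
    rho: float = 0.05
    max_iter: int = 200
    tol: float = 1e-6
    n_restarts: int = 1
    seed: int = 0
    mode: Mode = "dm_espca"
    edge_norm: Literal["sqrt", "sumsq"] = "sqrt"
    svd_init: bool = False
    center: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.omega < 0 or self.rho < 0:
            raise ValueError("omega and rho must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")


@dataclass
class SparseComponent:
    """One extracted component: unit loading u, unit score v, selection."""

    u: np.ndarray
    v: np.ndarray
    selected_edges: list[tuple[str, str]]
    selected_genes: list[str]
    objective: float
    subtype: str | None = None
    trajectory: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.u)


@dataclass
class FitResult:
    """All components of one fit plus bookkeeping for reproducibility."""

    components: list[SparseComponent]
    params: SolverParams
    restart_objectives: list[list[float]]
    seeds_used: list[list[int]]


# ---------------------------------------------------------------------------
# projections


def l0_project(z: np.ndarray, s: int) -> np.ndarray:
    """Keep the s largest-|z| entries, zero the rest (ties: lowest index)."""
    z = np.asarray(z, dtype=float)
    if s > z.size:
        raise ValueError(f"s={s} exceeds vector length {z.size}")
    order = np.lexsort((np.arange(z.size), -np.abs(z)))
    out = np.zeros_like(z)
    keep = order[:s]
    out[keep] = z[keep]
    return out


def candidate_edges(weights: np.ndarray, k: int, omega: float) -> np.ndarray:
    """Row indices of the floor((1+omega)*k) top-weighted edges.

    Ties break toward the lexicographically smaller edge (edges are stored
    in lexicographic id order, so row order is the tie-break). Capped at
    the number of available edges.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty edge weight vector")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_cand = min(int(math.floor((1.0 + omega) * k)), weights.size)
    order = np.lexsort((np.arange(weights.size), -weights))
    return np.sort(order[:n_cand])


def sample_edges(I: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample (without replacement) of min(k, |I|) edges from I."""
    I = np.asarray(I)
    if I.size == 0:
        raise ValueError("cannot sample from an empty candidate set")
    if I.size <= k:
        return np.sort(I)
    picked = rng.choice(I, size=k, replace=False)
    return np.sort(picked)


def decay_omega(omega: float, rho: float) -> float:
    """One annealing step: omega <- max(0, omega - rho)."""
    if omega < 0 or rho < 0:
        raise ValueError("omega and rho must be >= 0")
    return max(0.0, omega - rho)


def dm_project(
    z: np.ndarray,
    edge_index: np.ndarray,
    k: int,
    omega: float,
    rng: np.random.Generator,
    t: np.ndarray | None = None,
    edge_norm: Literal["sqrt", "sumsq"] = "sqrt",
) -> tuple[np.ndarray, np.ndarray]:
    """Randomised greedy edge-group projection of z.

    Weights every edge at the current z (dynamically via t when given),
    extracts the enlarged candidate set, samples k edges J_k from it, and
    returns (u_hat, J_k) where u_hat keeps z on the endpoints of J_k and
    is zero elsewhere. u_hat is *not* normalised here; callers divide by
    its norm.
    """
    z = np.asarray(z, dtype=float)
    w = edge_weights_array(z, edge_index, t=t, edge_norm=edge_norm)
    if not np.any(w > 0):
        raise ValueError("no informative edges: all edge weights are zero")
    I = candidate_edges(w, k, omega)
    J = sample_edges(I, k, rng)
    u_hat = np.zeros_like(z)
    verts = np.unique(edge_index[J].ravel())
    u_hat[verts] = z[verts]
    return u_hat, J


def exhaustive_project(
    z: np.ndarray,
    edge_index: np.ndarray,
    k: int,
    t: np.ndarray | None = None,
    max_subsets: int = 10**6,
) -> tuple[np.ndarray, float]:
    """Optimal k-edge subset by enumeration (test oracle only).

    Maximises the retained mass ||z restricted to the subset's vertex
    set||_2 over all C(E, k) subsets. Returns (edge row indices, retained
    norm). Refuses instances with more than ``max_subsets`` subsets.
    """
    E = edge_index.shape[0]
    if k > E:
        k = E
    if math.comb(E, k) > max_subsets:
        raise ValueError(f"C({E},{k}) subsets exceed the enumeration budget")
    z = np.asarray(z, dtype=float)
    zz = z**2
    best_norm2 = -1.0
    best: tuple[int, ...] = ()
    for subset in combinations(range(E), k):
        verts = np.unique(edge_index[list(subset)].ravel())
        n2 = float(zz[verts].sum())
        if n2 > best_norm2 + 1e-15:
            best_norm2 = n2
            best = subset
    return np.array(best, dtype=np.int64), math.sqrt(max(best_norm2, 0.0))


# ---------------------------------------------------------------------------
# alternating solver


def _random_unit(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(n)
    nrm = np.linalg.norm(v)
    while nrm == 0.0:  # pragma: no cover - probability zero
        v = rng.standard_normal(n)
        nrm = np.linalg.norm(v)
    return v / nrm


def _zero_component(m: int, n: int, subtype: str | None) -> SparseComponent:
    logger.warning("degenerate direction (z = 0); returning zero component")
    return SparseComponent(
        u=np.zeros(m),
        v=np.zeros(n),
        selected_edges=[],
        selected_genes=[],
        objective=0.0,
        subtype=subtype,
        trajectory=[],
        converged=True,
        n_iter=0,
    )


def fit_component(
    X: np.ndarray,
    params: SolverParams,
    rng: np.random.Generator,
    edge_index: np.ndarray | None = None,
    t: np.ndarray | None = None,
    gene_ids: Sequence[str] | None = None,
    subtype: str | None = None,
    v0: np.ndarray | None = None,
) -> SparseComponent:
    """One alternating run from a single initial v.

    Records the objective u'Xv each iteration, decays omega once per
    iteration, declares convergence when omega has reached 0 and the
    relative objective change drops below tol, and returns the final
    iterate — by then the candidate enlargement has annealed away and
    the iterate is a fixed point of the pure greedy projection. Never
    raises on non-convergence; the ``converged`` flag is set instead.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if gene_ids is None:
        gene_ids = [str(i) for i in range(m)]
    v = _random_unit(n, rng) if v0 is None else np.asarray(v0, dtype=float)

    omega = params.omega
    trajectory: list[float] = []
    last: tuple[np.ndarray, np.ndarray, np.ndarray, float] | None = None
    prev_obj: float | None = None
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        z = X @ v
        if not np.any(z):
            if last is None:
                return _zero_component(m, n, subtype)
            break
        if params.mode == "spca":
            u_hat = l0_project(z, params.s)
            J = np.array([], dtype=np.int64)
        else:
            assert edge_index is not None
            u_hat, J = dm_project(
                z, edge_index, params.k, omega, rng, t=t, edge_norm=params.edge_norm
            )
        nrm = np.linalg.norm(u_hat)
        if nrm == 0.0:
            if last is None:
                return _zero_component(m, n, subtype)
            break
        u = u_hat / nrm
        v_hat = X.T @ u
        v_nrm = np.linalg.norm(v_hat)
        if v_nrm == 0.0:
            if last is None:
                return _zero_component(m, n, subtype)
            break
        v = v_hat / v_nrm
        obj = float(u @ X @ v)
        trajectory.append(obj)
        last = (u.copy(), v.copy(), J.copy(), obj)
        if omega == 0.0 and prev_obj is not None:
            if abs(obj - prev_obj) / max(abs(obj), 1e-12) < params.tol:
                converged = True
                break
        prev_obj = obj
        omega = decay_omega(omega, params.rho)

    assert last is not None
    u, v, J, final_obj = last
    if params.mode == "spca":
        sel_edges: list[tuple[str, str]] = []
        sel_genes = [gene_ids[i] for i in np.flatnonzero(u)]
    else:
        assert edge_index is not None
        sel_edges = [(gene_ids[a], gene_ids[b]) for a, b in edge_index[J]]
        sel_genes = [gene_ids[i] for i in np.unique(edge_index[J].ravel())]
    if not converged:
        logger.warning("fit_component: max_iter=%d reached without convergence", params.max_iter)
    return SparseComponent(
        u=u,
        v=v,
        selected_edges=sel_edges,
        selected_genes=sel_genes,
        objective=final_obj,
        subtype=subtype,
        trajectory=trajectory,
        converged=converged,
        n_iter=it,
    )


def _spawn_seeds(seed: int, n_pcs: int, n_restarts: int) -> list[list[int]]:
    """Named substreams: one child seed per (component, restart)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_pcs * n_restarts)
    flat = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return [flat[p * n_restarts : (p + 1) * n_restarts] for p in range(n_pcs)]


def fit(
    X: ExpressionMatrix,
    params: SolverParams,
    networks: Sequence[SubtypeWeightedNetwork] | GeneNetwork | None = None,
    n_pcs: int = 1,
    warm_starts: Sequence[np.ndarray | None] | None = None,
) -> FitResult:
    """Extract ``n_pcs`` components with restarts and Hotelling deflation.

    Mode ``spca`` ignores ``networks``; ``espca`` expects a single
    :class:`GeneNetwork` shared by all components; ``dm_espca`` expects
    the per-subtype weighted networks in subtype order, and component p
    uses subtype p's network (so ``n_pcs`` may not exceed the number of
    subtypes).

    With ``params.center`` (default) genes are mean-centred before
    solving, the usual PCA convention — otherwise the shared log2
    baseline dominates every loading. ``warm_starts`` optionally gives a
    deterministic initial v per component (e.g. a subtype-indicator
    direction); when set, every restart of that component starts there
    and restarts differ only through the randomised projection stream.
    """
    mat = X.values.copy()
    if params.center:
        mat -= mat.mean(axis=1, keepdims=True)
    gene_ids = list(X.gene_ids)

    per_pc: list[tuple[np.ndarray | None, np.ndarray | None, str | None]] = []
    if params.mode == "spca":
        per_pc = [(None, None, None)] * n_pcs
    elif params.mode == "espca":
        if not isinstance(networks, GeneNetwork):
            raise TypeError("espca mode needs a single GeneNetwork")
        ei = networks.edge_index_array(gene_ids)
        per_pc = [(ei, None, None)] * n_pcs
    elif params.mode == "dm_espca":
        if networks is None or isinstance(networks, GeneNetwork):
            raise TypeError("dm_espca mode needs the per-subtype weighted networks")
        nets = list(networks)
        if n_pcs > len(nets):
            raise ValueError(
                f"n_pcs={n_pcs} exceeds the {len(nets)} subtype networks available"
            )
        for net in nets[:n_pcs]:
            ei = net.base_edges.edge_index_array(gene_ids)
            per_pc.append((ei, net.t_array(gene_ids), net.subtype))
    else:  # pragma: no cover
        raise ValueError(f"unknown mode {params.mode!r}")

    seeds = _spawn_seeds(params.seed, n_pcs, params.n_restarts)
    components: list[SparseComponent] = []
    restart_objectives: list[list[float]] = []
    for p in range(n_pcs):
        ei, t, subtype = per_pc[p]
        best_comp: SparseComponent | None = None
        objs: list[float] = []
        warm = warm_starts[p] if warm_starts is not None else None
        for r in range(params.n_restarts):
            rng = np.random.default_rng(seeds[p][r])
            v0 = None
            if warm is not None:
                w = np.asarray(warm, dtype=float)
                v0 = w / np.linalg.norm(w)
            elif params.svd_init and r == 0:
                # deterministic warm start from the leading right singular vector
                _, _, vt = np.linalg.svd(mat, full_matrices=False)
                v0 = vt[0]
            comp = fit_component(
                mat, params, rng,
                edge_index=ei, t=t, gene_ids=gene_ids, subtype=subtype, v0=v0,
            )
            objs.append(comp.objective)
            if best_comp is None or comp.objective > best_comp.objective:
                best_comp = comp
        assert best_comp is not None
        components.append(best_comp)
        restart_objectives.append(objs)
        # Hotelling deflation: remove the extracted rank-one structure
        mat = mat - best_comp.objective * np.outer(best_comp.u, best_comp.v)
    return FitResult(
        components=components,
        params=replace(params),
        restart_objectives=restart_objectives,
        seeds_used=seeds,
    )
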