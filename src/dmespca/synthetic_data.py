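"""Synthetic benchmark data with planted subtype modules.

Emulates, at desk scale, a log2-intensity microarray matrix over a gene
interaction network: baseline Gaussian noise everywhere, and for each
subtype a disjoint "planted module" — a connected set of genes
up-shifted by a fixed effect in exactly that subtype's samples. The
network wires each module as a random spanning tree plus extra
within-module edges, drowned in uniformly random background edges. An
optional fraction of decoy probes sits below the usual log2-intensity
floor so the low-intensity filter has something to remove. Ground truth
(module genes and edges per subtype) is returned for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import ExpressionMatrix, GeneNetwork, SubtypeLabels

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "small_worked_instance"]


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give the standard benchmark instance."""

    n_genes: int = 500
    n_samples: int = 100
    subtype_sizes: list[int] = field(default_factory=lambda: [25, 25, 25, 25])
    module_size: int = 20
    module_extra_edges: int = 10
    effect: float = 5.0
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    background_edges: int = 2000
    low_intensity_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        P = len(self.subtype_sizes)
        if P < 1 or any(s < 1 for s in self.subtype_sizes):
            raise ValueError("subtype_sizes must be positive")
        if sum(self.subtype_sizes) != self.n_samples:
            raise ValueError("subtype_sizes must sum to n_samples")
        if P * self.module_size > self.n_genes:
            raise ValueError("P * module_size exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.low_intensity_fraction < 1:
            raise ValueError("low_intensity_fraction must be in [0, 1)")

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_sizes)


@dataclass
class GroundTruth:
    module_genes: dict[str, list[str]]
    module_edges: dict[str, list[tuple[str, str]]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_genes": self.module_genes,
            "module_edges": {
                p: [list(e) for e in edges] for p, edges in self.module_edges.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _module_edges(
    genes: list[str], extra: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """A random spanning tree over ``genes`` plus ``extra`` distinct chords."""
    n = len(genes)
    # random Prüfer-style attachment: connect each new vertex to a random earlier one
    perm = [genes[i] for i in rng.permutation(n)]
    edges = {tuple(sorted((perm[i], perm[int(rng.integers(0, i))]))) for i in range(1, n)}
    all_pairs = [
        tuple(sorted((genes[i], genes[j])))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    chords = [e for e in all_pairs if e not in edges]
    n_extra = min(extra, len(chords))
    for idx in rng.choice(len(chords), size=n_extra, replace=False):
        edges.add(chords[int(idx)])
    return sorted(edges)


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SubtypeLabels, GeneNetwork, GroundTruth]:
    """Deterministic draw of (expression, labels, network, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    P = spec.n_subtypes
    width = len(str(spec.n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]

    subtypes = [f"subtype{p}" for p in range(P)]
    assignments: dict[str, str] = {}
    start = 0
    for p, size in enumerate(spec.subtype_sizes):
        for s in samples[start : start + size]:
            assignments[s] = subtypes[p]
        start += size
    labels = SubtypeLabels(assignments=assignments, subtype_order=subtypes)

    values = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_samples))

    module_genes: dict[str, list[str]] = {}
    module_edge_map: dict[str, list[tuple[str, str]]] = {}
    edge_set: set[tuple[str, str]] = set()
    col_of = {s: j for j, s in enumerate(samples)}
    for p in range(P):
        mg = genes[p * spec.module_size : (p + 1) * spec.module_size]
        module_genes[subtypes[p]] = mg
        rows = [genes.index(g) for g in mg]
        cols = [col_of[s] for s in labels.samples_of(subtypes[p])]
        values[np.ix_(rows, cols)] += spec.effect
        medges = _module_edges(mg, spec.module_extra_edges, rng)
        module_edge_map[subtypes[p]] = medges
        edge_set.update(medges)

    module_gene_set = {g for mg in module_genes.values() for g in mg}
    # background edges over non-module pairs, uniform without replacement
    target = len(edge_set) + spec.background_edges
    attempts = 0
    while len(edge_set) < target and attempts < 50 * spec.background_edges:
        i, j = rng.integers(0, spec.n_genes, size=2)
        attempts += 1
        if i == j:
            continue
        e = tuple(sorted((genes[int(i)], genes[int(j)])))
        if e[0] in module_gene_set and e[1] in module_gene_set:
            continue
        edge_set.add(e)

    # low-intensity decoys: non-module probes dropped to baseline 2.0
    n_decoys = int(round(spec.low_intensity_fraction * spec.n_genes))
    if n_decoys:
        non_module = [i for i, g in enumerate(genes) if g not in module_gene_set]
        decoys = rng.choice(non_module, size=min(n_decoys, len(non_module)), replace=False)
        values[decoys, :] = 2.0 + rng.normal(0.0, 0.25, (len(decoys), spec.n_samples))
        values[decoys, :] = np.minimum(values[decoys, :], 3.9)

    X = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
    G = GeneNetwork(edges=sorted(edge_set))
    truth = GroundTruth(module_genes=module_genes, module_edges=module_edge_map)
    # module connectivity is a generator invariant worth asserting
    for p, medges in module_edge_map.items():
        g = nx.Graph(medges)
        assert nx.is_connected(g) and set(g.nodes) == set(module_genes[p])
    return X, labels, G, truth


def small_worked_instance() -> tuple[ExpressionMatrix, SubtypeLabels, GeneNetwork]:
    """A fixed 6-gene × 8-sample × 7-edge instance with hand-checkable numbers.

    Two subtypes of 4 samples. Genes A and B are up-shifted in subtype
    "one"; gene F is a constant probe; the network is a path A–B–C–D–E
    plus chords A–C and D–F. Values are exact one-decimal numbers so the
    Welch statistics can be verified by hand (see docs).
    """
    genes = ["A", "B", "C", "D", "E", "F"]
    samples = [f"s{i}" for i in range(8)]
    values = np.array(
        [
            [8.0, 8.2, 7.8, 8.1, 4.0, 4.2, 3.8, 4.1],  # A: +4 in subtype one
            [7.0, 7.1, 6.9, 7.2, 5.0, 5.1, 4.9, 5.2],  # B: +2 in subtype one
            [6.0, 6.1, 5.9, 6.2, 6.1, 6.0, 6.2, 5.9],  # C: null
            [5.5, 5.6, 5.4, 5.7, 5.6, 5.5, 5.7, 5.4],  # D: null
            [6.5, 6.4, 6.6, 6.3, 6.4, 6.5, 6.3, 6.6],  # E: null
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],  # F: constant
        ]
    )
    X = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
    labels = SubtypeLabels(
        assignments={s: ("one" if i < 4 else "two") for i, s in enumerate(samples)},
        subtype_order=["one", "two"],
    )
    G = GeneNetwork(
        edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "C"), ("D", "F"), ("B", "E")]
    )
    return X, labels, G
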