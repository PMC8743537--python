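"""Markov clustering of an all-vs-all protein similarity graph.

This reproduces the clustering stage that defined the CP/MP/RdRP protein
families: pairwise local-alignment scores form a weighted graph, and MCL
(alternating random-walk expansion and inflation) partitions it.  Plain MCL
on symmetrized scores is used — the inputs are one pooled protein set, so
orthology-specific normalizations do not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .align import local_score_bits
from .seq_io import ProteinRecord, atomic_open

DEFAULT_SCORE_FLOOR_BITS = 30.0
DEFAULT_INFLATION = 2.0
DEFAULT_PRUNE_BELOW = 1e-5
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-6


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over protein ids (weights ≥ 0)."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if not np.isfinite(weight) or weight < 0:
            raise ValueError(f"edge weight must be finite and >= 0, got {weight}")
        key = (a, b) if a <= b else (b, a)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key}")
        self.edges[key] = weight

    def to_matrix(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        m = np.zeros((n, n))
        for (a, b), w in self.edges.items():
            i, j = idx[a], idx[b]
            m[i, j] = w
            m[j, i] = w
        return m

    def write_tsv(self, path) -> None:
        with atomic_open(path) as fh:
            fh.write("id_a\tid_b\tweight\n")
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w:.4f}\n")


@dataclass
class ClusterSet:
    """A partition of protein ids into labelled, disjoint clusters."""

    clusters: list[set[str]]
    labels: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if c & seen:
                raise ValueError("clusters are not disjoint")
            seen |= c
        if len(self.labels) != len(self.clusters):
            raise ValueError("one label per cluster required")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def label_of(self, node: str) -> str:
        for lab, c in zip(self.labels, self.clusters):
            if node in c:
                return lab
        raise KeyError(node)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": n, "cluster_label": lab}
            for lab, c in zip(self.labels, self.clusters)
            for n in sorted(c)
        ]
        return pd.DataFrame(rows, columns=["protein_id", "cluster_label"])

    def write_tsv(self, path) -> None:
        with atomic_open(path) as fh:
            self.as_frame().to_csv(fh, sep="\t", index=False)


def all_vs_all_similarity(
    proteins: list[ProteinRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    score_floor_bits: float = DEFAULT_SCORE_FLOOR_BITS,
) -> SimilarityGraph:
    """Local-alignment similarity graph; pairs scoring below the floor get no edge."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    graph = SimilarityGraph(nodes=ids)
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            # score is symmetric; one direction suffices (symmetrize by max is a no-op)
            s = local_score_bits(
                proteins[i], proteins[j], matrix=matrix,
                gap_open=gap_open, gap_extend=gap_extend,
            )
            if s >= score_floor_bits:
                graph.add_edge(ids[i], ids[j], s)
    return graph


def mcl(
    graph: SimilarityGraph,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = DEFAULT_MAX_ITER,
    prune_below: float = DEFAULT_PRUNE_BELOW,
    convergence_tol: float = DEFAULT_TOL,
) -> ClusterSet:
    """Markov clustering.

    The adjacency matrix gets unit self-loops, is column-normalized, then
    iterates expansion (matrix square) and inflation (elementwise power,
    renormalize, prune small entries) until the largest column change falls
    below convergence_tol.  Clusters are the connected components of the
    attractor support.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if not graph.nodes:
        raise ValueError("empty graph")
    m = graph.to_matrix()
    np.fill_diagonal(m, np.maximum(m.diagonal(), 1.0))  # self-loops
    t = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = t @ t
        inflated = expanded**inflation
        inflated[inflated < prune_below] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        delta = np.abs(inflated - t).max()
        t = inflated
        if delta < convergence_tol:
            break
    support = csr_matrix((t + t.T) > 0)
    n_comp, comp = connected_components(support, directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for node, c in zip(graph.nodes, comp):
        clusters[c].add(node)
    clusters = [c for c in clusters if c]
    clusters.sort(key=lambda c: min(c))
    labels = [f"cluster_{k + 1}" for k in range(len(clusters))]
    return ClusterSet(clusters=clusters, labels=labels)


def label_clusters(clusters: ClusterSet, anchors: dict[str, str]) -> ClusterSet:
    """Rename clusters after anchor members (e.g. known CP_A representatives).

    Clusters without an anchor get deterministic novel_<role>_<k> labels;
    conflicting anchors in one cluster are an error.
    """
    new_labels: list[str] = []
    novel_counter: dict[str, int] = {}
    for c in clusters.clusters:
        hits = sorted({anchors[a] for a in c if a in anchors})
        if len(hits) > 1:
            raise ValueError(f"conflicting anchor labels {hits} in one cluster")
        if hits:
            new_labels.append(hits[0])
        else:
            new_labels.append(None)  # placeholder, filled below
    from .hmm import role_of

    for i, (lab, c) in enumerate(zip(new_labels, clusters.clusters)):
        if lab is None:
            roles = {role_of(n) or "protein" for n in c}
            role = roles.pop() if len(roles) == 1 else "protein"
            k = novel_counter.get(role, 0) + 1
            novel_counter[role] = k
            new_labels[i] = f"novel_{role}_{k}"
    return ClusterSet(clusters=clusters.clusters, labels=new_labels)
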