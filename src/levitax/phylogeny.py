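"""Distance trees from PAAI matrices and clade/label concordance checks.

Neighbor joining over 1 − PAAI/100 distances stands in for likelihood-based
phylogenetics: it is deterministic, exact on additive distances, and keeps
the pipeline self-contained.  Concordance between tree clades and the
profile-HMM taxon predictions flags sequences whose placement disagrees
with their cluster assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .demarcation import PairwiseIdentityMatrix
from .seq_io import atomic_open


@dataclass
class DistanceMatrix:
    """Symmetric, non-negative distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be 0")
        if not np.all(np.isfinite(self.values)) or self.values.min() < -1e-12:
            raise ValueError("distances must be finite and non-negative")


def paai_to_distance(m: PairwiseIdentityMatrix) -> DistanceMatrix:
    """d = 1 − PAAI/100."""
    return DistanceMatrix(ids=list(m.ids), values=1.0 - m.values / 100.0)


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    On equal Q the lexicographically smallest pair is joined (nodes keyed by
    the smallest leaf id in their subtree).  Negative branch estimates are
    clamped to zero with the deficit moved to the sibling branch.  The result
    is an unrooted tree represented with a trifurcating seed node.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(d.ids)
    nodes = []
    for i in d.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(i))
        nodes.append(nd)
    keys = list(d.ids)  # smallest leaf id under each active node
    dist = d.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic choice among ties
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in ties
        )
        _, ai, aj = best
        i_idx, j_idx = active[ai], active[aj]
        dij = dist[i_idx, j_idx]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i_idx])
        parent.add_child(nodes[j_idx])
        nodes[i_idx].edge.length = li
        nodes[j_idx].edge.length = lj
        nodes.append(parent)
        keys.append(min(keys[i_idx], keys[j_idx]))
        # distances to the new node
        new_row = 0.5 * (dist[i_idx, :] + dist[j_idx, :] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row)] = new_row
        dist[: len(new_row), -1] = new_row
        dist[-1, -1] = 0.0
        u = dist.shape[0] - 1
        active = [a for a in active if a not in (i_idx, j_idx)] + [u]

    # join the last three on a central (seed) node
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with atomic_open(path) as fh:
        fh.write(
            tree.as_string(
                schema="newick", suppress_rooting=True, real_value_format_specifier=".12g"
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def _bipartition_sides(tree: dendropy.Tree) -> list[frozenset]:
    sides = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.append(leaves)
    return sides


def _is_clade(group: frozenset, remaining: frozenset, sides) -> bool:
    if len(group) <= 1 or group == remaining:
        return True
    for side in sides:
        s = side & remaining
        if s == group or (remaining - s) == group:
            return True
    return False


def clade_concordance(
    tree: dendropy.Tree, labels: dict[str, str], exact_limit: int = 20
) -> tuple[pd.DataFrame, int]:
    """Monophyly of each label's leaves on the unrooted tree.

    For non-monophyletic labels the minimal leaf set whose removal restores
    monophyly is found by exhaustive search over increasing subset sizes
    (exact for label groups up to `exact_limit` leaves, greedy beyond).
    Returns the per-label report and the disagreement count = number of
    distinct leaves in all removal sets.
    """
    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaf_ids if l not in labels]
    if missing:
        raise ValueError(f"unlabelled leaves: {missing[:5]}")
    all_leaves = frozenset(leaf_ids)
    sides = _bipartition_sides(tree)

    rows = []
    removed_union: set[str] = set()
    for label in sorted(set(labels[l] for l in leaf_ids)):
        group = frozenset(l for l in leaf_ids if labels[l] == label)
        mono = _is_clade(group, all_leaves, sides)
        outliers: list[str] = []
        if not mono:
            outliers = _minimal_removal(group, all_leaves, sides, exact_limit)
            removed_union |= set(outliers)
        rows.append(
            {
                "label": label,
                "n_leaves": len(group),
                "monophyletic": mono,
                "outlier_ids": ",".join(sorted(outliers)),
            }
        )
    report = pd.DataFrame(
        rows, columns=["label", "n_leaves", "monophyletic", "outlier_ids"]
    )
    return report, len(removed_union)


def _minimal_removal(group, all_leaves, sides, exact_limit) -> list[str]:
    # candidate pool: members plus intruders inside the smallest side containing the group
    containing = [s for s in sides if group <= s] + [all_leaves]
    smallest = min(containing, key=len)
    pool = sorted(smallest - group) + sorted(group)

    def ok(removal: frozenset) -> bool:
        rem = all_leaves - removal
        return _is_clade(group - removal, rem, sides)

    if len(group) <= exact_limit and len(pool) <= 16:
        # pool lists intruders before group members, so among equal-size
        # solutions the one pruning foreign leaves wins deterministically
        for r in range(1, len(pool) + 1):
            for c in combinations(pool, r):
                if ok(frozenset(c)):
                    return sorted(c)
    # greedy fallback
    removal: set[str] = set()
    candidates = list(pool)
    while candidates and not ok(frozenset(removal)):
        best = None
        for c in candidates:
            trial = frozenset(removal | {c})
            rem = all_leaves - trial
            g = group - trial
            # score: solved beats unsolved; then fewer intruders in smallest containing side
            solved = _is_clade(g, rem, sides)
            cont = [s & rem for s in sides if g <= (s & rem)] + [rem]
            inliers = min((len(s - g) for s in cont), default=0)
            score = (0 if solved else 1, inliers, c)
            if best is None or score < best[0]:
                best = (score, c)
        removal.add(best[1])
        candidates.remove(best[1])
    return sorted(removal)
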