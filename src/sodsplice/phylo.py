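"""Distance-based phylogeny: p-distances under partial deletion,
neighbor-joining, and bootstrap supports.

Partial deletion removes alignment columns whose non-gap fraction is
below the site-coverage threshold (default 70%) globally, before any
pairwise comparison; p-distance is then the mismatch fraction over the
columns where both sequences are ungapped.  Neighbor joining follows the
standard Q-matrix formulation and recovers additive matrices exactly;
negative branch-length estimates are clamped to zero.  Bootstrap support
of an internal branch is the percentage of column-resampled replicate
trees containing the same bipartition of taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .errors import ConfigurationError, InputError
from .models import SequenceRecord

GAP_CHARS = ("-", ".")


@dataclass(frozen=True)
class PhyloConfig:
    site_coverage: float = 0.70
    bootstrap_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.site_coverage <= 1):
            raise ConfigurationError("site coverage must be in (0, 1]")
        if self.bootstrap_replicates < 1:
            raise ConfigurationError("need >= 1 bootstrap replicate")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise InputError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _alignment_matrix(alignment: Sequence[SequenceRecord]) -> tuple[tuple[str, ...], np.ndarray]:
    labels = tuple(r.id for r in alignment)
    if len(set(labels)) != len(labels):
        raise InputError("alignment taxon labels are not unique")
    lengths = {len(r.residues) for r in alignment}
    if len(lengths) != 1:
        raise InputError("aligned sequences have unequal lengths")
    rows = np.array([list(r.residues) for r in alignment])
    return labels, rows


def pdistance_partial_deletion(alignment: Sequence[SequenceRecord],
                               config: PhyloConfig = PhyloConfig()) -> DistanceMatrix:
    """Pairwise p-distances after global partial deletion of low-coverage
    columns.  A pair with no comparable sites raises, naming the pair."""
    if len(alignment) < 2:
        raise InputError("need at least two sequences")
    labels, rows = _alignment_matrix(alignment)
    gaps = np.isin(rows, GAP_CHARS)
    coverage = 1.0 - gaps.mean(axis=0)
    keep = coverage >= config.site_coverage
    rows, gaps = rows[:, keep], gaps[:, keep]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gaps[i] & ~gaps[j]
            compared = int(both.sum())
            if compared == 0:
                raise InputError(
                    f"no comparable sites between {labels[i]!r} and "
                    f"{labels[j]!r} after partial deletion")
            mism = int((rows[i, both] != rows[j, both]).sum())
            d[i, j] = d[j, i] = mism / compared
    return DistanceMatrix(labels=labels, values=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining; exact on additive matrices.

    Joins minimize the Q criterion with deterministic tie-breaking
    (smallest index pair); negative branch estimates are clamped to 0 and
    flagged in ``tree.clamped_branches``.  The returned dendropy tree is
    unrooted with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(list(dm.labels))
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in dm.labels]
    D = dm.values.astype(float).copy()
    active = list(range(n))
    clamped = []
    next_d = {(i, j): D[i, j] for i in range(n) for j in range(n)}

    def dist(i, j):
        return next_d[(i, j)] if i <= j else next_d[(j, i)]

    def set_dist(i, j, v):
        next_d[(min(i, j), max(i, j))] = v

    node_of = {i: nodes[i] for i in range(n)}
    new_index = n
    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * dist(i, j) - R[i] - R[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = dist(i, j)
        vi = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        vj = dij - vi
        parent = dendropy.Node()
        for child, v in ((node_of[i], vi), (node_of[j], vj)):
            if v < 0:
                clamped.append((new_index, float(v)))
                v = 0.0
            child.edge.length = float(v)
            parent.add_child(child)
        for k in active:
            if k in (i, j):
                continue
            set_dist(new_index, k, 0.5 * (dist(i, k) + dist(j, k) - dij))
        node_of[new_index] = parent
        active = [k for k in active if k not in (i, j)] + [new_index]
        new_index += 1

    i, j, k = active
    root = dendropy.Node()
    vi = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    vj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    vk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        if v < 0:
            clamped.append((idx, float(v)))
            v = 0.0
        node_of[idx].edge.length = float(v)
        root.add_child(node_of[idx])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    tree.clamped_branches = tuple(clamped)
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of taxon labels."""
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) <= 1 or len(all_taxa - side) <= 1:
            continue
        if anchor in side:
            side = all_taxa - side
        out.add(side)
    return out


def bootstrap_support(alignment: Sequence[SequenceRecord],
                      config: PhyloConfig = PhyloConfig()) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; each internal
    node of the original tree is labelled with the integer percentage of
    replicate trees containing its bipartition.  Replicates whose
    resampled alignment leaves a pair with no comparable sites are
    skipped (supports are percentages of completed replicates).
    """
    labels, rows = _alignment_matrix(alignment)
    tree = nj_tree(pdistance_partial_deletion(alignment, config))
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    done = 0
    n_cols = rows.shape[1]
    for _ in range(config.bootstrap_replicates):
        cols = rng.integers(0, n_cols, n_cols)
        resampled = [SequenceRecord(lab, "".join(rows[i, cols]))
                     for i, lab in enumerate(labels)]
        try:
            rep_tree = nj_tree(pdistance_partial_deletion(resampled, config))
        except InputError:
            continue
        done += 1
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    if done == 0:
        raise InputError("every bootstrap replicate was degenerate")
    all_taxa = frozenset(labels)
    anchor = min(all_taxa)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) <= 1 or len(all_taxa - side) <= 1:
            continue
        if anchor in side:
            side = all_taxa - side
        node.label = str(round(100 * counts.get(side, 0) / done))
    tree.bootstrap_replicates_done = done
    return tree


def bipartition_support(tree: dendropy.Tree, taxa: Iterable[str]) -> Optional[int]:
    """Support label of the branch splitting ``taxa`` from the rest, or
    None when the tree does not contain that bipartition."""
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_taxa)
    want = frozenset(taxa)
    if anchor in want:
        want = all_taxa - want
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_taxa - side
        if side == want:
            return int(node.label) if node.label is not None else None
    return None
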