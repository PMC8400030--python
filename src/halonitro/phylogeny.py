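"""16S rRNA phylogeny: p-distances, neighbour joining, bootstrap.

Distances are p-distances with pairwise deletion: alignment columns
containing a gap or an N in either member of a pair are excluded from
that pair's comparison.  Tree construction is the Saitou-Nei
neighbour-joining algorithm, implemented from first principles: at each
step the pair (i, j) minimising

    Q(i, j) = (n - 2) * d(i, j) - r_i - r_j        (r = row sums)

is joined, with branch lengths from the standard two-point formulas.
Ties in Q are broken by the lexicographically smallest pair of cluster
labels (a cluster is labelled by its smallest member leaf), which makes
the result invariant to input order.  Negative branch lengths are
clamped to zero without redistribution.

Bootstrap supports are percentages of column-resampled replicates whose
NJ tree contains the same leaf bipartition, attached to the original
topology (no consensus tree is built).  Each replicate draws its columns
from an independent, deterministic substream of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DegeneratePairError, FormatError
from .seqio import SequenceRecord
from .tree import Tree, TreeNode, _canonical_split


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise FormatError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in distance matrix")
        if not np.allclose(self.d, self.d.T):
            raise FormatError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise FormatError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise FormatError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)


def _encode_alignment(records: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"aligned records have unequal lengths {sorted(lengths)}")
    return np.array(
        [np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8) for r in records]
    )


def p_distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise p-distances on an alignment, with pairwise gap deletion."""
    if not records:
        raise FormatError("empty alignment")
    mat = _encode_alignment(records)
    labels = [r.id for r in records]
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            denom = int(comparable.sum())
            if denom == 0:
                raise DegeneratePairError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((mat[i, comparable] != mat[j, comparable]).sum())
            d[i, j] = d[j, i] = mism / denom
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining; returns the unrooted tree
    represented with a trifurcating root at the final join."""
    n = len(dm)
    if n < 3:
        raise ConfigError(f"neighbour joining needs >= 3 taxa, got {n}")
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    # cluster label for tie-breaks: smallest leaf label in the cluster
    tags = list(dm.labels)
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        sub = d[np.ix_(active, active)]
        k = len(active)
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((tags[active[a]], tags[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        _, ai, bj = best
        i, j = active[ai], active[bj]
        dij = d[i, j]
        li = dij / 2 + (r[ai] - r[bj]) / (2 * (k - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining clusters
        new_row = np.zeros(d.shape[0] + 1)
        for m in active:
            if m in (i, j):
                continue
            new_row[m] = (d[i, m] + d[j, m] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [m for m in active if m not in (i, j)] + [len(nodes) - 1]

    # close with the three-point formulas
    a, b, c = active
    root = TreeNode()
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        root.add_child(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def bootstrap_support(
    records: Sequence[SequenceRecord],
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> Tree:
    """NJ tree of the alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement (length preserved); the
    support of each internal edge of the original tree is the percentage
    of replicates containing the same leaf bipartition, rounded half-up.
    """
    if n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {n_reps}")
    mat = _encode_alignment(records)
    length = mat.shape[1]
    tree = nj_tree(p_distance_matrix(records))
    split_nodes = tree.support_by_split()
    counts = {split: 0 for split in split_nodes}

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(id=rec.id, residues=bytes(mat[k, cols]).decode("ascii"))
            for k, rec in enumerate(records)
        ]
        rep_tree = nj_tree(p_distance_matrix(resampled))
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    for split, node in split_nodes.items():
        node.support = _round_half_up(100.0 * counts[split] / n_reps)
    return tree


# ---------------------------------------------------------------------------
# Rooting


def root_on_outgroup(tree: Tree, outgroup_label: str) -> Tree:
    """Root the tree on the outgroup's pendant edge, splitting it in half.

    The set of non-trivial bipartitions (and any supports attached to
    them) is unchanged; only the representation is re-rooted.
    """
    tree = tree.copy()
    leaf = tree.find_leaf(outgroup_label)
    if leaf is None:
        raise KeyError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    old_parent = leaf.parent
    if old_parent is None:
        raise ConfigError("cannot root a single-node tree")
    half = (leaf.length or 0.0) / 2

    # detach the outgroup, then re-hang the rest of the tree from its
    # former parent outward
    old_parent.children.remove(leaf)
    new_root = TreeNode()
    leaf.length = half
    new_root.add_child(leaf)

    # reverse parent links along the path old_parent -> old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    prev = new_root
    carry_length = half
    carry_support = None
    for node in path:
        parent = node.parent
        node.parent = None
        if parent is not None:
            parent.children.remove(node)
        length_up = node.length
        support_here = node.support
        node.length = carry_length
        node.support = carry_support
        prev.add_child(node)
        carry_length = length_up
        carry_support = support_here
        prev = node
    # the old root (last in path) may now have a single child: splice it out
    _suppress_unifurcations(new_root)
    return Tree(new_root)


def _suppress_unifurcations(root: TreeNode) -> None:
    for node in list(root.traverse_preorder()):
        while len(node.children) == 1 and not node.children[0].is_leaf:
            child = node.children[0]
            node.children = child.children
            for c in node.children:
                c.parent = node
            if node.length is not None or child.length is not None:
                node.length = (node.length or 0.0) + (child.length or 0.0)
            if node.support is None:
                node.support = child.support
        if (
            len(node.children) == 1
            and node.children[0].is_leaf
            and node.parent is not None
        ):
            # unifurcation above a leaf: merge edge lengths
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child
            child.parent = node.parent
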