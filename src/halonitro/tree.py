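"""Minimal rooted-representation tree used for neighbour-joining output.

An unrooted NJ tree is represented rooted at its final three-way join
(a trifurcating root); :func:`halonitro.phylogeny.root_on_outgroup`
converts it to a conventional rooted bifurcation.  Internal nodes may
carry an integer bootstrap support (percent of replicates).
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[int] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind}>"


class Tree:
    """A tree with labelled leaves, branch lengths and optional supports."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.traverse_preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find_leaf(self, label: str) -> Optional[TreeNode]:
        for n in self.leaves():
            if n.label == label:
                return n
        return None

    def leafset(self, node: TreeNode) -> frozenset[str]:
        return frozenset(
            n.label for n in node.traverse_preorder() if n.is_leaf
        )

    def bipartitions(self) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
        """Non-trivial leaf bipartitions induced by internal edges.

        Each split is canonicalised independently of rooting, so the set
        is invariant under re-rooting.  Trivial splits (single leaf vs
        rest) are excluded.
        """
        full = frozenset(self.leaf_labels())
        splits = set()
        for node in self.root.traverse_preorder():
            if node is self.root or node.is_leaf:
                continue
            side = self.leafset(node)
            if len(side) < 2 or len(full - side) < 2:
                continue
            splits.add(_canonical_split(side, full))
        return splits

    def support_by_split(self) -> dict:
        """Map canonical bipartition -> internal node carrying it."""
        full = frozenset(self.leaf_labels())
        out = {}
        for node in self.root.traverse_preorder():
            if node is self.root or node.is_leaf:
                continue
            side = self.leafset(node)
            if len(side) < 2 or len(full - side) < 2:
                continue
            out[_canonical_split(side, full)] = node
        return out

    def total_length(self) -> float:
        return sum(
            n.length or 0.0
            for n in self.root.traverse_preorder()
            if n is not self.root
        )

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.label, node.length, node.support)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return Tree(clone(self.root))


def _canonical_split(
    side: frozenset[str], full: frozenset[str]
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    a = tuple(sorted(side))
    b = tuple(sorted(full - side))
    return (a, b) if a <= b else (b, a)
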