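"""Rooted phylogenetic trees with integer branch lengths.

A deliberately small tree structure: leaves are biopsy regions, branch
lengths count inferred genomic changes, internal nodes may carry clade
bootstrap percentages, and branches carry free-text annotations (driver
labels).  Newick serialisation keeps branch lengths and writes clade
support as internal-node labels; parsing goes through dendropy so any
standard newick round-trips.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

__all__ = ["TreeNode", "PhyloTree", "rf_distance", "support_band"]


class TreeNode:
    __slots__ = ("name", "length", "support", "annotations", "children", "parent")

    def __init__(
        self,
        name: str = "",
        length: float = 0.0,
        support: Optional[float] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.annotations: list[str] = []
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, len={self.length}, n_children={len(self.children)})"


class PhyloTree:
    """A rooted tree whose leaf names are sample ids."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[TreeNode]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Optional[TreeNode]:
        for n in self.preorder():
            if n.name == name:
                return n
        return None

    def mrca(self, names: Iterable[str]) -> TreeNode:
        want = set(names)
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name} & want
            else:
                below[node] = set().union(*(below[c] for c in node.children))
        for node in self.postorder():
            if below[node] == want:
                return node
        raise ValueError(f"leaves {sorted(want)} not all present in tree")

    # -- splits and comparison --------------------------------------------

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each given as the smaller-side-free
        representation: the leaf set below each internal edge, excluding
        the root and single-leaf/full sets."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()
        below: dict[TreeNode, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node is not self.root:
                s = below[node]
                if 1 < len(s) < len(all_leaves) - 1:
                    out.add(s)
        return out

    def clade_sets(self) -> dict[frozenset[str], TreeNode]:
        """Map from below-edge leaf set to the node under that edge."""
        out: dict[frozenset[str], TreeNode] = {}
        below: dict[TreeNode, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            out[below[node]] = node
        return out

    # -- serialisation -----------------------------------------------------

    def to_newick(self, with_support: bool = True) -> str:
        def fmt_len(x: float) -> str:
            if float(x).is_integer():
                return str(int(x))
            return repr(round(float(x), 6))

        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name
            else:
                inner = ",".join(rec(c) for c in node.children)
                label = f"({inner})"
                if with_support and node.support is not None:
                    label += fmt_len(node.support)
                elif node.name:
                    label += node.name
            if node is self.root:
                return label
            return f"{label}:{fmt_len(node.length)}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(_from_dendropy(dtree.seed_node))

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.support)
            new.annotations = list(node.annotations)
            for c in node.children:
                new.add(rec(c))
            return new

        return PhyloTree(rec(self.root))


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        node = TreeNode(name=name)
    else:
        node = TreeNode(name="")
        label = dnode.label
        if label is not None:
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
    node.length = dnode.edge.length if dnode.edge.length is not None else 0.0
    for c in dnode.child_nodes():
        node.add(_from_dendropy(c))
    return node


def rf_distance(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Robinson-Foulds symmetric difference of non-trivial splits.

    Raises ``ValueError`` when the two trees carry different leaf sets.
    """
    la, lb = set(tree_a.leaf_names()), set(tree_b.leaf_names())
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")

    # Splits are compared as unordered bipartitions: normalise each side
    # to the half not containing a fixed reference leaf.
    ref = min(la)

    def norm(splits: set[frozenset[str]]) -> set[frozenset[str]]:
        return {s if ref not in s else frozenset(la - s) for s in splits}

    sa, sb = norm(tree_a.splits()), norm(tree_b.splits())
    return len(sa ^ sb)


def support_band(support: Optional[float]) -> str:
    """Banding used when drawing trees: blank for strong support (>95),
    '+' for moderate (65-95), '++' for weak (<65)."""
    if support is None:
        return ""
    if support > 95:
        return ""
    if support >= 65:
        return "+"
    return "++"
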