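"""Rooted dendrograms with merge heights and per-edge support.

The :class:`Dendrogram` is the shared tree container for the whole
package: hierarchical clustering produces one, Newick round-trips go
through it, and tree-comparison metrics consume it.  It is deliberately
small — nodes carry a leaf/internal label, an optional branch length, a
merge height, and an optional support record — and purely topological
queries (clades, bipartitions, leaf-pair edge-path distances) are
implemented directly on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

from .errors import NewickParseError

__all__ = ["Node", "Dendrogram"]


@dataclass
class Node:
    """A dendrogram node.

    ``name`` is the leaf label for leaves; for internal nodes it holds
    whatever label the source carried (e.g. a Newick support string).
    ``height`` is the merge height (cophenetic distance between the two
    subtrees being merged); leaves sit at height 0 in ultrametric trees.
    """

    name: Optional[str] = None
    length: Optional[float] = None
    height: float = 0.0
    children: list["Node"] = field(default_factory=list)
    edge_id: Optional[int] = None
    support: object = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Dendrogram:
    """A rooted tree over uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    def leaf_names(self) -> list[str]:
        """Leaf labels left to right."""
        return [n.name for n in self.root.walk() if n.is_leaf]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_names())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def clades(self) -> list[frozenset]:
        """Leaf sets of all proper internal nodes (root and leaves excluded)."""
        out = []
        self._collect_clades(self.root, out, is_root=True)
        return out

    def _collect_clades(self, node: Node, out: list, is_root: bool) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        members = frozenset().union(
            *(self._collect_clades(c, out, is_root=False) for c in node.children)
        )
        if not is_root:
            out.append(members)
        return members

    def bipartitions(self) -> set[frozenset]:
        """Informative rooted splits: proper clades with at least two leaves.

        These are the leaf sets below each internal edge of the rooted
        tree (singletons excluded — every tree has them).  Two rooted
        trees over the same leaves have equal topology iff these sets
        are equal, and bootstrap support is counted over exactly these.
        """
        n = len(self.leaf_set())
        return {c for c in self.clades() if 1 < len(c) < n}

    def path_distances(self) -> dict[tuple[str, str], int]:
        """Edge counts along the path between every unordered leaf pair.

        The tree is treated as drawn: both edges incident to the root
        count, so for the rooted triplet ((A,B),C) the distance A-C is 3.
        """
        depths: dict[str, int] = {}
        out: dict[tuple[str, str], int] = {}

        def descend(node: Node, depth: int) -> list[str]:
            if node.is_leaf:
                depths[node.name] = depth
                return [node.name]
            groups = [descend(c, depth + 1) for c in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a in groups[i]:
                        for b in groups[j]:
                            key = (a, b) if a < b else (b, a)
                            out[key] = depths[a] + depths[b] - 2 * depth
            merged = []
            for g in groups:
                merged.extend(g)
            return merged

        descend(self.root, 0)
        return out

    # ------------------------------------------------------------------
    # Newick round trip
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        """Serialise with branch lengths and internal labels.

        Branch lengths are taken from ``Node.length`` when set; otherwise
        they are derived from merge heights (parent height minus child
        height), which reconstructs the ultrametric tree produced by
        clustering.
        """

        def fmt(node: Node, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                body = f"({inner})" + (node.name or "")
            length = node.length
            if length is None and parent_height is not None:
                length = parent_height - node.height
            if length is not None:
                body += f":{length:g}"
            return body

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Dendrogram":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            node = Node()
            if dnode.taxon is not None:
                node.name = dnode.taxon.label
            elif dnode.label is not None:
                node.name = dnode.label
            node.length = dnode.edge.length
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        root = convert(dtree.seed_node)
        tree = cls(root)
        tree._set_heights_from_lengths()
        if not tree.leaf_names():
            raise NewickParseError("tree has no leaves")
        return tree

    def _set_heights_from_lengths(self) -> None:
        """Assign heights as the maximum path length down to a leaf."""

        def fill(node: Node) -> float:
            if node.is_leaf:
                node.height = 0.0
                return 0.0
            node.height = max(
                fill(c) + (c.length if c.length is not None else 1.0)
                for c in node.children
            )
            return node.height

        fill(self.root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dendrogram({self.to_newick()})"
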