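"""A minimal bifurcating phylogenetic tree with branch lengths and supports.

Branch lengths are in substitutions per site; bootstrap supports are
percentages (0-100) attached to internal edges and serialised as internal
node labels in Newick, the convention RAxML/PHYLIP-style consumers expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class Node:
    name: str = ""
    length: float = 0.0  # branch length to parent
    support: Optional[float] = None  # bootstrap % on the edge to parent
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted container for an (usually unrooted) phylogeny."""

    def __init__(self, root: Node):
        self.root = root
        leaves = self.leaf_names()
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names")

    # -- traversal ---------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-or-canonical leaf set.

        A split is represented by the frozenset of leaf names on the child
        side of an internal edge, canonicalised so the representation does
        not depend on rooting: the side not containing the lexicographically
        smallest leaf is used.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def clade(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(clade(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if anchor in below else below
                splits.add(side)
            return below

        clade(self.root)
        return splits

    def clade_map(self) -> dict[int, frozenset[str]]:
        """id(node) -> leaf set below that node."""
        out: dict[int, frozenset[str]] = {}

        def walk(node: Node) -> frozenset[str]:
            s = (
                frozenset([node.name])
                if node.is_leaf
                else frozenset().union(*(walk(c) for c in node.children))
            )
            out[id(node)] = s
            return s

        walk(self.root)
        return out

    # -- Newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip().rstrip(";")
        pos = 0

        def parse() -> Node:
            nonlocal pos
            node = Node()
            if text[pos] == "(":
                pos += 1
                node.children.append(parse())
                while text[pos] == ",":
                    pos += 1
                    node.children.append(parse())
                if text[pos] != ")":
                    raise ValueError(f"expected ')' at {pos} in newick")
                pos += 1
            # label (leaf name, or internal support)
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            label = text[start:pos]
            if node.is_leaf:
                node.name = label
            elif label:
                node.support = float(label)
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in ",();":
                    pos += 1
                node.length = float(text[start:pos])
            return node

        root = parse()
        return cls(root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.leaf_names())} leaves)"
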