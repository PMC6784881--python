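"""Phylogenetic tree container and Newick round-trip.

A :class:`Tree` is a rooted node structure (the root may be a
trifurcation, which is how unrooted trees are represented).  Branch
lengths are expected substitutions per site.  Parsing is delegated to
dendropy; the in-memory structure is a light node graph suited to the
pruning-likelihood machinery in :mod:`lirio.likelihood`.
"""

from __future__ import annotations

import io
import itertools
from typing import Iterable, Iterator

import dendropy

__all__ = ["Node", "Tree", "TreeError", "parse_newick", "write_newick"]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, {self.length!r}, n_children={len(self.children)})"


class Tree:
    """Rooted tree with named leaves and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise TreeError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf names: {dupes}")
        for node in self.postorder():
            if node.length is not None and not (node.length >= 0):
                raise TreeError(f"negative or non-finite branch length: {node.length}")

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def __len__(self) -> int:
        return len(self.leaves())

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    # -- utilities -----------------------------------------------------
    def scale_branches(self, factor: float) -> "Tree":
        """Return a copy with every branch length multiplied by `factor`."""
        out = self.copy()
        for node in out.postorder():
            if node.length is not None:
                node.length *= factor
        return out

    def set_branch_lengths(self, internal: float, terminal: float) -> "Tree":
        """Return a copy with uniform internal/terminal branch lengths."""
        out = self.copy()
        for node in out.postorder():
            if node is out.root:
                continue
            node.length = terminal if node.is_leaf else internal
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Patristic distance between every pair of leaves."""
        # accumulate root-to-leaf distances and LCA depths
        dist_to_root: dict[str, float] = {}
        ancestry: dict[str, list[Node]] = {}

        def walk(node: Node, acc: float, anc: list[Node]) -> None:
            acc2 = acc + (node.length or 0.0)
            anc2 = anc + [node]
            if node.is_leaf:
                dist_to_root[node.name] = acc2
                ancestry[node.name] = anc2
            for child in node.children:
                walk(child, acc2, anc2)

        walk(self.root, 0.0, [])
        out: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations(sorted(dist_to_root), 2):
            shared = 0.0
            for na, nb in zip(ancestry[a], ancestry[b]):
                if na is not nb:
                    break
                shared += na.length or 0.0
            out[(a, b)] = dist_to_root[a] + dist_to_root[b] - 2 * shared
        return out

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial leaf bipartitions (as the smaller-side leaf sets,
        canonicalized); equal sets <=> same unrooted topology."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            below = frozenset(l.name for l in _subtree_leaves(node))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return frozenset(parts)

    def same_topology(self, other: "Tree") -> bool:
        if set(self.leaf_names()) != set(other.leaf_names()):
            return False
        return self.bipartitions() == other.bipartitions()

    def prune_to_taxa(self, taxa: Iterable[str]) -> "Tree":
        return prune_to_taxa(self, taxa)

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.to_newick()!r})"


def _subtree_leaves(node: Node) -> list[Node]:
    if node.is_leaf:
        return [node]
    out: list[Node] = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def parse_newick(text: str) -> Tree:
    """Parse one Newick string into a :class:`Tree`.

    Raises :class:`TreeError` on malformed input or duplicate leaf names.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(name, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Tree(convert(dt.seed_node))


def _fmt_length(x: float) -> str:
    s = repr(float(x))
    return s


def write_newick(tree: Tree) -> str:
    def render(node: Node) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None and node.parent is not None:
            body += ":" + _fmt_length(node.length)
        return body

    return render(tree.root) + ";"


def prune_to_taxa(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Induced subtree on `taxa`, with degree-2 nodes suppressed and their
    branch lengths summed.  Leaf-to-leaf path lengths among retained taxa
    are preserved exactly."""
    keep = set(taxa)
    missing = keep - set(tree.leaf_names())
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 3:
        raise TreeError("pruning requires at least 3 taxa")

    work = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.name in keep else None
        kept = [c2 for c in node.children if (c2 := prune(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            # suppress this degree-2 node: fold its length into the child
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            child.parent = node.parent
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    new_root = prune(work.root)
    assert new_root is not None
    # a root that ended up with a single child is also suppressed
    while not new_root.is_leaf and len(new_root.children) == 1:
        new_root = new_root.children[0]
    new_root.parent = None
    if new_root.length is not None and not new_root.is_leaf:
        new_root.length = None
    return Tree(new_root)
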