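"""Phylogenetic trees with per-branch omega-category labels.

Newick parsing is delegated to dendropy; category tags use the codeml
convention of a ``#k`` suffix on a leaf or internal-node label, where the
tag on an internal node labels the branch subtending that node (its stem
edge).  Category 0 is the background.  Internally the tree is a plain
node structure so pruning, clade queries, and the likelihood engine's
postorder traversal stay simple and fast.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

_CAT_RE = re.compile(r"^(.*?)\s*#\s*(\d+)$")


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "category", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        category: int = 0,
    ) -> None:
        self.name = name
        self.length = length
        self.category = category
        self.children: list["Node"] = []
        self.parent: "Node" | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]


class PhyloTree:
    """Rooted (or arbitrarily rooted unrooted) tree over taxon labels."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self, categories: bool = True, lengths: bool = True) -> str:
        return _to_newick(self.root, categories, lengths) + ";"

    def write(self, path: str | Path, **kw) -> None:
        Path(path).write_text(self.to_newick(**kw) + "\n")

    # ------------------------------------------------------------ structure

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    @property
    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    @property
    def branches(self) -> list[Node]:
        """Every non-root node; each identifies the edge above itself."""
        return [n for n in self.postorder() if n is not self.root]

    @property
    def n_categories(self) -> int:
        return max(n.category for n in self.branches) + 1 if self.branches else 1

    def validate_categories(self) -> None:
        cats = sorted({n.category for n in self.branches})
        if cats != list(range(len(cats))):
            raise TreeError(f"branch categories {cats} are not contiguous from 0")

    def find_leaf(self, name: str) -> Node:
        for n in self.postorder():
            if n.is_leaf and n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def mrca(self, taxa: Iterable[str]) -> Node:
        """Most recent common ancestor of the given leaf labels."""
        want = set(taxa)
        missing = want - set(self.leaves)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        node = self.find_leaf(next(iter(want)))
        while not want <= set(node.leaf_names()):
            node = node.parent
            if node is None:  # pragma: no cover - root covers everything
                raise TreeError("MRCA search escaped the root")
        return node

    def clade_id(self, node: Node) -> tuple[str, ...]:
        """Canonical identifier of the edge above ``node``: its leaf set."""
        return tuple(sorted(node.leaf_names()))

    # ----------------------------------------------------------- operations

    def copy(self) -> "PhyloTree":
        return PhyloTree(_clone(self.root))

    def prune_to(self, taxa: Sequence[str]) -> "PhyloTree":
        """Restrict to the given taxa, preserving the induced topology.

        Unifurcations created by pruning are suppressed, summing branch
        lengths along the collapsed path; the surviving edge keeps the
        category of the edge nearest the leaves.
        """
        keep = set(taxa)
        missing = keep - set(self.leaves)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        root = _clone(self.root)
        root = _prune(root, keep)
        if root is None:
            raise TreeError("pruning removed every leaf")
        root = _suppress_unifurcations(root)
        root.parent = None
        return PhyloTree(root)

    def set_categories(
        self,
        foreground: Iterable[str] | None = None,
        category: int = 1,
        clade_inclusive: bool = True,
        reset: bool = False,
    ) -> None:
        """Label foreground branches with an omega category.

        With ``clade_inclusive`` every branch whose descendant leaves all
        lie in ``foreground`` is labelled (stem and internal branches of a
        foreground clade included); otherwise only the terminal branches of
        the named taxa are labelled.
        """
        if reset:
            for n in self.postorder():
                n.category = 0
        if foreground is None:
            return
        fg = set(foreground)
        for n in self.branches:
            if n.is_leaf:
                if n.name in fg:
                    n.category = category
            elif clade_inclusive and set(n.leaf_names()) <= fg:
                n.category = category

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches)

    def set_lengths(self, value: float | Callable[[Node], float]) -> None:
        for n in self.branches:
            n.length = value(n) if callable(value) else value


# ------------------------------------------------------------------ helpers


def _split_category(label: str | None) -> tuple[str | None, int]:
    if not label:
        return label, 0
    m = _CAT_RE.match(label)
    if m:
        return (m.group(1) or None), int(m.group(2))
    return label, 0


def _from_dendropy(dnode) -> Node:
    raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
    name, cat = _split_category(raw)
    node = Node(name=name, length=dnode.edge.length, category=cat)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    if node.is_leaf and node.name is None:
        raise TreeError("leaf without a label in newick input")
    return node


def _to_newick(node: Node, categories: bool, lengths: bool) -> str:
    if node.is_leaf:
        s = node.name or ""
    else:
        s = "(" + ",".join(_to_newick(c, categories, lengths) for c in node.children) + ")"
        if node.name:
            s += node.name
    if categories and node.category and node.parent is not None:
        s += f"#{node.category}"
    if lengths and node.length is not None and node.parent is not None:
        s += f":{node.length:.10g}"
    return s


def _clone(node: Node) -> Node:
    new = Node(name=node.name, length=node.length, category=node.category)
    for c in node.children:
        new.add_child(_clone(c))
    return new


def _prune(node: Node, keep: set[str]) -> Node | None:
    if node.is_leaf:
        return node if node.name in keep else None
    kept = []
    for c in node.children:
        p = _prune(c, keep)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    node.children = []
    for c in kept:
        node.add_child(c)
    return node


def _suppress_unifurcations(node: Node, is_root: bool = True) -> Node:
    """Collapse degree-2 nodes bottom-up, summing lengths along the chain.

    The surviving edge keeps the category of the edge nearest the leaves.
    A unifurcate root is replaced by its child (whose edge length is then
    meaningless and dropped).
    """
    new_children = [_suppress_unifurcations(c, is_root=False) for c in node.children]
    node.children = []
    for c in new_children:
        node.add_child(c)
    if len(node.children) == 1:
        child = node.children[0]
        if is_root:
            child.parent = None
            child.length = None
            return child
        child.length = (node.length or 0.0) + (child.length or 0.0)
        return child
    return node
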