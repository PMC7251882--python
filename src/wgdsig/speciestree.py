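"""Dated species trees.

A :class:`DatedSpeciesTree` is a rooted binary tree whose branch lengths are
in calendar time (My), as obtained from e.g. the TimeTree database.  Every
branch is identified by the node below it: leaf branches carry the species
name, internal branches an internal node label (auto-generated if the newick
has none).  The branch above the root has length 0 and is never referenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class DatedSpeciesTree:
    """Rooted, binary, ultrametric-in-intent species tree.

    Attributes
    ----------
    parent : list[int]
        ``parent[i]`` is the parent node index of node ``i`` (-1 for root).
    length : list[float]
        Branch length (My) above each node; 0.0 for the root.
    label : list[str]
        Node label; species name for leaves, unique id for internal nodes.
    """

    parent: list[int]
    length: list[float]
    label: list[str]
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not (len(self.length) == len(self.label) == n):
            raise TreeError("parent/length/label arrays must have equal size")
        roots = [i for i, p in enumerate(self.parent) if p < 0]
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self._children = {i: [] for i in range(n)}
        for i, p in enumerate(self.parent):
            if p >= 0:
                self._children[p].append(i)
        for i, kids in self._children.items():
            if kids and len(kids) != 2:
                raise TreeError(f"node {self.label[i]} is not binary")
        if any(l < 0 for l in self.length):
            raise TreeError("negative branch length")
        if len(set(self.label)) != n:
            raise TreeError("branch ids (node labels) must be unique")

    # -- basic structure ---------------------------------------------------

    @property
    def root(self) -> int:
        return next(i for i, p in enumerate(self.parent) if p < 0)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def is_leaf(self, node: int) -> bool:
        return not self._children[node]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.label[i] for i in self.leaves]

    def node_by_label(self, label: str) -> int:
        try:
            return self.label.index(label)
        except ValueError:
            raise TreeError(f"unknown branch id {label!r}") from None

    def postorder(self) -> list[int]:
        """Node indices, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self._children[node])
        order.reverse()
        return order

    def leaf_set(self, node: int) -> set[int]:
        """All leaf indices in the clade below ``node``."""
        out: set[int] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.add(v)
            else:
                stack.extend(self._children[v])
        return out

    def root_clades(self) -> tuple[set[int], set[int]]:
        """Leaf sets of the two clades stemming from the root."""
        kids = self._children[self.root]
        if len(kids) != 2:
            raise TreeError("root must have exactly two children")
        return self.leaf_set(kids[0]), self.leaf_set(kids[1])

    def is_dated(self) -> bool:
        """True if every non-root branch has strictly positive length."""
        r = self.root
        return all(l > 0 for i, l in enumerate(self.length) if i != r)

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "DatedSpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, length, label = [], [], []
        auto = 0
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            length.append(float(nd.edge.length or 0.0))
            if nd.taxon is not None:
                label.append(nd.taxon.label.replace(" ", "_"))
            elif nd.label:
                label.append(nd.label)
            else:
                label.append(f"n{auto}")
                auto += 1
        return cls(parent=parent, length=length, label=label)

    @classmethod
    def read(cls, path) -> "DatedSpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if self.is_leaf(node):
                core = self.label[node]
            else:
                inner = ",".join(fmt(c) for c in self._children[node])
                core = f"({inner}){self.label[node]}"
            if node == self.root:
                return core
            return f"{core}:{self.length[node]:g}"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def balanced_dated_tree(species: Iterable[str], depth: float = 300.0) -> DatedSpeciesTree:
    """A caterpillar-free balanced-ish dated tree over ``species``.

    Convenience constructor for simulations: splits the species list
    recursively in half, assigning equal-height subtrees so the tree is
    ultrametric with total depth ``depth`` My.
    """
    species = list(species)
    if len(species) < 2:
        raise TreeError("need at least two species")

    def build(names: list[str], h: float) -> str:
        if len(names) == 1:
            return f"{names[0]}:{h:g}"
        mid = len(names) // 2
        child_h = h / 2
        left = build(names[:mid], child_h)
        right = build(names[mid:], child_h)
        return f"({left},{right}):{h - child_h:g}"

    mid = len(species) // 2
    newick = f"({build(species[:mid], depth)},{build(species[mid:], depth)});"
    return DatedSpeciesTree.from_newick(newick)
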