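"""Rooted phylogenies for likelihood computation.

Thin wrapper around a dendropy-parsed Newick tree, flattened into an
index-based structure convenient for postorder dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class TreeNode:
    label: str | None
    length: float  # branch length to parent (expected substitutions/site)
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with nonnegative branch lengths.

    Internal nodes without explicit labels get generated ones
    (``node0`` for the root, then preorder ``node1``, ``node2``, ...)
    so every ancestor can be queried.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._label_nodes()
        self._index = {}
        for node in self.preorder():
            if node.label in self._index:
                raise ValueError(f"duplicate node label {node.label!r}")
            self._index[node.label] = node
        for node in self.preorder():
            if node.length < 0:
                raise ValueError("branch lengths must be nonnegative")

    def _label_nodes(self) -> None:
        counter = 0
        for node in self.preorder():
            if not node.label:
                node.label = f"node{counter}"
            counter += 1

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(dnode, parent=None):
            if dnode.taxon is not None:
                label = dnode.taxon.label
            else:
                label = dnode.label
            node = TreeNode(
                label=label,
                length=dnode.edge.length if dnode.edge.length is not None else 0.0,
                parent=parent,
            )
            node.children = [convert(c, node) for c in dnode.child_nodes()]
            return node

        return cls(convert(tree.seed_node))

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index
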