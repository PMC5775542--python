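"""Phylogenies with wild/domestic branch classes.

Trees enter the pipeline as Newick strings in the branch-tag dialect used
by branch-model Ka/Ks software: a ``#1`` suffix on a leaf or internal-node
label marks the subtending branch as DOMESTIC; every unmarked branch is
WILD.  Tags are not inherited by descendant branches — each DOMESTIC
branch is marked explicitly.

Internally the tree is a plain rooted node structure; the substitution
model is time-reversible, so the likelihood does not depend on root
placement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

WILD = "WILD"
DOMESTIC = "DOMESTIC"

_TAG_SENTINEL = "xDOMTAGx"


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    branch_class: str = WILD
    children: list = field(default_factory=list)
    branch_id: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children


class TaggedTree:
    """Rooted tree with per-branch lengths and WILD/DOMESTIC classes.

    Every node except the root subtends exactly one branch; the node's
    ``length`` and ``branch_class`` describe that branch.  Branch ids are
    stable: the leaf name for terminal branches, ``inner<k>`` (preorder)
    for internal ones.
    """

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "TaggedTree":
        """Parse a Newick string in the ``#1`` branch-tag dialect."""
        tagged = re.sub(r"\s*#\s*1(?=\s*[:,)(;])", _TAG_SENTINEL, newick)
        if "#" in tagged:
            raise ValueError("unsupported branch tag in Newick "
                             "(only '#1' is recognised)")
        dtree = dendropy.Tree.get(
            data=tagged, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label is not None:
                label = dnode.label
            cls_ = WILD
            if label is not None and label.endswith(_TAG_SENTINEL):
                cls_ = DOMESTIC
                label = label[: -len(_TAG_SENTINEL)].strip() or None
            node = Node(
                name=label,
                length=dnode.edge.length if dnode.edge.length is not None else 0.0,
                branch_class=cls_,
                children=[convert(c) for c in dnode.child_nodes()],
            )
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        """Serialise back to the ``#1`` dialect (root length omitted)."""

        def fmt(node: Node, is_root: bool) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if not is_root:
                if node.branch_class == DOMESTIC:
                    s += " #1"
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root, True) + ";"

    # -- traversal ----------------------------------------------------

    def postorder(self):
        out = []

        def walk(node):
            for c in node.children:
                walk(c)
            out.append(node)

        walk(self.root)
        return out

    def preorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    @property
    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self):
        return [n.name for n in self.leaves]

    @property
    def branches(self):
        """All nodes that subtend a branch (everything but the root)."""
        return [n for n in self.preorder() if n is not self.root]

    def branch_classes(self) -> set:
        return {n.branch_class for n in self.branches}

    # -- bookkeeping ---------------------------------------------------

    def _assign_ids(self):
        k = 0
        for node in self.preorder():
            if node is self.root:
                node.branch_id = "root"
            elif node.is_leaf:
                if not node.name:
                    raise ValueError("unnamed leaf")
                node.branch_id = node.name
            else:
                node.branch_id = f"inner{k}"
                k += 1

    def validate(self):
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        for node in self.branches:
            if not (node.length >= 0.0 and node.length == node.length
                    and node.length != float("inf")):
                raise ValueError(
                    f"branch {node.branch_id}: invalid length {node.length}")
            if node.branch_class not in (WILD, DOMESTIC):
                raise ValueError(
                    f"branch {node.branch_id}: unknown class {node.branch_class}")

    def check_taxa(self, taxa) -> None:
        tree_taxa = set(self.leaf_names)
        aln_taxa = set(taxa)
        if tree_taxa != aln_taxa:
            missing = sorted(aln_taxa - tree_taxa)
            extra = sorted(tree_taxa - aln_taxa)
            raise ValueError(
                f"tree/alignment taxa mismatch (alignment-only: {missing}, "
                f"tree-only: {extra})")

    def unrooted(self) -> "TaggedTree":
        """Collapse a degree-2 root into a trifurcation (new tree).

        With a rooted tree the two root-adjacent branch lengths are not
        separately identifiable under a reversible model, which distorts
        likelihood-ratio comparisons between branch-class models; ML
        fitting therefore works on the unrooted shape.  The merged
        branch is DOMESTIC if either collapsed root edge was (the
        wild/domestic boundary lies on that path).
        """
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        internal = [c for c in root.children if not c.is_leaf]
        if not internal:
            return tree   # two-leaf tree: nothing to collapse
        a = internal[0]
        b = root.children[1] if a is root.children[0] else root.children[0]
        b.length += a.length
        if a.branch_class == DOMESTIC or b.branch_class == DOMESTIC:
            b.branch_class = DOMESTIC
        root.children = list(a.children) + [b]
        return TaggedTree(root)

    def copy(self) -> "TaggedTree":

        def clone(node: Node) -> Node:
            return Node(node.name, node.length, node.branch_class,
                        [clone(c) for c in node.children], node.branch_id)

        return TaggedTree(clone(self.root))

    def total_length(self, branch_class: str | None = None) -> float:
        return sum(n.length for n in self.branches
                   if branch_class is None or n.branch_class == branch_class)
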