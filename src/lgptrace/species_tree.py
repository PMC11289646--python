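"""Rooted species tree with clade / MRCA / sister / root-path queries.

The phylogeny is the coordinate system of the whole analysis: orthogroup and
domain origins are tree nodes, fold changes compare a clade against its
sister lineage, and LGP classification asks about presence outside a clade
and along the chain of ancestors of a focal node (by default the land-plant
LCA).  Internal nodes are addressed by unique labels so that any rooted
Newick tree with named backbone nodes can be used.

Multifurcations are permitted anywhere except at the root (the root must be
a bifurcation so that "sister of the root's child" is well defined); at a
multifurcating node the sister of a child is the union of its co-children.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = ["TreeNode", "SpeciesTree"]


@dataclass(eq=False)
class TreeNode:
    """A node of a :class:`SpeciesTree`.

    ``name`` is the species ID for leaves and the (optional) internal label
    otherwise.  ``leafset`` caches the species under the node.
    """

    name: str | None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    leafset: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "node"
        return f"<{kind} {self.name or '?'} ({len(self.leafset)} spp)>"


class SpeciesTree:
    """Rooted tree over species with named internal nodes and a focal node.

    Parameters
    ----------
    root:
        Root :class:`TreeNode` of a fully built node structure.
    focal_label:
        Label of the focal node (default ``"land_plants"``); resolved lazily
        so trees without the default label can still be constructed and used
        for queries that do not need a focal node.
    """

    DEFAULT_FOCAL_LABEL = "land_plants"

    def __init__(self, root: TreeNode, focal_label: str = DEFAULT_FOCAL_LABEL):
        self.root = root
        self.focal_label = focal_label
        self._autolabel_internals()
        self._by_name: dict[str, TreeNode] = {}
        self._leaves: list[TreeNode] = []
        for node in self.preorder():
            if node.name is not None:
                if node.name in self._by_name:
                    raise ValueError(f"duplicate node name {node.name!r} in tree")
                self._by_name[node.name] = node
            if node.is_leaf:
                if node.name is None:
                    raise ValueError("leaf without a species ID")
                self._leaves.append(node)
        self._fill_leafsets(self.root)

    def _autolabel_internals(self) -> None:
        """Give unnamed internal nodes stable labels (N1, N2, … in preorder).

        Origin assignment and reporting address every node by name; trees in
        the wild rarely label all internal nodes, so missing labels are
        filled deterministically from the topology.
        """
        taken = {n.name for n in self.preorder() if n.name is not None}
        counter = 1
        for node in self.preorder():
            if not node.is_leaf and node.name is None:
                while f"N{counter}" in taken:
                    counter += 1
                node.name = f"N{counter}"
                taken.add(node.name)

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, focal_label: str = DEFAULT_FOCAL_LABEL) -> "SpeciesTree":
        """Parse a rooted Newick string with internal-node labels.

        The root must be bifurcating; a multifurcating root is rejected with
        an instruction to root the tree first (an unrooted tree is
        conventionally written with a basal trifurcation).
        """
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        droot = dtree.seed_node
        if len(droot.child_nodes()) != 2:
            raise ValueError(
                "tree root is not bifurcating (found "
                f"{len(droot.child_nodes())} children); root the tree before use"
            )

        def build(dnode, parent):
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            else:
                name = dnode.label
            node = TreeNode(name=name, parent=parent)
            for child in dnode.child_nodes():
                node.children.append(build(child, node))
            return node

        return cls(build(droot, None), focal_label=focal_label)

    @classmethod
    def from_newick_file(cls, path, focal_label: str = DEFAULT_FOCAL_LABEL) -> "SpeciesTree":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_newick(fh.read(), focal_label=focal_label)

    def _fill_leafsets(self, node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            node.leafset = frozenset([node.name])
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= self._fill_leafsets(child)
            node.leafset = frozenset(acc)
        return node.leafset

    # -- basic accessors ----------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaves(self) -> list[str]:
        return [leaf.name for leaf in self._leaves]

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.root.leafset

    def node(self, name: str) -> TreeNode:
        """Look up a node (leaf or internal) by name."""
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no node named {name!r} in tree") from None

    @property
    def focal(self) -> TreeNode:
        return self.node(self.focal_label)

    def internal_labels(self) -> list[str]:
        return [n.name for n in self.preorder() if not n.is_leaf and n.name is not None]

    # -- queries -------------------------------------------------------

    def mrca(self, species: set[str] | frozenset[str]) -> TreeNode:
        """Most recent common ancestor of a non-empty set of leaves.

        A singleton set maps to the leaf itself.  Implemented by descending
        from the root into the unique child whose leafset still covers the
        query, which is linear in tree depth.
        """
        query = frozenset(species)
        if not query:
            raise ValueError("mrca of an empty species set is undefined")
        unknown = query - self.leaf_set
        if unknown:
            raise KeyError(f"unknown species: {', '.join(sorted(unknown))}")
        node = self.root
        while not node.is_leaf:
            covering = [c for c in node.children if query <= c.leafset]
            if not covering:
                return node
            node = covering[0]
        return node

    def clade_species(self, node: TreeNode | str) -> frozenset[str]:
        return self._resolve(node).leafset

    def sister_species(self, node: TreeNode | str) -> frozenset[str]:
        """Leaves of the sister lineage: all other children of the parent."""
        node = self._resolve(node)
        if node.parent is None:
            raise ValueError("the root has no sister lineage")
        acc: set[str] = set()
        for child in node.parent.children:
            if child is not node:
                acc |= child.leafset
        return frozenset(acc)

    def outgroup_species(self, node: TreeNode | str) -> frozenset[str]:
        return self.leaf_set - self._resolve(node).leafset

    def ancestors(self, node: TreeNode | str, include_root: bool = True) -> list[TreeNode]:
        """Ancestors from the node's parent up to (optionally) the root."""
        node = self._resolve(node)
        out = []
        cur = node.parent
        while cur is not None:
            if cur.parent is not None or include_root:
                out.append(cur)
            cur = cur.parent
        return out

    def path_to_focal(self) -> list[TreeNode]:
        """Ordered root-to-focal chain of nodes (inclusive at both ends)."""
        path = [self.focal]
        cur = self.focal.parent
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        path.reverse()
        return path

    def is_descendant_or_equal(self, node: TreeNode | str, ancestor: TreeNode | str) -> bool:
        node = self._resolve(node)
        ancestor = self._resolve(ancestor)
        cur = node
        while cur is not None:
            if cur is ancestor:
                return True
            cur = cur.parent
        return False

    def _resolve(self, node: TreeNode | str) -> TreeNode:
        if isinstance(node, TreeNode):
            return node
        return self.node(node)

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        buf = io.StringIO()

        def write(node: TreeNode):
            if node.is_leaf:
                buf.write(node.name)
                return
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                write(child)
            buf.write(")")
            if node.name:
                buf.write(node.name)

        write(self.root)
        buf.write(";")
        return buf.getvalue()
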