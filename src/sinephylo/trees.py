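"""Rooted trees for presence/absence character phylogenetics.

A deliberately small mutable tree structure tuned for the operations the
package needs: postorder traversal, clade (descendant leaf set) queries,
leaf insertion/removal during stepwise addition, NNI/SPR rearrangement and
outgroup rerooting.  Newick text is parsed with dendropy; writing is a
plain recursive emitter so per-edge annotation comments stay under our
control.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Optional

import dendropy

from .errors import InputError

__all__ = ["Node", "RootedTree", "tree_from_clades"]


class Node:
    __slots__ = ("children", "parent", "label", "length", "annotations")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.length = length
        self.annotations: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '·'} children={len(self.children)}>"


class RootedTree:
    """A rooted phylogeny with uniquely labelled leaves.

    Edges are identified by their child node; the *clade* of an edge is the
    frozenset of leaf labels below it, which is the stable edge identifier
    used throughout (reconstruction, support tables, bootstrap tallies).
    """

    def __init__(self, root: Node):
        self.root = root
        self.annotations: dict = {}

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        return cls._from_dendropy(dt)

    @classmethod
    def read(cls, path) -> "RootedTree":
        dt = dendropy.Tree.get(path=str(path), schema="newick",
                               preserve_underscores=True)
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "RootedTree":
        def build(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(build(child))
            return node

        tree = cls(build(dt.seed_node))
        for leaf in tree.leaves():
            if leaf.label is None:
                raise InputError("newick tree contains an unlabelled leaf")
        labels = [leaf.label for leaf in tree.leaves()]
        if len(labels) != len(set(labels)):
            raise InputError("duplicate leaf labels in tree")
        return tree

    def to_newick(self, lengths: bool = False, annotations: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += _quote(node.label)
            if annotations and node.annotations:
                body = ",".join(f"{k}={v}" for k, v in sorted(node.annotations.items()))
                s += f"[&{body}]"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    # ------------------------------------------------------------ traversal
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    # --------------------------------------------------------------- clades
    def clade_map(self) -> dict[Node, frozenset]:
        """Descendant leaf-label set for every node, bottom-up."""
        clades: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                clades[node] = frozenset([node.label])
            else:
                acc: set = set()
                for child in node.children:
                    acc |= clades[child]
                clades[node] = frozenset(acc)
        return clades

    def clades(self, trivial: bool = False) -> set[frozenset]:
        """Clades of all edges; by default only non-trivial ones
        (>1 leaf, not the full leaf set)."""
        cm = self.clade_map()
        full = cm[self.root]
        out = set()
        for node, clade in cm.items():
            if node is self.root:
                continue
            if not trivial and (len(clade) < 2 or clade == full):
                continue
            out.add(clade)
        return out

    def find_clade(self, leafset: Iterable[str]) -> Optional[Node]:
        target = frozenset(leafset)
        for node, clade in self.clade_map().items():
            if clade == target:
                return node
        return None

    # ----------------------------------------------------------- structure
    def copy(self) -> "RootedTree":
        def dup(node: Node) -> Node:
            clone = Node(label=node.label, length=node.length)
            clone.annotations = dict(node.annotations)
            for child in node.children:
                clone.add_child(dup(child))
            return clone

        tree = RootedTree(dup(self.root))
        tree.annotations = dict(self.annotations)
        return tree

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        parent.children[idx] = child
                        child.parent = parent
                    changed = True
                    break

    def insert_leaf_on_edge(self, child: Node, label: str) -> Node:
        """Insert a new leaf on the edge above ``child``; returns the new
        attachment node.  If ``child`` is the root a new root is created
        (attachment on the stem)."""
        attach = Node()
        leaf = Node(label=label)
        parent = child.parent
        if parent is None:
            attach.add_child(child)
            attach.add_child(leaf)
            self.root = attach
        else:
            idx = parent.children.index(child)
            parent.children[idx] = attach
            attach.parent = parent
            attach.add_child(child)
            attach.add_child(leaf)
        return attach

    def remove_leaf(self, leaf: Node) -> None:
        parent = leaf.parent
        if parent is None:
            raise InputError("cannot remove the only node of a tree")
        parent.remove_child(leaf)
        self.suppress_unifurcations()

    def reroot_above(self, node: Node) -> None:
        """Reroot so the root's two children are ``node``'s subtree and the
        rest of the tree."""
        if node.parent is None:
            return
        # detach node, then reverse the parent chain
        old_parent = node.parent
        old_parent.remove_child(node)
        new_root = Node()
        new_root.add_child(node)
        new_root.add_child(_reverse_chain(old_parent, self.root))
        self.root = new_root
        self.suppress_unifurcations()

    def collapse_edge(self, child: Node) -> None:
        """Collapse the internal edge above ``child`` (child's children are
        promoted into its parent)."""
        parent = child.parent
        if parent is None or child.is_leaf:
            raise InputError("can only collapse internal, non-root edges")
        idx = parent.children.index(child)
        parent.children.pop(idx)
        for i, grand in enumerate(child.children):
            grand.parent = parent
            parent.children.insert(idx + i, grand)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return (set(self.leaf_labels()) == set(other.leaf_labels())
                and self.clades(trivial=True) == other.clades(trivial=True))

    def __hash__(self):  # topological identity
        return hash(frozenset(self.clades(trivial=True)))


def _reverse_chain(node: Node, root: Node) -> Node:
    """Reverse parentage from ``node`` up to ``root``; returns ``node`` as
    the head of the reversed subtree."""
    if node.parent is None:
        return node
    parent = node.parent
    parent.remove_child(node)
    node.add_child(_reverse_chain(parent, root))
    node.parent = None
    return node


def tree_from_clades(leaf_labels: Iterable[str], clades: Iterable[frozenset]) -> RootedTree:
    """Build the (possibly multifurcating) rooted tree displaying exactly the
    given compatible clades."""
    labels = list(leaf_labels)
    full = frozenset(labels)
    nontrivial = sorted(
        {frozenset(c) for c in clades if 1 < len(c) < len(full)},
        key=lambda c: (-len(c), sorted(c)),
    )
    for c in nontrivial:
        if not c <= full:
            raise InputError(f"clade {sorted(c)} not a subset of the leaf set")
    for i, a in enumerate(nontrivial):
        for b in nontrivial[i + 1:]:
            if a & b and not (a <= b or b <= a):
                raise InputError("incompatible clades cannot form a tree")
    root = Node()
    owner: dict[frozenset, Node] = {full: root}
    ordered = [full] + nontrivial
    # processed largest-first, so each clade's host is its smallest strict
    # superset and existing siblings are necessarily disjoint from it
    for clade in nontrivial:
        host_clade = min((c for c in ordered if clade < c), key=len)
        owner[clade] = owner[host_clade].add_child(Node())
    for label in labels:
        host = owner[min((c for c in ordered if label in c), key=len)]
        host.add_child(Node(label=label))
    tree = RootedTree(root)
    # order children deterministically by smallest leaf label
    cm = tree.clade_map()
    for node in tree.postorder():
        node.children.sort(key=lambda ch: min(cm[ch]))
    return tree


def _node_leafsets(node: Node) -> list[tuple[Node, frozenset]]:
    out = []
    for child in node.children:
        acc: set = set()
        stack = [child]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                acc.add(cur.label)
            else:
                stack.extend(cur.children)
        out.append((child, frozenset(acc)))
    return out


_SAFE = re.compile(r"^[\w.\-|]+$")


def _quote(label: str) -> str:
    if label is None:
        return ""
    if _SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"
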