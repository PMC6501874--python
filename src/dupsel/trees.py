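"""Phylogenetic trees with branch lengths, support values and foreground marks.

Newick parsing is delegated to dendropy; the PAML-style ``#1`` branch tag
dialect used to designate foreground branches for branch-site tests is not
part of standard Newick, so tags are lifted into node labels by a regex
pre-pass before parsing and restored onto the corresponding branches
afterwards.  Writing emits the same dialect (`` #1`` after the branch
length) so trees round-trip.

Each branch is identified by its child node.  Node ids are assigned in
preorder and are stable for a given topology, so unnamed internal branches
can be addressed as ``node<k>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import dendropy

_FGTAG = "__FGTAG"
_NUM = r"[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass
class Node:
    id: int = -1
    name: Optional[str] = None
    length: float = 0.0
    foreground: bool = False
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def label(self) -> str:
        return self.name if self.name is not None else f"node{self.id}"

    def __repr__(self) -> str:  # keep dataclass repr from recursing via parent
        return f"Node({self.label}, t={self.length}, fg={self.foreground})"


class PhyloTree:
    """A rooted view of a (possibly unrooted) phylogeny.

    Branch lengths are expected substitutions per codon.  The foreground
    flag lives on the child node of the marked branch.  Likelihoods under
    reversible models are invariant to the root placement, so consuming an
    unrooted Newick as rooted-at-the-basal-polytomy is safe.
    """

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()

    def _assign_ids(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.id = i
            for child in node.children:
                child.parent = node

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.label for n in self.tips()]

    def branches(self) -> list[Node]:
        """All non-root nodes; each represents the branch above it."""
        return [n for n in self.preorder() if n.parent is not None]

    def find(self, key: int | str) -> Node:
        for node in self.preorder():
            if node.id == key or node.name == key or node.label == key:
                return node
        raise KeyError(f"no node {key!r} in tree")

    # -- foreground handling ----------------------------------------------
    @property
    def foreground(self) -> list[Node]:
        return [n for n in self.branches() if n.foreground]

    def clear_foreground(self) -> None:
        for node in self.preorder():
            node.foreground = False

    def mark_foreground(self, *keys: int | str) -> None:
        for key in keys:
            node = self.find(key)
            if node.parent is None:
                raise ValueError("root has no branch to mark as foreground")
            node.foreground = True

    def with_foreground(self, *keys: int | str) -> "PhyloTree":
        tree = self.copy()
        tree.clear_foreground()
        tree.mark_foreground(*keys)
        return tree

    # -- structure ---------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            return Node(name=node.name, length=node.length, foreground=node.foreground,
                        support=node.support, children=[clone(c) for c in node.children])
        return PhyloTree(clone(self.root))

    def rerooted_at(self, key: int | str) -> "PhyloTree":
        """A copy rooted at the given internal node.

        Rooting at a tip is refused: the tip's observation would no longer
        correspond to a leaf.  Use :meth:`rerooted_on_branch` to place the
        root on a terminal branch instead.
        """
        tree = self.copy()
        target = tree.find(key)
        if target.is_tip:
            raise ValueError("cannot reroot at a tip; use rerooted_on_branch")
        if target.parent is None:
            return tree
        # reverse the path target -> old root
        path = []
        node: Optional[Node] = target
        while node is not None:
            path.append(node)
            node = node.parent
        orig = {id(n): (n.length, n.foreground) for n in path}
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
            child.children.append(parent)
            # branch child-parent was stored on child; now parent hangs below child
            parent.length, parent.foreground = orig[id(child)]
        target.length = 0.0
        target.foreground = False
        return PhyloTree(target)

    def rerooted_on_branch(self, key: int | str, fraction: float = 0.5) -> "PhyloTree":
        """A copy with a new root placed on the branch above the given node.

        The branch of length t is split into t*fraction (below, toward the
        node) and t*(1-fraction) (toward the rest of the tree).  Under
        reversible models the likelihood is invariant to this placement.
        """
        if not (0.0 <= fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        tree = self.copy()
        node = tree.find(key)
        parent = node.parent
        if parent is None:
            raise ValueError("the root has no branch to reroot on")
        t, fg = node.length, node.foreground
        path = []
        p: Optional[Node] = parent
        while p is not None:
            path.append(p)
            p = p.parent
        orig = {id(n): (n.length, n.foreground) for n in path}
        for child, par in zip(path, path[1:]):
            par.children.remove(child)
            child.children.append(par)
            par.length, par.foreground = orig[id(child)]
        parent.children.remove(node)
        node.length = t * fraction
        node.foreground = fg
        parent.length = t * (1.0 - fraction)
        parent.foreground = fg  # both halves of a split foreground branch stay marked
        new_root = Node(children=[node, parent])
        return PhyloTree(new_root)

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    def unrooted_canonical(self) -> "PhyloTree":
        """Copy with any basal bifurcation collapsed into a multifurcation.

        A rooted binary representation of an unrooted tree carries the
        root on an edge, splitting it in two; under reversible models only
        the sum of the two parts is identifiable.  Collapsing the fake
        root node gives every unrooted edge a unique representative node,
        which keeps branch-length bookkeeping stable across rerooting.
        Tip names are preserved; unnamed internal nodes receive stable
        ``node<k>`` names so fitted branch lengths can be keyed by label.
        """
        tree = self.copy()
        root = tree.root
        while len(root.children) == 2 and any(not c.is_tip for c in root.children):
            absorb = next(c for c in root.children if not c.is_tip)
            other = next(c for c in root.children if c is not absorb)
            other.length += absorb.length
            other.foreground = other.foreground or absorb.foreground
            if root.name is None:
                root.name = absorb.name
            if root.support is None:
                root.support = absorb.support
            root.children = [c for c in root.children if c is not absorb] + absorb.children
            root = tree.root
            tree._assign_ids()
        tree._assign_ids()
        for node in tree.preorder():
            if node.name is None:
                node.name = f"node{node.id}"
        return tree

    # -- newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return _parse_newick(text)

    def to_newick(self, include_foreground: bool = True,
                  include_support: bool = True) -> str:
        def render(node: Node) -> str:
            if node.is_tip:
                core = node.name or ""
            else:
                inner = ",".join(render(c) for c in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = _fmt_num(node.support)
                elif node.name:
                    label = node.name
                core = f"({inner}){label}"
            if node.parent is not None:
                core += f":{_fmt_num(node.length)}"
                if include_foreground and node.foreground:
                    core += " #1"
            return core
        return render(self.root) + ";"


def _fmt_num(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _extract_tags(text: str) -> str:
    # move "...:0.2 #1" tags in front of the colon, then glue remaining
    # "label #1" / ") #1" tags onto the label so standard parsers accept them
    text = re.sub(rf":\s*({_NUM})\s*#\s*(\d+)", rf"{_FGTAG}\g<2>:\g<1>", text)
    text = re.sub(r"\s*#\s*(\d+)", rf"{_FGTAG}\g<1>", text)
    return text


def _parse_newick(text: str) -> PhyloTree:
    prepared = _extract_tags(text.strip())
    if prepared.count("(") != prepared.count(")"):
        # report the offset of the first surplus parenthesis
        depth = 0
        offset = len(text.strip())
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    offset = i
                    break
        raise NewickError(f"unbalanced parentheses in Newick near offset {offset}")
    try:
        dtree = dendropy.Tree.get(data=prepared, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
        name: Optional[str] = raw
        foreground = False
        support: Optional[float] = None
        if raw is not None:
            m = re.search(rf"{_FGTAG}(\d+)$", raw)
            if m:
                foreground = int(m.group(1)) >= 1
                name = raw[:m.start()] or None
        if dnode.child_nodes() and name is not None:
            # internal labels that parse as numbers are support values
            try:
                support = float(name)
                name = None
            except ValueError:
                pass
        length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        if length < 0:
            raise NewickError(f"negative branch length {length}")
        return Node(name=name, length=length, foreground=foreground, support=support,
                    children=[convert(c) for c in dnode.child_nodes()])

    return PhyloTree(convert(dtree.seed_node))


def read_tree(path: str | Path) -> PhyloTree:
    """Read a Newick tree (with optional PAML ``#1`` foreground tags)."""
    return PhyloTree.from_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
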