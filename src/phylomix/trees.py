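"""Phylogenetic trees: parsing, writing, rerooting, bipartitions, NNI.

Newick parsing is delegated to dendropy; the in-memory representation is
a plain parent/child node structure tuned for likelihood work. Unrooted
trees are stored rooted at an arbitrary multifurcating node with
``rooted=False``; all reversible-model results must be invariant to that
choice (the pulley principle, asserted in the test suite).
"""
from __future__ import annotations

import io
import itertools
import re
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["Node", "Tree", "read_trees", "parse_newick", "write_tree",
           "write_trees", "random_tree"]

_node_counter = itertools.count()


class Node:
    __slots__ = ("children", "parent", "length", "label", "uid")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length  # length of the edge above this node
        self.label = label
        self.uid = next(_node_counter)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"<Node {self.label or '·'} uid={self.uid}>"


class Tree:
    def __init__(self, root: Node, rooted: bool | None = None):
        self.root = root
        self.rooted = (len(root.children) == 2) if rooted is None else rooted
        self._check()

    def _check(self):
        labels = [n.label for n in self.leaves()]
        if any(l is None for l in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf label(s): {dupes}")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[Node]:
        out, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Edges identified by their child node (root excluded)."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Edges whose child node is internal (callers that need the
        unrooted notion should ``unroot()`` first)."""
        return [n for n in self.edges() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- copying -----------------------------------------------------------
    def copy(self) -> tuple["Tree", dict[int, Node]]:
        """Deep copy; returns the copy and a uid -> new-node map."""
        mapping: dict[int, Node] = {}

        def rec(node: Node) -> Node:
            nn = Node(node.label, node.length)
            mapping[node.uid] = nn
            for c in node.children:
                nn.add(rec(c))
            return nn

        return Tree(rec(self.root), self.rooted), mapping

    # -- serialization -----------------------------------------------------
    def to_newick(self, precision: int = 10, lengths: bool = True) -> str:
        def fmt(x: float) -> str:
            s = f"{x:.{precision}f}".rstrip("0").rstrip(".")
            return s if s else "0"

        def quote(label: str) -> str:
            if re.search(r"[\s()\[\]{}:;,']", label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def rec(node: Node) -> str:
            if node.is_leaf:
                core = quote(node.label)
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    core += quote(node.label)
            if lengths and node.parent is not None:
                core += f":{fmt(node.length)}"
            return core

        return rec(self.root) + ";"

    # -- restructuring -----------------------------------------------------
    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a trifurcation (in place)."""
        root = self.root
        if len(root.children) == 2:
            a, b = root.children
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                self.rooted = False
                return self  # 2-leaf tree: nothing to collapse
            total = a.length + b.length
            keep.parent = None
            keep.length = 0.0
            keep.add(move)
            move.length = total
            self.root = keep
        self.rooted = False
        return self

    def reroot_on_edge(self, edge_child_uid: int, dist_from_child: float | None = None) -> "Tree":
        """Return a new tree rooted on the edge above the given node.

        The edge of length L is split into ``dist_from_child`` (below the
        new root, toward the child) and ``L - dist_from_child`` (above).
        Defaults to the midpoint. The original tree is unchanged.
        """
        copy, mapping = self.copy()
        child = mapping[edge_child_uid]
        if child.parent is None:
            raise ValueError("cannot reroot on the root node")
        L = child.length
        d = L / 2.0 if dist_from_child is None else float(dist_from_child)
        if not (0.0 <= d <= L + 1e-12):
            raise ValueError("split distance outside edge length")

        old_parent = child.parent
        old_parent.children.remove(child)
        new_root = Node()
        new_root.add(child)
        child.length = d

        # reverse the path from old_parent up to the old root
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        lengths_up = [n.length for n in path]  # length of edge above each path node

        new_root.add(old_parent)
        old_parent.length = L - d
        for i in range(len(path) - 1):
            upper = path[i + 1]
            lower = path[i]
            upper.children.remove(lower)
            lower.add(upper)
            upper.length = lengths_up[i]
        # suppress the old root if it became degree-2 (was a bifurcating root)
        old_root = path[-1]
        if len(old_root.children) == 1 and old_root.parent is not None:
            only = old_root.children[0]
            gp = old_root.parent
            gp.children[gp.children.index(old_root)] = only
            only.parent = gp
            only.length = only.length + old_root.length
        t = Tree(new_root, rooted=True)
        return t

    # -- bipartitions ------------------------------------------------------
    def clades(self) -> dict[int, frozenset]:
        """uid of edge-child -> frozenset of leaf labels below it."""
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n.uid] = frozenset([n.label])
            else:
                s = frozenset().union(*(below[c.uid] for c in n.children))
                below[n.uid] = s
        below.pop(self.root.uid)
        return below

    def splits(self, nontrivial_only: bool = True) -> set[frozenset]:
        """Unrooted splits as frozensets of {side, complement} pairs."""
        all_leaves = frozenset(self.leaf_names())
        out = set()
        for side in self.clades().values():
            other = all_leaves - side
            if nontrivial_only and (len(side) < 2 or len(other) < 2):
                continue
            out.add(frozenset([side, other]))
        return out

    def same_unrooted_topology(self, other: "Tree") -> bool:
        if set(self.leaf_names()) != set(other.leaf_names()):
            return False
        return self.splits() == other.splits()

    # -- NNI ---------------------------------------------------------------
    def nni_edges(self) -> list[int]:
        """uids of child nodes whose parent edge admits NNI rearrangement."""
        out = []
        for n in self.edges():
            if n.is_leaf:
                continue
            u = n.parent
            if u is self.root and len(self.root.children) < 3 and self.rooted:
                continue  # rooted root edge: handled after unrooting
            out.append(n.uid)
        return out

    def nni_neighbors(self, edge_child_uid: int) -> list["Tree"]:
        """The two NNI rearrangements of an internal edge (new trees)."""
        out = []
        for which in (0, 1):
            copy, mapping = self.copy()
            v = mapping[edge_child_uid]
            u = v.parent
            sibs = [c for c in u.children if c is not v]
            if not sibs or len(v.children) < 2:
                raise ValueError("edge does not admit NNI")
            c = sibs[0]
            a = v.children[which]
            # swap subtree a (below v) with subtree c (sibling of v)
            v.children[v.children.index(a)] = c
            u.children[u.children.index(c)] = a
            a.parent, c.parent = u, v
            out.append(Tree(copy.root, copy.rooted))
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            n = Node(label, dnode.edge.length or 0.0)
        else:
            n = Node(dnode.label, dnode.edge.length or 0.0)
            for c in dnode.child_nodes():
                n.add(rec(c))
        return n

    root = rec(dtree.seed_node)
    return Tree(root)


def parse_newick(text: str) -> Tree:
    trees = read_trees(io.StringIO(text))
    if len(trees) != 1:
        raise ValueError(f"expected one tree, found {len(trees)}")
    return trees[0]


def read_trees(source) -> list[Tree]:
    """Read all Newick statements from a path or file-like object."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    if ";" not in text:
        raise ValueError("no ';'-terminated Newick statement found")
    try:
        tlist = dendropy.TreeList.get(data=text, schema="newick",
                                      preserve_underscores=True,
                                      suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises its own hierarchy
        raise ValueError(f"Newick parse error: {e}") from e
    if len(tlist) == 0:
        raise ValueError("no trees parsed")
    return [_from_dendropy(t) for t in tlist]


def write_tree(tree: Tree, path, precision: int = 10) -> None:
    Path(path).write_text(tree.to_newick(precision=precision) + "\n")


def write_trees(trees, path, precision: int = 10) -> None:
    Path(path).write_text(
        "".join(t.to_newick(precision=precision) + "\n" for t in trees))


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------

def random_tree(taxa, rng: np.random.Generator,
                branch_lengths=(0.05, 0.3), rooted: bool = False) -> Tree:
    """Random topology by sequential addition; lengths ~ U(lo, hi)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    lo, hi = branch_lengths
    root = Node()
    for t in taxa[:3]:
        root.add(Node(t, 1.0))
    tree = Tree(root, rooted=False)
    for t in taxa[3:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(length=1.0)
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(t, 1.0))
        tree = Tree(root, rooted=False)
    for e in tree.edges():
        e.length = float(rng.uniform(lo, hi))
    if rooted:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        tree = tree.reroot_on_edge(target.uid)
    return tree
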