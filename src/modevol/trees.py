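"""Rooted/unrooted phylogenetic trees with bootstrap supports.

The package's tree container is a small mutable node class. Newick parsing is
delegated to dendropy; integer-valued internal-node labels are interpreted as
bootstrap supports (0-100), the field convention for support-annotated trees.
Unrooted trees are represented in the usual way as a tree whose root has three
children; a root with two children denotes a rooted tree.
"""

from __future__ import annotations

import hashlib
from typing import Callable, Iterator, Optional

import dendropy


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class Node:
    """A node of a phylogenetic tree.

    Attributes
    ----------
    name : str or None
        Leaf label, or an internal-node name that is not an integer support.
    length : float or None
        Length of the branch above this node.
    support : int or None
        Bootstrap support (0-100) of the branch above this node.
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        if children:
            for c in children:
                self.add_child(c)

    # -- construction -------------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def copy(self) -> "Node":
        n = Node(self.name, self.length, self.support)
        for c in self.children:
            n.add_child(c.copy())
        return n

    # -- queries -------------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or to_newick(self)[:40]}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _from_dendropy(dn) -> Node:
    if dn.is_leaf():
        name = dn.taxon.label if dn.taxon is not None else dn.label
        node = Node(name=name, length=dn.edge.length)
    else:
        node = Node(length=dn.edge.length)
        label = dn.label
        if label is not None:
            try:
                node.support = int(label)
            except ValueError:
                try:
                    f = float(label)
                    if f.is_integer():
                        node.support = int(f)
                    else:
                        node.name = label
                except ValueError:
                    node.name = label
        for c in dn.child_nodes():
            node.add_child(_from_dendropy(c))
    return node


def parse_newick(text: str) -> Node:
    """Parse one Newick string into a :class:`Node` tree.

    Integer internal-node labels become branch supports; other labels are kept
    as internal-node names. Malformed input raises :class:`NewickError` with
    dendropy's diagnostic (which includes the offending position).
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed Newick: {exc}") from exc
    if dt.seed_node is None or (dt.seed_node.is_leaf() and dt.seed_node.taxon is None):
        raise NewickError("empty Newick string")
    return _from_dendropy(dt.seed_node)


def read_newick(path) -> Node:
    with open(path) as fh:
        return parse_newick(fh.read())


def _newick_parts(node: Node) -> str:
    if node.is_leaf:
        s = node.name or ""
    else:
        inner = ",".join(_newick_parts(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = str(int(node.support))
        elif node.name:
            label = node.name
        s = f"({inner}){label}"
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def to_newick(root: Node) -> str:
    return _newick_parts(root) + ";"


def write_newick(root: Node, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(root) + "\n")


def canonical_newick(root: Node) -> str:
    """Topology-only Newick with children sorted; a deterministic tree key."""

    def rec(n: Node) -> str:
        if n.is_leaf:
            return n.name or ""
        return "(" + ",".join(sorted(rec(c) for c in n.children)) + ")"

    return rec(root) + ";"


# ---------------------------------------------------------------------------
# Topology utilities
# ---------------------------------------------------------------------------


def parent_map(root: Node) -> dict[Node, Optional[Node]]:
    return {n: n.parent for n in root.postorder()}


def depth_map(root: Node) -> dict[Node, int]:
    depths = {root: 0}
    for n in root.preorder():
        for c in n.children:
            depths[c] = depths[n] + 1
    return depths


def mrca(depths: dict[Node, int], a: Node, b: Node) -> Node:
    """Lowest common ancestor via parent pointers and precomputed depths."""
    while a is not b:
        if depths[a] < depths[b]:
            b = b.parent
        elif depths[a] > depths[b]:
            a = a.parent
        else:
            a, b = a.parent, b.parent
    return a


def bipartitions(root: Node, nontrivial: bool = True) -> set:
    """Unrooted bipartitions of the leaf set, one per internal edge.

    Each bipartition is a frozenset of the two leaf-name frozensets, so the
    representation is rooting-invariant.
    """
    all_leaves = frozenset(root.leaf_names())
    out = set()
    for n in root.postorder():
        if n is root or n.is_leaf:
            continue
        side = frozenset(n.leaf_names())
        other = all_leaves - side
        if nontrivial and (len(side) < 2 or len(other) < 2):
            continue
        out.add(frozenset((side, other)))
    return out


def rf_distance(t1: Node, t2: Node) -> int:
    """Robinson-Foulds distance: symmetric difference of bipartition sets."""
    if frozenset(t1.leaf_names()) != frozenset(t2.leaf_names()):
        raise ValueError("trees are over different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def is_binary_rooted(root: Node) -> bool:
    return all(len(n.children) in (0, 2) for n in root.postorder())


def auto_label_internal(root: Node, prefix: str = "N") -> Node:
    """Label unnamed internal nodes by a hash of their sorted leaf set.

    Gives every species-tree branch a stable, content-derived identity for
    per-branch reports.
    """
    for n in root.postorder():
        if not n.is_leaf and not n.name:
            key = ",".join(sorted(n.leaf_names()))
            n.name = prefix + hashlib.md5(key.encode()).hexdigest()[:8]
    return root


# ---------------------------------------------------------------------------
# Rootings of an unrooted tree
# ---------------------------------------------------------------------------


def _unrooted_edges(root: Node):
    """Adjacency view of the tree as an unrooted graph.

    A two-child root is suppressed (its two edges become one), so rooted and
    unrooted representations of the same topology yield the same edge set.
    """
    adj: dict[int, list] = {}
    nodes: dict[int, Node] = {}

    def reg(n: Node):
        nodes[id(n)] = n
        adj.setdefault(id(n), [])

    for n in root.postorder():
        reg(n)
    edges = []
    root_children = root.children
    skip = set()
    if len(root_children) == 2:
        a, b = root_children
        la = (a.length or 0.0) + (b.length or 0.0)
        sup = a.support if a.support is not None else b.support
        edges.append((id(a), id(b), la, sup))
        skip = {id(a), id(b)}
        del adj[id(root)], nodes[id(root)]
    for n in root.postorder():
        if n is root:
            continue
        if id(n) in skip:
            continue
        edges.append((id(n.parent), id(n), n.length, n.support))
    for u, v, ln, sup in edges:
        adj[u].append((v, ln, sup))
        adj[v].append((u, ln, sup))
    return nodes, adj, edges


def _build_rooted(nodes, adj, nid: int, came_from: int, length, support) -> Node:
    orig = nodes[nid]
    if all(v == came_from for v, _, _ in adj[nid]):
        return Node(orig.name, length, support)
    n = Node(orig.name if not orig.children else None, length, support)
    for v, ln, sup in adj[nid]:
        if v == came_from:
            continue
        n.add_child(_build_rooted(nodes, adj, v, nid, ln, sup))
    return n


def _root_at(nodes, adj, u, v, ln, sup, frac: float = 0.5) -> Node:
    """Root on the edge (u, v), placing the root ``frac`` of the way from u."""
    lu = lv = None
    if ln is not None:
        lu, lv = ln * frac, ln * (1.0 - frac)
    root = Node()
    root.add_child(_build_rooted(nodes, adj, u, v, lu, sup))
    root.add_child(_build_rooted(nodes, adj, v, u, lv, sup))
    return root


def enumerate_rootings(tree: Node) -> list[Node]:
    """All rooted versions of an unrooted tree, one per edge (2n-3 of them).

    The root is placed at the midpoint of each edge; edge supports travel with
    their bipartition.
    """
    nodes, adj, edges = _unrooted_edges(tree)
    return [_root_at(nodes, adj, u, v, ln, sup) for u, v, ln, sup in edges]


def midpoint_root(tree: Node) -> Node:
    """Root an unrooted tree at the midpoint of its longest leaf-leaf path.

    The standard rooting for distance trees without an outgroup; edge supports
    travel with their bipartitions. A tree that is already rooted (two-child
    root) is returned unchanged.
    """
    if len(tree.children) == 2:
        return tree
    nodes, adj, edges = _unrooted_edges(tree)
    leaf_ids = [nid for nid, n in nodes.items() if not n.children]
    if len(leaf_ids) < 2:
        return tree

    def distances(src: int):
        dist = {src: 0.0}
        prev = {src: None}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, ln, _ in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + (ln or 0.0)
                    prev[y] = x
                    stack.append(y)
        return dist, prev

    # double sweep: farthest leaf from an arbitrary leaf, then farthest from it
    d0, _ = distances(leaf_ids[0])
    a = max(leaf_ids, key=lambda l: d0[l])
    da, prev = distances(a)
    b = max(leaf_ids, key=lambda l: da[l])
    if a == b or da[b] == 0.0:
        # degenerate (all-zero-length) tree: root on the first edge
        u, v, ln, sup = edges[0]
        return _root_at(nodes, adj, u, v, ln, sup)
    # walk back from b to a, find the edge containing the midpoint
    half = da[b] / 2.0
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    acc = 0.0
    for x, y in zip(path, path[1:]):  # from b towards a; da decreases
        ln, sup = next((l, s) for z, l, s in adj[x] if z == y)
        step = ln or 0.0
        if acc + step >= da[b] - half - 1e-12 or (x, y) == (path[-2], path[-1]):
            frac_from_x = min(max((da[b] - half - acc) / step if step else 0.5, 0.0), 1.0)
            return _root_at(nodes, adj, x, y, ln, sup, frac=frac_from_x)
        acc += step
    raise AssertionError("midpoint edge not found")  # pragma: no cover
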