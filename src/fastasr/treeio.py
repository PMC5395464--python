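"""Rooted phylogenies: parsing, validation, traversal orders, rerooting.

Trees are stored in a flat array representation keyed by integer node ids:
tips are numbered ``1..N`` in Newick left-to-right order, the root is
``N + 1``, and the remaining internal nodes follow in preorder discovery
order.  This matches the numbering convention of common phylogenetic R
tooling, so node-keyed output tables are directly comparable.

Only a restricted Newick dialect is accepted: unquoted labels, optional
internal-node labels, branch lengths on every non-root edge, polytomies
allowed.  Quoted labels and ``[...]`` comment/NHX blocks are rejected.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "EdgeOrders",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "edge_orders",
    "reroot",
]


class NewickParseError(ValueError):
    """Raised when the Newick text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural requirement."""


@dataclass(frozen=True)
class Tree:
    """A rooted phylogeny with branch lengths.

    Attributes
    ----------
    n_tips
        Number of terminal taxa ``N``.
    parent
        ``parent[i]`` is the parent id of node ``i`` (0 for the root);
        index 0 is unused.
    length
        ``length[i]`` is the length of the edge above node ``i`` in time
        units; the root carries 0 (the tree has no root edge).
    children
        ``children[i]`` is a tuple of child ids of node ``i``.
    labels
        ``labels[i]`` is the node label (tip labels are mandatory and
        unique; internal labels optional, ``None`` when absent).
    """

    n_tips: int
    parent: np.ndarray
    length: np.ndarray
    children: tuple
    labels: tuple

    @property
    def root(self) -> int:
        return self.n_tips + 1

    @property
    def n_nodes(self) -> int:
        return len(self.parent) - 1

    def is_tip(self, node: int) -> bool:
        return 1 <= node <= self.n_tips

    @property
    def tip_labels(self) -> tuple:
        return self.labels[1 : self.n_tips + 1]

    def tip_index(self) -> dict:
        """Map tip label -> tip id (1-based)."""
        return {lab: i for i, lab in enumerate(self.tip_labels, start=1)}

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths, indexed by node id (index 0 unused)."""
        depth = np.zeros(self.n_nodes + 1)
        for v in preorder_nodes(self):
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.length[v]
        return depth

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tree(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


@dataclass(frozen=True)
class EdgeOrders:
    """Edge traversal orders; an edge is identified by its child node id.

    ``postorder`` lists every non-root edge with children before parents;
    ``preorder`` is its exact reverse.  ``children`` is the per-node child
    list of the underlying tree.
    """

    postorder: np.ndarray
    preorder: np.ndarray
    children: tuple


def _build_from_structure(root_key, children_of, lengths, labels) -> Tree:
    """Renumber an arbitrary-keyed rooted structure into Tree convention.

    ``children_of[k]`` lists child keys, ``lengths[k]`` the edge length
    above ``k`` (ignored for the root), ``labels[k]`` an optional label.
    """
    # Preorder walk to fix discovery order (iterative; trees can be deep).
    order = []
    stack = [root_key]
    while stack:
        k = stack.pop()
        order.append(k)
        stack.extend(reversed(children_of.get(k, ())))
    tips = [k for k in order if not children_of.get(k)]
    internals = [k for k in order if children_of.get(k)]
    if internals and internals[0] != root_key:
        raise TreeValidationError("root must be first in preorder")
    n_tips = len(tips)
    ids = {k: i for i, k in enumerate(tips, start=1)}
    ids.update({k: n_tips + 1 + j for j, k in enumerate(internals)})
    n_nodes = len(order)
    parent = np.zeros(n_nodes + 1, dtype=np.int64)
    length = np.zeros(n_nodes + 1)
    children = [()] * (n_nodes + 1)
    labs = [None] * (n_nodes + 1)
    for k in order:
        i = ids[k]
        labs[i] = labels.get(k)
        children[i] = tuple(ids[c] for c in children_of.get(k, ()))
        for c in children_of.get(k, ()):
            parent[ids[c]] = i
            length[ids[c]] = lengths[c]
    return Tree(
        n_tips=n_tips,
        parent=parent,
        length=length,
        children=tuple(children),
        labels=tuple(labs),
    )


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick tree with branch lengths.

    Tips are numbered ``1..N`` left to right, the root is ``N + 1``, and
    internal nodes follow in preorder discovery order.  A root edge
    length, if present, is ignored with a warning (the model places no
    edge above the root).

    Raises
    ------
    NewickParseError
        On malformed input, with the offending character position.
    TreeValidationError
        On a missing branch length, a non-positive terminal branch
        length, or duplicate/empty tip labels.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    for pos, ch in enumerate(text):
        if ch in "'\"":
            raise NewickParseError(
                f"quoted labels are not supported (character {pos})"
            )
        if ch in "[]":
            raise NewickParseError(
                f"comment/NHX blocks are not supported (character {pos})"
            )
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' (character {pos})"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(' (character {text.rindex('(')})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None

    seed = dtree.seed_node
    if seed.edge.length is not None and seed.edge.length != 0:
        warnings.warn(
            "root edge length in Newick input is ignored (the root has "
            "no edge)",
            stacklevel=2,
        )
    children_of, lengths, labels = {}, {}, {}
    for nd in dtree.preorder_node_iter():
        children_of[id(nd)] = [id(c) for c in nd.child_nodes()]
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        labels[id(nd)] = lab
        if nd is not seed:
            if nd.edge.length is None:
                where = lab or "an internal node"
                raise TreeValidationError(
                    f"missing branch length on the edge above {where!r}"
                )
            lengths[id(nd)] = float(nd.edge.length)
            if not nd.child_nodes() and lengths[id(nd)] <= 0:
                raise TreeValidationError(
                    f"tip {lab!r} has a non-positive branch length "
                    f"({lengths[id(nd)]}); terminal edges must be > 0"
                )
            if nd.child_nodes() and lengths[id(nd)] < 0:
                raise TreeValidationError(
                    f"negative internal branch length above {lab!r}"
                )
    tree = _build_from_structure(id(seed), children_of, lengths, labels)
    tips = tree.tip_labels
    if any(lab is None or lab == "" for lab in tips):
        raise TreeValidationError("every tip must carry a non-empty label")
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise TreeValidationError(f"duplicate tip labels: {dupes}")
    if tree.n_tips < 1:
        raise TreeValidationError("tree has no tips")
    return tree


def write_newick(tree: Tree, internal_labels: bool = True) -> str:
    """Serialize a Tree back to Newick (branch lengths round-trip)."""
    out = io.StringIO()

    def fmt(x: float) -> str:
        return repr(float(x))

    # Iterative write to survive deep trees.
    def walk(v: int) -> str:
        if tree.is_tip(v):
            return f"{tree.labels[v]}:{fmt(tree.length[v])}"
        inner = ",".join(walk(c) for c in tree.children[v])
        lab = tree.labels[v] if (internal_labels and tree.labels[v]) else ""
        if v == tree.root:
            return f"({inner}){lab}"
        return f"({inner}){lab}:{fmt(tree.length[v])}"

    out.write(walk(tree.root))
    out.write(";")
    return out.getvalue()


def preorder_nodes(tree: Tree) -> list:
    """All node ids, parents before children, root first."""
    order = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(tree.children[v]))
    return order


def edge_orders(tree: Tree) -> EdgeOrders:
    """Postorder and preorder edge lists (edges keyed by child node id)."""
    pre = [v for v in preorder_nodes(tree) if v != tree.root]
    post = pre[::-1]
    return EdgeOrders(
        postorder=np.asarray(post, dtype=np.int64),
        preorder=np.asarray(pre, dtype=np.int64),
        children=tree.children,
    )


def reroot(tree: Tree, node: int) -> Tree:
    """Reroot at an internal node, preserving all tip-to-tip path lengths.

    The old root is kept as a (possibly degree-two) internal node, which
    leaves every patristic distance unchanged.  Used by the dense
    reference implementations; the two-pass algorithm never reroots.
    """
    if tree.is_tip(node):
        raise TreeValidationError("rerooting at a tip is not supported")
    if not (1 <= node <= tree.n_nodes):
        raise TreeValidationError(f"no such node: {node}")
    # Undirected adjacency with edge lengths.
    adj = {v: [] for v in range(1, tree.n_nodes + 1)}
    for v in range(1, tree.n_nodes + 1):
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        adj[v].append((p, float(tree.length[v])))
        adj[p].append((v, float(tree.length[v])))
    children_of, lengths, labels = {}, {}, {}
    labels = {v: tree.labels[v] for v in range(1, tree.n_nodes + 1)}
    seen = {node}
    stack = [node]
    while stack:
        v = stack.pop()
        kids = []
        for u, t in adj[v]:
            if u not in seen:
                seen.add(u)
                kids.append(u)
                lengths[u] = t
                stack.append(u)
        children_of[v] = kids
    return _build_from_structure(node, children_of, lengths, labels)


def patristic_distances(tree: Tree) -> np.ndarray:
    """N x N matrix of tip-to-tip path lengths, tips in label-sorted order."""
    depth = tree.node_depths()
    labs = sorted(tree.tip_labels)
    idx = tree.tip_index()
    mrca_depth = _mrca_depths(tree)
    n = tree.n_tips
    D = np.zeros((n, n))
    for i, la in enumerate(labs):
        for j, lb in enumerate(labs):
            a, b = idx[la], idx[lb]
            D[i, j] = depth[a] + depth[b] - 2 * mrca_depth[a - 1, b - 1]
    return D


def _mrca_depths(tree: Tree) -> np.ndarray:
    """N x N matrix of root-to-MRCA depths for tip pairs (tip-id order)."""
    depth = tree.node_depths()
    n = tree.n_tips
    M = np.zeros((n, n))
    tipsets = {}
    for v in preorder_nodes(tree)[::-1]:
        if tree.is_tip(v):
            tipsets[v] = np.array([v - 1])
            M[v - 1, v - 1] = depth[v]
        else:
            kids = [tipsets[c] for c in tree.children[v]]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    M[np.ix_(kids[i], kids[j])] = depth[v]
                    M[np.ix_(kids[j], kids[i])] = depth[v]
            tipsets[v] = np.concatenate(kids)
    return M
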