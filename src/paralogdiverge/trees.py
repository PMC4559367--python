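"""Neighbor-joining tree construction and paralog-clade branch-length contrast.

Trees are unrooted, represented with a trifurcating root node.  NJ is the
plain Saitou–Nei algorithm (join the pair minimising the Q-criterion);
BioNJ-style variance weighting is deliberately not used — on the
near-additive matrices produced at these divergences the two coincide,
and plain NJ is far easier to verify against additivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch length to parent; None = absent
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted representation of an (optionally unrooted) tree.

    An unrooted tree carries a trifurcating root.  Leaf labels are the
    sequence ids and must be unique.
    """

    root: Node

    def __post_init__(self):
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise TreeError("leaf labels must be unique")

    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def total_length(self) -> float:
        total = 0.0

        def walk(n: Node):
            nonlocal total
            if n.length is not None:
                total += n.length
            for c in n.children:
                walk(c)

        walk(self.root)
        return total

    # -- newick ---------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                body = n.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")" + (n.name or "")
            if n.length is not None:
                body += f":{n.length:.10g}"
            return body

        return fmt(self.root) + ";"

    # -- adjacency view for path computations ---------------------------
    def adjacency(self) -> tuple[dict[int, list[tuple[int, float]]], dict[int, Node]]:
        """Undirected edge list keyed by node ids (missing lengths as 0)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        nodes: dict[int, Node] = {}

        def walk(n: Node):
            nodes[id(n)] = n
            adj.setdefault(id(n), [])
            for c in n.children:
                w = c.length if c.length is not None else 0.0
                adj.setdefault(id(c), [])
                adj[id(n)].append((id(c), w))
                adj[id(c)].append((id(n), w))
                walk(c)

        walk(self.root)
        return adj, nodes


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick tree (path or literal string)."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        n = Node(
            name=dnode.taxon.label if dnode.taxon else dnode.label,
            length=dnode.edge.length,
        )
        n.children = [convert(c) for c in dnode.child_nodes()]
        return n

    root = convert(dtree.seed_node)
    return PhyloTree(root=root)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair (i, j) minimising
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), with the standard
    branch-length formulas.  Negative branch lengths are clamped to zero
    and the clamped deficit logged.  The last three lineages join at a
    trifurcating root (unrooted representation).
    """
    if len(dm.ids) < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if dm.saturated.any():
        raise TreeError("distance matrix contains saturated entries")
    d = dm.values.astype(float).copy()
    nodes = [Node(name=i) for i in dm.ids]
    active = list(range(len(nodes)))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (n - 2))
        lj = dij - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent = Node(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.vstack([d, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        d = np.hstack([d, new_col[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final trifurcation
    i, j, k = active
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    if deficit > 0:
        logger.info("clamped negative NJ branch lengths; total deficit %.3g", deficit)
    return PhyloTree(root=root)


def tree_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Path length between two leaves."""
    adj, nodes = tree.adjacency()
    start = next(k for k, n in nodes.items() if n.is_leaf and n.name == a)
    goal = next(k for k, n in nodes.items() if n.is_leaf and n.name == b)
    dist = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        if u == goal:
            return dist[u]
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    raise TreeError(f"no path between {a} and {b}")


# ---------------------------------------------------------------------------
# clade contrast

@dataclass(frozen=True)
class GroupBranchStats:
    group: str
    total_length: float
    mean_tip_depth: float
    n_leaves: int


@dataclass(frozen=True)
class CladeRateContrast:
    """Branch-length contrast between two leaf groups on one tree.

    ``ratio`` is mean tip depth of group a over group b, depths measured
    from each group's basal attachment node (stem edge excluded).
    ``monophyletic`` records whether each group forms a clade on the
    unrooted tree; violations are reported, not fatal.
    """

    a: GroupBranchStats
    b: GroupBranchStats
    ratio: float | None
    monophyletic: bool


def _leafsets_below(tree: PhyloTree):
    """For each node, the set of leaf names in its rooted subtree."""
    below: dict[int, frozenset[str]] = {}

    def walk(n: Node) -> frozenset[str]:
        if n.is_leaf:
            s = frozenset([n.name])
        else:
            s = frozenset().union(*(walk(c) for c in n.children))
        below[id(n)] = s
        return s

    walk(tree.root)
    return below


def clade_contrast(tree: PhyloTree, groups: Mapping[str, str]) -> CladeRateContrast:
    """Contrast the branch lengths of two paralog groups sharing one tree.

    Per group: the total branch length of the minimal spanning subtree of
    its leaves, and the mean distance from the group's basal node to its
    tips.  The ratio of the two mean depths quantifies the rate
    asymmetry a tree figure shows visually.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise TreeError(f"clade_contrast needs exactly 2 groups, got {labels}")
    ga, gb = labels
    set_a = {l for l, g in groups.items() if g == ga}
    set_b = {l for l, g in groups.items() if g == gb}
    if len(set_a) < 2 or len(set_b) < 2:
        raise TreeError("each group needs at least 2 leaves")
    all_leaves = set(tree.leaf_names())
    if not (set_a | set_b) <= all_leaves:
        raise TreeError("group map references leaves absent from the tree")

    below = _leafsets_below(tree)
    adj, nodes = tree.adjacency()
    universe = set_a | set_b

    def span_length(s: set[str]) -> float:
        """Sum of edges on paths between the group's leaves."""
        total = 0.0
        for nid, n in nodes.items():
            if n is tree.root or n.length is None:
                continue
            inside = below[nid] & s
            if 0 < len(inside) < len(s):
                total += n.length
        return total

    def basal_node(s: set[str], other: set[str]) -> int | None:
        """Node whose subtree leafset (restricted to grouped leaves) is exactly s."""
        for nid in below:
            rel = below[nid] & universe
            if rel == s:
                return nid
        # group may span the root: the complement subtree is the other group
        for nid, n in nodes.items():
            if n is not tree.root and (below[nid] & universe) == other:
                # s's basal point is the parent end of that edge: find neighbour
                for v, _ in adj[nid]:
                    if below.get(v, frozenset()) >= below[nid] or v == id(tree.root):
                        return v
        return None

    na, nb = basal_node(set_a, set_b), basal_node(set_b, set_a)
    mono = na is not None and nb is not None
    if not mono:
        logger.warning("groups are not monophyletic on this tree; using MRCA fallback")

    def mrca(s: set[str]) -> int:
        # deepest node whose subtree covers s
        best, best_size = id(tree.root), len(below[id(tree.root)])
        for nid, leafset in below.items():
            if s <= leafset and len(leafset) < best_size:
                best, best_size = nid, len(leafset)
        return best

    def mean_depth(anchor: int, s: set[str]) -> float:
        dist = {anchor: 0.0}
        stack = [anchor]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        vals = [dist[k] for k, n in nodes.items() if n.is_leaf and n.name in s]
        return float(np.mean(vals))

    anchor_a = na if na is not None else mrca(set_a)
    anchor_b = nb if nb is not None else mrca(set_b)
    stats_a = GroupBranchStats(ga, span_length(set_a), mean_depth(anchor_a, set_a), len(set_a))
    stats_b = GroupBranchStats(gb, span_length(set_b), mean_depth(anchor_b, set_b), len(set_b))
    if stats_a.mean_tip_depth == 0 or stats_b.mean_tip_depth == 0:
        ratio = None
    else:
        ratio = stats_a.mean_tip_depth / stats_b.mean_tip_depth
    return CladeRateContrast(a=stats_a, b=stats_b, ratio=ratio, monophyletic=mono)
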