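"""Distance-based tree building (UPGMA and neighbor joining) with Newick output.

Both algorithms are agglomerative and fully deterministic here: whenever two
candidate pairs tie on the merge criterion, the pair whose sorted label pair
is lexicographically smallest is merged first (labels of internal clusters
are the lexicographically smallest leaf label they contain).  UPGMA produces
a rooted ultrametric tree (merge height = half the cluster distance,
cluster-size-weighted average linkage); neighbor joining follows the
Saitou-Nei update and yields an unrooted tree written with a trifurcating
root.  Negative neighbor-joining branch length estimates are clamped to
zero, the usual convention for distance matrices that are not perfectly
additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .similarity import DistanceMatrix

__all__ = ["Clade", "Tree", "build_tree", "upgma", "neighbor_joining", "to_newick"]


@dataclass
class Clade:
    """A node: leaf if it has a name and no children; branch_length is the
    length of the edge above it (None for the root)."""

    name: Optional[str] = None
    branch_length: Optional[float] = None
    children: list["Clade"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Clade
    rooted: bool = True

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(c: Clade) -> None:
            if c.is_leaf():
                out.append(c.name or "")
            for ch in c.children:
                walk(ch)

        walk(self.root)
        return out

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (ultrametric for UPGMA trees)."""
        out: dict[str, float] = {}

        def walk(c: Clade, depth: float) -> None:
            if c.is_leaf():
                out[c.name or ""] = depth
            for ch in c.children:
                walk(ch, depth + (ch.branch_length or 0.0))

        walk(self.root, 0.0)
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        out: list[frozenset[str]] = []

        def walk(c: Clade) -> frozenset[str]:
            if c.is_leaf():
                return frozenset([c.name or ""])
            leaves = frozenset().union(*(walk(ch) for ch in c.children))
            out.append(leaves)
            return leaves

        walk(self.root)
        return out


def build_tree(m: DistanceMatrix, method: str = "upgma") -> Tree:
    """Build a tree from a distance matrix by ``upgma`` or ``nj``."""
    if method == "upgma":
        return upgma(m)
    if method in ("nj", "neighbor-joining"):
        return neighbor_joining(m)
    raise ValueError(f"unknown tree method {method!r}")


def upgma(m: DistanceMatrix) -> Tree:
    """Average-linkage agglomeration; heights are half the cluster distance."""
    if len(m.labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    # cluster state keyed by representative label (smallest member leaf)
    nodes = {lab: Clade(name=lab) for lab in m.labels}
    size = {lab: 1 for lab in m.labels}
    height = {lab: 0.0 for lab in m.labels}
    dist = {
        _key(a, b): m[a, b]
        for i, a in enumerate(m.labels)
        for b in m.labels[i + 1 :]
    }
    active = set(m.labels)
    while len(active) > 1:
        a, b = min(
            (_key(x, y) for i, x in enumerate(sorted(active)) for y in sorted(active)[i + 1 :]),
            key=lambda k: (dist[k], k),
        )
        d = dist[_key(a, b)]
        h = d / 2.0
        na, nb = nodes[a], nodes[b]
        na.branch_length = h - height[a]
        nb.branch_length = h - height[b]
        merged = Clade(children=[na, nb])
        rep = min(a, b)
        for c in active - {a, b}:
            dist[_key(rep, c)] = (
                size[a] * dist[_key(a, c)] + size[b] * dist[_key(b, c)]
            ) / (size[a] + size[b])
        active -= {a, b}
        active.add(rep)
        nodes[rep] = merged
        size[rep] = size[a] + size[b]
        height[rep] = h
    return Tree(root=nodes[active.pop()], rooted=True)


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree."""
    if len(m.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes = {lab: Clade(name=lab) for lab in m.labels}
    dist = {
        _key(a, b): m[a, b]
        for i, a in enumerate(m.labels)
        for b in m.labels[i + 1 :]
    }
    active = sorted(m.labels)
    while len(active) > 3:
        n = len(active)
        r = {x: sum(dist[_key(x, y)] for y in active if y != x) for x in active}
        pair = min(
            (_key(x, y) for i, x in enumerate(active) for y in active[i + 1 :]),
            key=lambda k: ((n - 2) * dist[k] - r[k[0]] - r[k[1]], k),
        )
        a, b = pair
        d_ab = dist[pair]
        la = d_ab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d_ab - la
        na, nb = nodes[a], nodes[b]
        na.branch_length = max(la, 0.0)
        nb.branch_length = max(lb, 0.0)
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dist[_key(rep, c)] = max(
                (dist[_key(a, c)] + dist[_key(b, c)] - d_ab) / 2.0, 0.0
            )
        active = sorted(set(active) - {a, b} | {rep})
        nodes[rep] = Clade(children=[na, nb])
    a, b, c = active
    d_ab, d_ac, d_bc = dist[_key(a, b)], dist[_key(a, c)], dist[_key(b, c)]
    for lab, ln in (
        (a, (d_ab + d_ac - d_bc) / 2.0),
        (b, (d_ab + d_bc - d_ac) / 2.0),
        (c, (d_ac + d_bc - d_ab) / 2.0),
    ):
        nodes[lab].branch_length = max(ln, 0.0)
    root = Clade(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, rooted=False)


def to_newick(t: Tree) -> str:
    """Standard Newick with 6-decimal branch lengths, semicolon-terminated.

    Leaf names needing protection (whitespace or Newick punctuation) are
    single-quoted, internal quotes doubled.
    """

    def fmt_name(name: Optional[str]) -> str:
        if not name:
            return ""
        if any(ch in name for ch in " \t(),:;[]'"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def walk(c: Clade) -> str:
        if c.is_leaf():
            s = fmt_name(c.name)
        else:
            s = "(" + ",".join(walk(ch) for ch in c.children) + ")" + fmt_name(c.name)
        if c.branch_length is not None:
            s += f":{c.branch_length:.6f}"
        return s

    return walk(t.root) + ";"


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)
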