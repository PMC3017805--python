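"""Neighbor-joining phylogeny of concatenated ortholog alignments.

Distances are Jukes–Cantor, computed over columns where both taxa are
ungapped.  The NJ implementation is Saitou–Nei with deterministic
tie-breaking by taxon order; negative branch lengths are clamped to zero
with the deficit moved to the sister edge.  Bootstrap support is the
classical column-resampling percentage per internal bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass(frozen=True)
class ConcatenatedAlignment:
    """Equal-length aligned blocks, one per gene, all covering all taxa."""

    taxa: tuple[str, ...]
    blocks: tuple[Mapping[str, str], ...]

    def __post_init__(self) -> None:
        for block in self.blocks:
            if set(block) != set(self.taxa):
                raise ValueError("every taxon must appear in every block")
            widths = {len(s) for s in block.values()}
            if len(widths) != 1:
                raise ValueError("block rows must share one width")

    @property
    def total_columns(self) -> int:
        return sum(len(next(iter(b.values()))) for b in self.blocks)

    def concatenated(self) -> dict[str, str]:
        return {t: "".join(b[t] for b in self.blocks) for t in self.taxa}


def jc_distance(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"p-distance {p} beyond Jukes-Cantor saturation")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - (4.0 / 3.0) * p)


def build_distance_matrix(
    alignment: Mapping[str, str], min_shared: int = 100
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Jukes–Cantor distances over shared ungapped columns."""
    taxa = list(alignment)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    arrs = {t: np.frombuffer(alignment[t].encode(), dtype=np.uint8)
            for t in taxa}
    widths = {len(a) for a in arrs.values()}
    if len(widths) != 1:
        raise ValueError("alignment rows must have equal length")
    gap = ord("-")
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[taxa[i]], arrs[taxa[j]]
            shared = (a != gap) & (b != gap)
            m = int(shared.sum())
            if m < min_shared:
                raise ValueError(
                    f"taxa {taxa[i]}/{taxa[j]} share only {m} ungapped "
                    f"columns (< {min_shared})"
                )
            p = float((a[shared] != b[shared]).mean())
            dm[i, j] = dm[j, i] = jc_distance(p)
    return dm, taxa


def neighbor_joining(dm: np.ndarray, taxa: Sequence[str]) -> TreeNode:
    """Saitou–Nei NJ; returns an unrooted tree as a trifurcating root.

    Ties in the Q-matrix resolve to the smallest (i, j) in taxon order.
    Negative branch lengths are clamped to 0 and the deficit moved to the
    sister edge.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if dm.shape != (n, n):
        raise ValueError("matrix shape does not match taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    d = dm.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest flat index wins ties
        ai, aj = divmod(int(np.argmin(q)), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent.children = [ni, nj]
        new_idx = d.shape[0]
        newrow = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, : new_idx] = newrow
        d[: new_idx, new_idx] = newrow
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [new_idx]
    # final trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each encoded as the leaf set on the
    far side of an internal edge (canonicalized to the smaller side,
    ties by sorted names)."""
    all_leaves = frozenset(tree.leaf_names())
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            out.add(_canonical(below, all_leaves))
        return below

    walk(tree)
    return out


def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return min(side, other, key=lambda s: sorted(s))


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 100,
    seed: int | None = None,
    min_shared: int = 100,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Column-resampling bootstrap for the NJ tree of ``alignment``.

    Returns the tree built from the original alignment, with internal
    ``support`` fields set, plus the support map per bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    dm, taxa = build_distance_matrix(alignment, min_shared)
    tree = neighbor_joining(dm, taxa)
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    cols = len(next(iter(alignment.values())))
    mats = {t: np.frombuffer(alignment[t].encode(), dtype=np.uint8)
            for t in taxa}
    for _ in range(n_reps):
        idx = rng.integers(0, cols, size=cols)
        resampled = {t: mats[t][idx].tobytes().decode() for t in taxa}
        try:
            dm_r, _ = build_distance_matrix(resampled, min_shared)
        except ValueError:
            continue
        for bp in bipartitions(neighbor_joining(dm_r, taxa)):
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    _annotate_support(tree, support)
    return tree, support


def _annotate_support(tree: TreeNode, support: Mapping[frozenset[str], float]) -> None:
    universe = frozenset(tree.leaf_names())

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(universe) - 1:
            node.support = support.get(_canonical(below, universe))
        return below

    walk(tree)


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root the (unrooted) NJ tree on the edge leading to ``outgroup``,
    splitting that edge at its midpoint.

    The input tree is not modified.  The outgroup leaf comes out as a
    direct child of the new root, sister to all ingroup taxa.
    """
    import copy

    tree = copy.deepcopy(tree)
    path = _find_path(tree, outgroup)
    if path is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    leaf = path[-1]
    chain = path[:-1]  # root .. parent-of-leaf
    # invert the edges along the chain so the leaf's parent becomes the top
    for i in range(len(chain) - 1, 0, -1):
        parent, child = chain[i - 1], chain[i]
        parent.children.remove(child)
        child.children.append(parent)
        parent.length = child.length
        parent.support = child.support
    pivot = chain[-1]
    pivot.children.remove(leaf)
    pivot.support = None
    half = leaf.length / 2
    leaf.length = half
    pivot.length = half
    root = TreeNode(children=[leaf, pivot])
    return root


def _find_path(tree: TreeNode, name: str) -> list[TreeNode] | None:
    if tree.is_leaf:
        return [tree] if tree.name == name else None
    for c in tree.children:
        sub = _find_path(c, name)
        if sub is not None:
            return [tree, *sub]
    return None


def distance_matrix_frame(dm: np.ndarray, taxa: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(dm, index=list(taxa), columns=list(taxa))
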