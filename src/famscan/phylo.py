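"""Phylogenetic trees: Newick I/O, Brownian covariance, independent contrasts.

The tree is the statistical backbone of the whole analysis: under a Brownian
motion model of trait evolution, the expected covariance between two species'
trait values is proportional to the branch length they share from the root,
so the phylogeny directly parameterises the error covariance of every
generalized least squares fit downstream.

Trees are stored in a flat pre-order array representation with a canonical
child order (children sorted by the lexicographically smallest tip label of
their clade), which makes every derived object — Newick strings, covariance
matrices, contrast sets — byte-reproducible across runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "NewickError",
    "PhyloTree",
    "CovMatrix",
    "ContrastSet",
    "PicCorrelation",
    "read_newick",
    "write_newick",
    "prune_to",
    "brownian_covariance",
    "independent_contrasts",
    "pic_correlation",
]

#: Relative tolerance on root-to-tip depths used for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Raised for malformed Newick input (parse errors, missing branch
    lengths, duplicate or empty tip labels)."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree with branch lengths, indexed in canonical pre-order.

    Node 0 is the root; every node's index is greater than its parent's, so a
    reversed iteration over node indices is a valid post-order traversal.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 for the root.
    brlen : (n_nodes,) float array; the root's entry is 0.
    children : tuple of tuples of child indices, in canonical order.
    labels : tuple of tip labels (``None`` for internal nodes).
    """

    parent: np.ndarray
    brlen: np.ndarray
    children: tuple
    labels: tuple

    # -- construction -----------------------------------------------------

    @staticmethod
    def from_arrays(parent: Sequence[int], brlen: Sequence[float],
                    labels: Sequence) -> "PhyloTree":
        """Build a tree from parent pointers in any node order.

        Validates the single-root / single-parent invariants, checks tip
        labels, then re-indexes into canonical pre-order.
        """
        parent = np.asarray(parent, dtype=int)
        brlen = np.asarray(brlen, dtype=float)
        labels = list(labels)
        n = len(parent)
        if not (len(brlen) == len(labels) == n):
            raise ValueError("parent, brlen and labels must have equal length")
        roots = np.flatnonzero(parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        root = int(roots[0])
        kids: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != root:
                kids[parent[i]].append(i)
        tip_labels = [labels[i] for i in range(n) if not kids[i]]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise NewickError("every tip must carry a non-empty label")
        seen: set[str] = set()
        for lab in tip_labels:
            if lab in seen:
                raise NewickError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        if np.any(brlen[np.arange(n) != root] < 0):
            bad = [i for i in range(n) if i != root and brlen[i] < 0]
            raise ValueError(f"negative branch length at node {bad[0]}")

        # smallest descendant tip label per node, for canonical child order
        minlab: list[str] = [""] * n
        order = _postorder(kids, root)
        for u in order:
            if not kids[u]:
                minlab[u] = labels[u]
            else:
                kids[u].sort(key=lambda c: minlab[c])
                minlab[u] = minlab[kids[u][0]]

        # re-index in pre-order
        perm: list[int] = []
        stack = [root]
        while stack:
            u = stack.pop()
            perm.append(u)
            stack.extend(reversed(kids[u]))
        pos = {old: new for new, old in enumerate(perm)}
        new_parent = np.array(
            [-1 if parent[old] < 0 else pos[parent[old]] for old in perm], dtype=int)
        new_brlen = brlen[perm].copy()
        new_brlen[0] = 0.0
        new_children = tuple(tuple(pos[c] for c in kids[old]) for old in perm)
        new_labels = tuple(labels[old] if not kids[old] else None for old in perm)
        return PhyloTree(new_parent, new_brlen, new_children, new_labels)

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> tuple:
        return tuple(i for i in range(self.n_nodes) if not self.children[i])

    @property
    def tip_labels(self) -> tuple:
        """Tip labels in canonical traversal order."""
        return tuple(self.labels[i] for i in self.tip_indices)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.brlen[i]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[list(self.tip_indices)]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.tip_depths()
        top = d.max()
        return top == 0 or (top - d.min()) <= rtol * top

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    # -- Newick -----------------------------------------------------------

    def to_newick(self) -> str:
        """Canonical Newick string with shortest-round-trip branch lengths."""

        def rec(u: int) -> str:
            if not self.children[u]:
                return f"{self.labels[u]}:{float(self.brlen[u])!r}"
            inner = ",".join(rec(c) for c in self.children[u])
            if u == 0:
                return f"({inner})"
            return f"({inner}):{float(self.brlen[u])!r}"

        if self.n_nodes == 1:  # degenerate single node
            return f"{self.labels[0]};"
        return rec(0) + ";"

    # -- pruning ----------------------------------------------------------

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to a subset of tips.

        Unary internal nodes on the retained subtree are suppressed with
        their branch lengths summed, and the new root is the MRCA of the
        kept tips, so all pairwise tip path lengths are preserved exactly.
        """
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least two tips to prune to")
        mark = np.zeros(self.n_nodes, dtype=bool)
        for i in self.tip_indices:
            if self.labels[i] in keep:
                u = i
                while u >= 0 and not mark[u]:
                    mark[u] = True
                    u = self.parent[u]

        parents: list[int] = []
        brlens: list[float] = []
        labels: list = []

        def emit(parent_idx: int, bl: float, lab) -> int:
            parents.append(parent_idx)
            brlens.append(bl)
            labels.append(lab)
            return len(parents) - 1

        def build(u: int, extra: float, parent_idx: int) -> None:
            kept_kids = [c for c in self.children[u] if mark[c]]
            if not kept_kids:
                emit(parent_idx, self.brlen[u] + extra, self.labels[u])
            elif len(kept_kids) == 1:
                # suppress the unary node: fold its edge into the child's
                build(kept_kids[0], extra + self.brlen[u], parent_idx)
            else:
                me = emit(parent_idx, self.brlen[u] + extra, None)
                for c in kept_kids:
                    build(c, 0.0, me)

        # descend to the MRCA of kept tips (first node with >=2 kept children)
        u = 0
        while True:
            kept_kids = [c for c in self.children[u] if mark[c]]
            if len(kept_kids) >= 2 or not kept_kids:
                break
            u = kept_kids[0]
        me = emit(-1, 0.0, None)
        for c in (c for c in self.children[u] if mark[c]):
            build(c, 0.0, me)
        return PhyloTree.from_arrays(parents, brlens, labels)

    # -- polytomy resolution ----------------------------------------------

    def resolve_polytomies(self) -> "PhyloTree":
        """Return a strictly bifurcating tree.

        Nodes with more than two children are resolved by repeatedly joining
        the first two children (canonical order, i.e. lexicographic by the
        clade's smallest tip label) under a new zero-length internal node.
        """
        if self.is_binary() and all(len(c) != 1 for c in self.children):
            return self
        parents = list(self.parent)
        brlens = list(self.brlen)
        labels = list(self.labels)
        kids = [list(c) for c in self.children]
        for u in range(self.n_nodes):
            while len(kids[u]) > 2:
                a, b = kids[u][0], kids[u][1]
                parents.append(u)
                brlens.append(0.0)
                labels.append(None)
                new = len(parents) - 1
                parents[a] = new
                parents[b] = new
                kids[u] = [new] + kids[u][2:]
                kids.append([a, b])
        return PhyloTree.from_arrays(parents, brlens, labels)

    def pairwise_tip_distances(self) -> tuple:
        """(labels, matrix) of patristic distances between tips."""
        labs = self.tip_labels
        d = self.depths()
        V = brownian_covariance(self).matrix
        tipd = d[list(self.tip_indices)]
        D = tipd[:, None] + tipd[None, :] - 2.0 * V
        np.fill_diagonal(D, 0.0)
        return labs, D


def _postorder(kids: Sequence[Sequence[int]], root: int) -> list[int]:
    order: list[int] = []
    stack = [(root, False)]
    while stack:
        u, done = stack.pop()
        if done:
            order.append(u)
        else:
            stack.append((u, True))
            for c in kids[u]:
                stack.append((c, False))
    return order


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths mandatory, comments ignored)."""
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    parents: list[int] = []
    brlens: list[float] = []
    labels: list = []
    index: dict = {}
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            parent_idx = -1
            bl = 0.0
        else:
            parent_idx = index[id(node.parent_node)]
            bl = node.edge.length
            if bl is None:
                who = node.taxon.label if node.taxon else "<internal>"
                raise NewickError(f"missing branch length on edge to {who!r}")
        lab = node.taxon.label if node.taxon is not None else (node.label or None)
        parents.append(parent_idx)
        brlens.append(float(bl))
        labels.append(lab)
        index[id(node)] = len(parents) - 1
    tree = PhyloTree.from_arrays(parents, brlens, labels)
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric within tolerance; GLS remains "
                      "valid for any positive semi-definite covariance",
                      stacklevel=2)
    return tree


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def prune_to(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Functional alias for :meth:`PhyloTree.prune_to`."""
    return tree.prune_to(keep)


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovMatrix:
    """Brownian-motion covariance among tips: shared root-to-MRCA path lengths."""

    species: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")


def brownian_covariance(tree: PhyloTree) -> CovMatrix:
    """Covariance implied by Brownian motion on the tree.

    ``V[i, j]`` is the root-to-MRCA path length of tips *i* and *j*; the
    diagonal holds root-to-tip depths. Species order is the canonical tip
    traversal order of the tree.
    """
    if tree.n_tips < 2:
        raise ValueError("covariance needs at least two tips")
    depths = tree.depths()
    tips = tree.tip_indices
    tip_pos = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    # post-order accumulation of tip sets; cross-child pairs share this node
    tipsets: dict[int, list[int]] = {}
    for u in reversed(range(tree.n_nodes)):
        if not tree.children[u]:
            tipsets[u] = [tip_pos[u]]
            V[tip_pos[u], tip_pos[u]] = depths[u]
        else:
            acc: list[int] = []
            for c in tree.children[u]:
                for a in acc:
                    for b in tipsets[c]:
                        V[a, b] = V[b, a] = depths[u]
                acc.extend(tipsets.pop(c))
            tipsets[u] = acc
    return CovMatrix(tree.tip_labels, V)


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSet:
    """Felsenstein's standardized contrasts (units: trait per sqrt(time))."""

    values: np.ndarray
    node_ids: np.ndarray
    variances: np.ndarray


def independent_contrasts(tree: PhyloTree, x: Mapping[str, float]) -> ContrastSet:
    """Phylogenetically independent contrasts by the pruning recursion.

    At each internal node the two daughter values are differenced and scaled
    by the square root of their summed (branch-extended) variances; the
    ancestral value is the precision-weighted mean and the node's branch is
    lengthened by ``v1*v2/(v1+v2)``. Polytomies are resolved deterministically
    into zero-length bifurcations first.
    """
    t = tree.resolve_polytomies()
    for lab in t.tip_labels:
        if lab not in x:
            raise KeyError(f"trait value missing for tip {lab!r}")
    val = np.zeros(t.n_nodes)
    var = np.zeros(t.n_nodes)
    contrasts: list[float] = []
    node_ids: list[int] = []
    variances: list[float] = []
    for u in reversed(range(t.n_nodes)):
        kids = t.children[u]
        if not kids:
            val[u] = float(x[t.labels[u]])
            var[u] = t.brlen[u]
            continue
        c1, c2 = kids
        v1, v2 = var[c1], var[c2]
        s = v1 + v2
        diff = val[c1] - val[c2]
        if s <= 0:
            if diff != 0:
                raise ZeroDivisionError(
                    f"zero contrast variance at node {u} with unequal values")
            contrasts.append(0.0)
            val[u] = 0.5 * (val[c1] + val[c2])
            var[u] = t.brlen[u]
        else:
            contrasts.append(diff / math.sqrt(s))
            val[u] = (val[c1] * v2 + val[c2] * v1) / s
            var[u] = t.brlen[u] + v1 * v2 / s
        node_ids.append(u)
        variances.append(s)
    order = np.argsort(node_ids)  # ascending node index, deterministic
    return ContrastSet(np.asarray(contrasts)[order],
                       np.asarray(node_ids)[order],
                       np.asarray(variances)[order])


@dataclass(frozen=True)
class PicCorrelation:
    """Correlation of two contrast sets, computed through the origin."""

    r: float
    p: float
    df: int
    degenerate: bool = False


def pic_correlation(tree: PhyloTree, x: Mapping[str, float],
                    y: Mapping[str, float]) -> PicCorrelation:
    """Independent-contrast correlation between two tip traits.

    The correlation is computed through the origin (contrasts have an
    arbitrary sign, so no intercept is fitted) and tested with
    ``t = r*sqrt(df/(1-r^2))`` on ``df = n_contrasts - 1`` degrees of
    freedom. A zero-variance contrast set yields a flagged degenerate
    result rather than a silent zero.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least three tips for a contrast correlation")
    cx = independent_contrasts(tree, x).values
    cy = independent_contrasts(tree, y).values
    sxx = float(cx @ cx)
    syy = float(cy @ cy)
    # a constant trait yields contrasts that are pure round-off; judge
    # degeneracy relative to the tip-value magnitude, not against exact zero
    tol_x = (1e-10 * max(1.0, max(abs(v) for v in x.values()))) ** 2 * len(cx)
    tol_y = (1e-10 * max(1.0, max(abs(v) for v in y.values()))) ** 2 * len(cy)
    if sxx <= tol_x or syy <= tol_y:
        return PicCorrelation(math.nan, math.nan, len(cx) - 1, degenerate=True)
    r = float(cx @ cy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = len(cx) - 1
    if abs(r) >= 1.0:
        return PicCorrelation(r, 0.0, df)
    tstat = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return PicCorrelation(r, p, df)
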