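"""Evolutionary distinctiveness indices: Fair Proportion, Shapley value, HED.

All three indices are linear combinations of branch lengths with split-based
coefficients, which makes them degree-agnostic (polytomies are handled for
free) and computable in a single pass over the tree:

* **Fair Proportion** (rooted): every edge is shared equally by the leaves
  below it, ``FP(x) = sum over the root-to-x path of len(e) / #leaves_below(e)``.
* **Shapley value** (unrooted): ``psi_x = sum_e |far(x,e)| / (n * |near(x,e)|) * len(e)``
  where ``near(x,e)`` is the split block containing ``x``.  This equals the
  game-theoretic Shapley value of the PD coalitional game.
* **HED** (unrooted, extinction probabilities ``p``): the expected marginal PD
  that ``x`` adds to the set of surviving taxa when every other taxon goes
  extinct independently with probability ``p(y)``; per edge the coefficient is
  ``prod(p over near(x,e)-{x}) * (1 - prod(p over far(x,e)))``.

The linear-time evaluation replaces every edge ``{v, w}`` by the two arcs
``(v, w)`` and ``(w, v)``.  For a leaf ``x``, the score is the sum of
``coef(a) * len(a)`` over the arcs directed *away* from ``x``; walking the
leaves in the planar (Euler-tour) order, consecutive leaves differ only in
the arcs along the path between them, so after one direct evaluation each
remaining leaf costs only its path — at most two touches per edge in total.

Every function accepts either a rooted or unrooted tree; the unrooted indices
silently suppress a degree-2 root first (with a log notice).  Quadratic
"direct" versions (:func:`shapley_quadratic`, :func:`hed_quadratic`) evaluate
the per-taxon edge sums without any incremental update and serve as mid-scale
cross-checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import TaxonSetError, ValidationError
from .tree import PhyloTree

__all__ = [
    "LeafOrdering",
    "ArcProducts",
    "TraversalStats",
    "fair_proportion",
    "shapley_linear",
    "shapley_quadratic",
    "hed_linear",
    "hed_quadratic",
    "hed_zero_prob",
    "edge_product",
    "pendant_lengths",
    "compute_leaf_ordering",
    "subtree_products",
    "score_table",
]

logger = logging.getLogger(__name__)

#: probabilities below this are treated as exactly zero (see hed_linear)
TINY_P = 1e-300

#: switch per-split probability products to log space above this many taxa
_LOG_DOMAIN_ABOVE = 64


# ----------------------------------------------------------------- utilities
def _as_unrooted(tree: PhyloTree) -> PhyloTree:
    if tree.is_rooted:
        logger.info(
            "rooted input: suppressing the root (unrooted-tree index requested)"
        )
        return tree.unrooted()
    return tree


def _align_probs(tree: PhyloTree, p) -> np.ndarray:
    """Extinction probabilities aligned to ``tree.taxa`` order.

    ``p`` may be a mapping, a pandas Series, or an ExtinctionMap-like object
    exposing ``probs``.  Missing taxa and out-of-range values are hard errors.
    """
    if hasattr(p, "probs"):
        p = p.probs
    if isinstance(p, pd.Series):
        p = p.to_dict()
    if not isinstance(p, Mapping):
        raise ValidationError(
            "extinction probabilities must be a mapping taxon -> p"
        )
    taxa = tree.taxa
    missing = [t for t in taxa if t not in p]
    if missing:
        raise TaxonSetError(f"no extinction probability for taxa: {missing}")
    arr = np.asarray([float(p[t]) for t in taxa], dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        bad = [t for t, v in zip(taxa, arr) if not (0.0 <= v <= 1.0)]
        raise ValidationError(f"extinction probabilities outside [0, 1]: {bad}")
    tiny = (arr > 0.0) & (arr < TINY_P)
    if np.any(tiny):
        logger.warning(
            "probabilities below %g for %s treated as exactly 0 to avoid "
            "catastrophic division; the zero-probability formula is used",
            TINY_P,
            [t for t, m in zip(taxa, tiny) if m],
        )
        arr[tiny] = 0.0
    return arr


# ------------------------------------------------------------- leaf ordering
@dataclass(frozen=True)
class LeafOrdering:
    """A planar walk order of the leaves plus the edge paths between
    consecutive leaves; each edge occurs in at most two of those paths."""

    labels: tuple[str, ...]
    vertices: tuple[int, ...]
    #: segments[i]: path from leaf i to leaf i+1 as (edge_id, moving_down)
    segments: tuple[tuple[tuple[int, bool], ...], ...]

    def between(self, i: int) -> tuple[int, ...]:
        """Edge ids on the path from leaf ``i`` to leaf ``i + 1``."""
        return tuple(e for e, _ in self.segments[i])


def _euler_leaf_tour(tree: PhyloTree):
    """Leaves in depth-first (Newick) order and the edge path between each
    consecutive pair, with per-step direction (True = descending away from
    the traversal root, i.e. the *next* leaf lies below that edge)."""
    r = tree.root if tree.root is not None else tree._start
    nbr = tree._nbr
    leaves: list[int] = []
    segs: list[list[tuple[int, bool]]] = []
    cur: list[tuple[int, bool]] = []
    stack: list[list[int]] = [[r, -1, 0]]
    while stack:
        fr = stack[-1]
        v, pe = fr[0], fr[1]
        if fr[2] == 0 and tree.is_leaf_vertex(v):
            if leaves:
                segs.append(cur)
            cur = []  # also discards the initial descent to the first leaf
            leaves.append(v)
        moved = False
        while fr[2] < len(nbr[v]):
            w, e = nbr[v][fr[2]]
            fr[2] += 1
            if e == pe:
                continue
            cur.append((e, True))
            stack.append([w, e, 0])
            moved = True
            break
        if not moved:
            stack.pop()
            if pe != -1:
                cur.append((pe, False))
    return leaves, segs


def compute_leaf_ordering(tree: PhyloTree) -> LeafOrdering:
    """The leaf sequence of a depth-first circuit of the tree (the Newick
    left-to-right order) and the connecting paths between consecutive
    leaves."""
    if tree.n < 2:
        raise ValidationError("need at least 2 taxa")
    leaves, segs = _euler_leaf_tour(tree)
    return LeafOrdering(
        tuple(tree.label_of(v) for v in leaves),
        tuple(leaves),
        tuple(tuple(s) for s in segs),
    )


# -------------------------------------------------------- traversal skeleton
@dataclass
class TraversalStats:
    """Instrumentation for the incremental leaf-to-leaf update."""

    edge_updates: int = 0
    num_edges: int = 0

    @property
    def within_linear_bound(self) -> bool:
        """Whether the amortised bound (<= 2 |E| coefficient updates) held."""
        return self.edge_updates <= 2 * self.num_edges


def _arc_sums(tree, kb_list, ka_list, stats: TraversalStats | None = None):
    """For every leaf x, ``sum over arcs directed away from x`` of
    ``coef(arc) * len(edge)``, for one or more coefficient families at once.

    ``kb_list[f][e]`` is family f's coefficient for the arc whose taxon is
    below edge e (relative to the traversal root), ``ka_list[f][e]`` for the
    arc whose taxon is above.  Returns one dict vertex->value per family.
    Evaluates the first leaf directly and updates along the planar order;
    the shared update counter is reported via ``stats``.
    """
    lam = tree._elen
    order, pv, pe = tree._orientation()
    leaves, segs = _euler_leaf_tour(tree)
    x1 = leaves[0]
    onpath = set()
    v = x1
    while pe[v] != -1:
        onpath.add(pe[v])
        v = pv[v]
    nfam = len(kb_list)
    acc = [0.0] * nfam
    for e in range(tree.num_edges):
        L = lam[e]
        if e in onpath:
            for f in range(nfam):
                acc[f] += kb_list[f][e] * L
        else:
            for f in range(nfam):
                acc[f] += ka_list[f][e] * L
    results = [{x1: a} for a in acc]
    updates = 0
    for i, seg in enumerate(segs):
        for e, down in seg:
            L = lam[e]
            if down:  # next leaf moves below e: its arc flips above -> below
                for f in range(nfam):
                    acc[f] += (kb_list[f][e] - ka_list[f][e]) * L
            else:
                for f in range(nfam):
                    acc[f] += (ka_list[f][e] - kb_list[f][e]) * L
            updates += 1
        xnext = leaves[i + 1]
        for f in range(nfam):
            results[f][xnext] = acc[f]
    if stats is not None:
        stats.edge_updates = updates
        stats.num_edges = tree.num_edges
    return results, leaves


def _series(tree: PhyloTree, per_vertex: dict[int, float], name: str) -> pd.Series:
    return pd.Series(
        [per_vertex[v] for v in tree._leaves],
        index=pd.Index(tree.taxa, name="taxon"),
        name=name,
        dtype=float,
    )


# ------------------------------------------------------------ fair proportion
def fair_proportion(tree: PhyloTree) -> pd.Series:
    """Fair Proportion (evolutionary distinctiveness) per taxon on a rooted
    tree; the values sum to the total edge length (root stem excluded)."""
    if not tree.is_rooted:
        raise ValidationError(
            "fair proportion is defined on a rooted tree: supply a rooted "
            "Newick or choose a root (e.g. tree.rooted_at / rooted_on_edge)"
        )
    order, pv, pe = tree._orientation(tree.root)
    below = tree.below_leaf_counts(order, pv, pe)
    acc = [0.0] * tree.num_vertices
    for v in order:
        e = pe[v]
        if e >= 0:
            acc[v] = acc[pv[v]] + tree._elen[e] / below[e]
    return _series(tree, {v: acc[v] for v in tree._leaves}, "fp")


# ------------------------------------------------------------------- Shapley
def _shapley_coefficients(t: PhyloTree):
    below = t.below_leaf_counts()
    n = t.n
    kb = [0.0] * t.num_edges
    ka = [0.0] * t.num_edges
    for e, b in enumerate(below):
        kb[e] = (n - b) / (n * b)
        ka[e] = b / (n * (n - b))
    return kb, ka


def shapley_linear(tree: PhyloTree, stats: TraversalStats | None = None) -> pd.Series:
    """Shapley value of every taxon, computed in linear time via the planar
    leaf ordering.  Rooted input is unrooted first (degree-2 root suppressed).
    The values sum to the total edge length (Shapley efficiency)."""
    t = _as_unrooted(tree)
    if t.n < 2:
        raise ValidationError("need at least 2 taxa")
    kb, ka = _shapley_coefficients(t)
    (vals,), _ = _arc_sums(t, [kb], [ka], stats)
    return _series(t, vals, "shapley")


def shapley_quadratic(tree: PhyloTree) -> pd.Series:
    """Direct per-taxon evaluation of the Shapley edge sum (O(n^2)); shares no
    code with the incremental update path and serves as a cross-check."""
    t = _as_unrooted(tree)
    if t.n < 2:
        raise ValidationError("need at least 2 taxa")
    below_sets = _edge_leaf_sets(t)
    n = t.n
    out = {}
    for x in t.taxa:
        s = 0.0
        for e in range(t.num_edges):
            b = len(below_sets[e])
            if x in below_sets[e]:
                s += (n - b) / (n * b) * t._elen[e]
            else:
                s += b / (n * (n - b)) * t._elen[e]
        out[x] = s
    return pd.Series(out, name="shapley", dtype=float).reindex(list(t.taxa)).rename_axis("taxon")


def _edge_leaf_sets(t: PhyloTree) -> list[frozenset[str]]:
    """Per edge, the set of taxa on its lower (away-from-start) side."""
    order, pv, pe = t._orientation()
    acc: list[set[str]] = [set() for _ in range(t.num_vertices)]
    below: list[frozenset[str]] = [frozenset()] * t.num_edges
    for v in reversed(order):
        if t.is_leaf_vertex(v):
            acc[v].add(t.label_of(v))
        e = pe[v]
        if e >= 0:
            below[e] = frozenset(acc[v])
            acc[pv[v]] |= acc[v]
    return below


# ----------------------------------------------------- probability products
@dataclass
class ArcProducts:
    """Per-edge products of extinction probabilities over each split side.

    Products are carried as (positive-factor part, zero-factor count): the
    positive part is a plain product for small trees and a sum of logs above
    :data:`_LOG_DOMAIN_ABOVE` taxa (plain products over thousands of factors
    underflow).  ``*_plain`` gives the true product (0 if any factor is 0);
    ``*_star`` the product over the strictly positive factors only.
    """

    log_domain: bool
    below_pos: list[float]
    below_zc: list[int]
    above_pos: list[float]
    above_zc: list[int]

    def _val(self, x: float) -> float:
        return math.exp(x) if self.log_domain else x

    def below_plain(self, e: int) -> float:
        return 0.0 if self.below_zc[e] else self._val(self.below_pos[e])

    def above_plain(self, e: int) -> float:
        return 0.0 if self.above_zc[e] else self._val(self.above_pos[e])

    def below_star(self, e: int) -> float:
        return self._val(self.below_pos[e])

    def above_star(self, e: int) -> float:
        return self._val(self.above_pos[e])


def subtree_products(tree: PhyloTree, p) -> ArcProducts:
    """Products of p over both sides of every edge, by one leafward and one
    rootward sweep (linear in the number of edges; sibling products are
    combined with prefix/suffix partials, never by division — division is
    unavailable when factors are 0)."""
    t = tree
    parr = _align_probs(t, p)
    pv_of = {t.vertex_of(lab): parr[i] for i, lab in enumerate(t.taxa)}
    log_domain = t.n > _LOG_DOMAIN_ABOVE
    ident = 0.0 if log_domain else 1.0

    def factor(pval: float) -> tuple[float, int]:
        if pval == 0.0:
            return ident, 1
        return (math.log(pval) if log_domain else pval), 0

    def comb(a: tuple[float, int], b: tuple[float, int]) -> tuple[float, int]:
        return (a[0] + b[0] if log_domain else a[0] * b[0]), a[1] + b[1]

    order, pvtx, pe = t._orientation()
    E = t.num_edges
    node: list[tuple[float, int]] = [(ident, 0)] * t.num_vertices
    below: list[tuple[float, int]] = [(ident, 0)] * E
    for v in reversed(order):
        cur = factor(pv_of[v]) if v in pv_of else (ident, 0)
        for w, e in t._nbr[v]:
            if e != pe[v]:
                cur = comb(cur, below[e])
        node[v] = cur
        if pe[v] >= 0:
            below[pe[v]] = cur
    above: list[tuple[float, int]] = [(ident, 0)] * E
    for v in order:
        kids = [(w, e) for w, e in t._nbr[v] if e != pe[v]]
        if not kids:
            continue
        base = factor(pv_of[v]) if v in pv_of else (ident, 0)
        if pe[v] >= 0:
            base = comb(base, above[pe[v]])
        m = len(kids)
        pref = [(ident, 0)] * (m + 1)
        for i, (w, e) in enumerate(kids):
            pref[i + 1] = comb(pref[i], below[e])
        suf = (ident, 0)
        for i in range(m - 1, -1, -1):
            w, e = kids[i]
            above[e] = comb(base, comb(pref[i], suf))
            suf = comb(suf, below[e])
    return ArcProducts(
        log_domain,
        [b[0] for b in below],
        [b[1] for b in below],
        [a[0] for a in above],
        [a[1] for a in above],
    )


# ----------------------------------------------------------------------- HED
def _hed_coefficients(t: PhyloTree, prods: ArcProducts):
    """Arc coefficients for HED: the ordinary family (for taxa with p > 0)
    and the zero-probability family, both per edge and per arc direction."""
    E = t.num_edges
    kbp = [0.0] * E
    kap = [0.0] * E
    kbt = [0.0] * E
    kat = [0.0] * E
    for e in range(E):
        Pb = prods.below_plain(e)
        Pa = prods.above_plain(e)
        kbp[e] = Pb * (1.0 - Pa)
        kap[e] = Pa * (1.0 - Pb)
        kbt[e] = prods.below_star(e) * (1.0 - Pa) if prods.below_zc[e] <= 1 else 0.0
        kat[e] = prods.above_star(e) * (1.0 - Pb) if prods.above_zc[e] <= 1 else 0.0
    return kbp, kap, kbt, kat


def hed_linear(tree: PhyloTree, p, stats: TraversalStats | None = None) -> pd.Series:
    """Heightened evolutionary distinctiveness of every taxon, in linear time.

    For taxa with ``p(x) > 0`` the ordinary arc sum divided by ``p(x)`` is
    used; taxa with ``p(x) = 0`` take the dedicated zero-probability arc sum
    (whose near-side products skip zero factors and vanish as soon as a split
    block holds two zero-probability taxa).  Both families ride the same
    incremental traversal.
    """
    t = _as_unrooted(tree)
    if t.n < 2:
        raise ValidationError("need at least 2 taxa")
    parr = _align_probs(t, p)
    prods = subtree_products(t, dict(zip(t.taxa, parr)))
    kbp, kap, kbt, kat = _hed_coefficients(t, prods)
    (s_pos, s_zero), _ = _arc_sums(t, [kbp, kbt], [kap, kat], stats)
    out = {}
    for lab, px in zip(t.taxa, parr):
        v = t.vertex_of(lab)
        out[v] = s_pos[v] / px if px > 0.0 else s_zero[v]
    return _series(t, out, "hed")


def hed_zero_prob(tree: PhyloTree, p, x: str) -> float:
    """HED of a single taxon with ``p(x) = 0`` via the zero-probability arc
    coefficients (equals the edge-sum definition for such taxa)."""
    t = _as_unrooted(tree)
    parr = _align_probs(t, p)
    pmap = dict(zip(t.taxa, parr))
    if x not in pmap:
        raise TaxonSetError(f"unknown taxon {x!r}")
    if pmap[x] > 0.0:
        raise ValidationError(
            f"taxon {x!r} has p > 0; use hed_linear for positive probabilities"
        )
    prods = subtree_products(t, pmap)
    _, _, kbt, kat = _hed_coefficients(t, prods)
    order, pv, pe = t._orientation()
    onpath = set()
    v = t.vertex_of(x)
    while pe[v] != -1:
        onpath.add(pe[v])
        v = pv[v]
    return float(
        sum(
            (kbt[e] if e in onpath else kat[e]) * t._elen[e]
            for e in range(t.num_edges)
        )
    )


def hed_quadratic(tree: PhyloTree, p) -> pd.Series:
    """Direct per-taxon evaluation of the HED edge sum (O(n^2) after per-edge
    products), independent of the incremental traversal; cross-check."""
    t = _as_unrooted(tree)
    if t.n < 2:
        raise ValidationError("need at least 2 taxa")
    parr = _align_probs(t, p)
    pmap = dict(zip(t.taxa, parr))
    below_sets = _edge_leaf_sets(t)
    E = t.num_edges
    pos_b = [1.0] * E
    zc_b = [0] * E
    for e in range(E):
        for lab in below_sets[e]:
            q = pmap[lab]
            if q == 0.0:
                zc_b[e] += 1
            else:
                pos_b[e] *= q
    tot_pos = 1.0
    tot_zc = 0
    for lab in t.taxa:
        q = pmap[lab]
        if q == 0.0:
            tot_zc += 1
        else:
            tot_pos *= q
    out = {}
    for lab in t.taxa:
        px = pmap[lab]
        s = 0.0
        for e in range(E):
            if lab in below_sets[e]:
                near_pos, near_zc = pos_b[e], zc_b[e]
                far_pos, far_zc = tot_pos / pos_b[e], tot_zc - zc_b[e]
            else:
                near_pos, near_zc = tot_pos / pos_b[e], tot_zc - zc_b[e]
                far_pos, far_zc = pos_b[e], zc_b[e]
            # remove the focal taxon from the near side
            if px == 0.0:
                near_zc -= 1
            else:
                near_pos /= px
            near = near_pos if near_zc == 0 else 0.0
            far = far_pos if far_zc == 0 else 0.0
            s += near * (1.0 - far) * t._elen[e]
        out[lab] = s
    return pd.Series(out, name="hed", dtype=float).reindex(list(t.taxa)).rename_axis("taxon")


# ----------------------------------------------------------------- EDGE etc.
def edge_product(fp_scores: pd.Series, p) -> pd.Series:
    """EDGE score: Fair Proportion multiplied by the extinction probability."""
    if hasattr(p, "probs"):
        p = p.probs
    pser = pd.Series(p, dtype=float)
    a = set(fp_scores.index)
    b = set(pser.index)
    if a != b:
        raise TaxonSetError(
            f"taxon sets differ; only in scores: {sorted(a - b)}, "
            f"only in probabilities: {sorted(b - a)}"
        )
    out = fp_scores * pser.reindex(fp_scores.index)
    out.name = "edge"
    return out


def pendant_lengths(tree: PhyloTree) -> pd.Series:
    """Terminal-edge length per taxon on the unrooted tree (a degree-2 root
    is suppressed first, so the two-taxon tree has one shared pendant)."""
    t = _as_unrooted(tree)
    d = t.pendant_lengths()
    return pd.Series(
        [d[lab] for lab in t.taxa],
        index=pd.Index(t.taxa, name="taxon"),
        name="pendant",
        dtype=float,
    )


_KNOWN_SCORES = ("fp", "shapley", "hed", "edge")


def score_table(
    tree: PhyloTree,
    scores: Iterable[str] = ("fp", "shapley"),
    p=None,
    include_pendant: bool = True,
) -> pd.DataFrame:
    """Requested scores for one tree as a DataFrame (rows in Newick leaf
    order).  ``hed`` and ``edge`` need extinction probabilities; ``fp`` and
    ``edge`` need a rooted tree."""
    scores = list(scores)
    unknown = [s for s in scores if s not in _KNOWN_SCORES]
    if unknown:
        raise ValidationError(
            f"unknown scores {unknown}; choose from {_KNOWN_SCORES}"
        )
    cols: dict[str, pd.Series] = {}
    if "fp" in scores or "edge" in scores:
        cols["fp"] = fair_proportion(tree)
    if "shapley" in scores:
        cols["shapley"] = shapley_linear(tree)
    if "hed" in scores or "edge" in scores:
        if p is None:
            raise ValidationError("hed/edge scores need extinction probabilities")
    if "hed" in scores:
        cols["hed"] = hed_linear(tree, p)
    if "edge" in scores:
        cols["edge"] = edge_product(cols["fp"], p)
    if include_pendant:
        cols["pendant"] = pendant_lengths(tree)
    ordered = [s for s in (*_KNOWN_SCORES, "pendant") if s in cols]
    df = pd.DataFrame({k: cols[k].reindex(list(tree.taxa)) for k in ordered})
    if "fp" not in scores and "fp" in df.columns:
        df = df.drop(columns=["fp"])
    df.index.name = "taxon"
    return df
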