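"""Edge-weighted phylogenetic trees: Newick I/O, splits, PD, rooting utilities.

The central object is :class:`PhyloTree`, an undirected tree with non-negative
edge lengths whose degree-1 vertices carry unique taxon labels.  A tree may be
*rooted* (a distinguished vertex, possibly of degree 2) or *unrooted* (no
vertex of degree 2 at all).  Branch lengths are kept in whatever units the
input uses (typically millions of years).

Newick parsing is delegated to dendropy; everything downstream works on the
light-weight adjacency representation defined here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

from .errors import NewickParseError, TaxonSetError, ValidationError

__all__ = [
    "PhyloTree",
    "Split",
    "parse_newick",
    "write_newick",
    "unroot",
    "phylogenetic_diversity",
    "split_of_edge",
]

_PLAIN_LABEL = re.compile(r"^[^\s()\[\]{}:;,\"']+$")


class PhyloTree:
    """An edge-weighted phylogenetic tree on a labelled taxon set.

    Vertices are integers ``0..num_vertices-1``; edges are indexed
    ``0..num_edges-1`` with endpoints in ``_eu``/``_ev`` and lengths in
    ``_elen``.  Adjacency lists preserve the left-to-right order of the
    source Newick string, which fixes the deterministic leaf ordering used
    throughout scoring.  Instances are treated as immutable; all "mutating"
    operations return new trees.
    """

    __slots__ = (
        "_nbr",
        "_eu",
        "_ev",
        "_elen",
        "_leaves",
        "_leaf_label",
        "_label_to_vertex",
        "root",
        "root_edge_length",
        "_start",
    )

    def __init__(
        self,
        nbr: list[list[tuple[int, int]]],
        eu: list[int],
        ev: list[int],
        elen: list[float],
        leaves: list[int],
        leaf_label: dict[int, str],
        root: int | None = None,
        root_edge_length: float | None = None,
        start: int = 0,
    ):
        self._nbr = nbr
        self._eu = eu
        self._ev = ev
        self._elen = elen
        self._leaves = leaves
        self._leaf_label = leaf_label
        self._label_to_vertex = {lab: v for v, lab in leaf_label.items()}
        self.root = root
        self.root_edge_length = root_edge_length
        self._start = start

    # ------------------------------------------------------------------ basic
    @property
    def num_vertices(self) -> int:
        return len(self._nbr)

    @property
    def num_edges(self) -> int:
        return len(self._elen)

    @property
    def n(self) -> int:
        """Number of taxa (leaves)."""
        return len(self._leaves)

    @property
    def taxa(self) -> tuple[str, ...]:
        """Taxon labels in input (Newick left-to-right) order."""
        return tuple(self._leaf_label[v] for v in self._leaves)

    @property
    def is_rooted(self) -> bool:
        return self.root is not None

    @property
    def total_length(self) -> float:
        """Sum of all edge lengths; a stored root-stem length is excluded."""
        return float(sum(self._elen))

    def degree(self, v: int) -> int:
        return len(self._nbr[v])

    def is_leaf_vertex(self, v: int) -> bool:
        return v in self._leaf_label

    def label_of(self, v: int) -> str:
        return self._leaf_label[v]

    def vertex_of(self, label: str) -> int:
        try:
            return self._label_to_vertex[label]
        except KeyError:
            raise TaxonSetError(f"unknown taxon {label!r}") from None

    def edge_length(self, e: int) -> float:
        return self._elen[e]

    def edge_endpoints(self, e: int) -> tuple[int, int]:
        return self._eu[e], self._ev[e]

    def pendant_edge(self, label: str) -> int:
        """Edge index of the terminal edge attaching taxon ``label``."""
        v = self.vertex_of(label)
        return self._nbr[v][0][1]

    def pendant_lengths(self) -> dict[str, float]:
        """Terminal-edge length per taxon, on this tree as given.

        For unrooted-index semantics (where a degree-2 root would be
        suppressed first) call this on ``tree.unrooted()``.
        """
        return {
            self._leaf_label[v]: self._elen[self._nbr[v][0][1]] for v in self._leaves
        }

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.is_rooted else "unrooted"
        return f"<PhyloTree {kind} n={self.n} edges={self.num_edges} total_length={self.total_length:g}>"

    # -------------------------------------------------------------- traversal
    def _orientation(self, r: int | None = None):
        """Orient the tree away from ``r``.

        Returns ``(order, parent_vertex, parent_edge)`` where ``order`` is a
        DFS pre-order (every vertex appears after its parent), so iterating
        ``reversed(order)`` is a valid bottom-up sweep.
        """
        if r is None:
            r = self.root if self.root is not None else self._start
        V = self.num_vertices
        pv = [-1] * V
        pe = [-2] * V
        pe[r] = -1
        order: list[int] = []
        stack = [r]
        while stack:
            v = stack.pop()
            order.append(v)
            for w, e in self._nbr[v]:
                if e != pe[v]:
                    pv[w] = v
                    pe[w] = e
                    stack.append(w)
        return order, pv, pe

    def below_leaf_counts(self, order=None, pv=None, pe=None) -> list[int]:
        """Per edge, the number of leaves on the side away from the traversal
        root (the "child" side)."""
        if order is None:
            order, pv, pe = self._orientation()
        cnt = [0] * self.num_vertices
        below = [0] * self.num_edges
        for v in reversed(order):
            if v in self._leaf_label:
                cnt[v] += 1
            e = pe[v]
            if e >= 0:
                below[e] = cnt[v]
                cnt[pv[v]] += cnt[v]
        return below

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        if self.n < 2:
            raise ValidationError(f"a tree needs at least 2 taxa, got {self.n}")
        if self.num_edges != self.num_vertices - 1:
            raise ValidationError("vertex/edge count mismatch: not a tree")
        order, _, _ = self._orientation(self._start if self.root is None else self.root)
        if len(order) != self.num_vertices:
            raise ValidationError("graph is not connected")
        labels = list(self._leaf_label.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate leaf labels: {dup}")
        for e, L in enumerate(self._elen):
            if not (math.isfinite(L) and L >= 0.0):
                raise ValidationError(
                    f"edge {e} has invalid length {L!r}; lengths must be finite and >= 0"
                )
        for v in range(self.num_vertices):
            d = self.degree(v)
            if d == 0:
                raise ValidationError("isolated vertex")
            if d == 1 and v not in self._leaf_label:
                raise ValidationError(f"unlabelled degree-1 vertex {v}")
            if d == 2 and v != self.root:
                raise ValidationError(
                    "degree-2 vertex (unifurcation) allowed only at the root"
                )

    # ------------------------------------------------------------ derivations
    def _copy(self) -> "PhyloTree":
        return PhyloTree(
            [list(a) for a in self._nbr],
            list(self._eu),
            list(self._ev),
            list(self._elen),
            list(self._leaves),
            dict(self._leaf_label),
            self.root,
            self.root_edge_length,
            self._start,
        )

    def scaled(self, c: float) -> "PhyloTree":
        """Multiply every branch length by ``c > 0``."""
        if not (c > 0):
            raise ValidationError(f"scale factor must be positive, got {c!r}")
        t = self._copy()
        t._elen = [L * c for L in t._elen]
        if t.root_edge_length is not None:
            t.root_edge_length *= c
        return t

    def unrooted(self) -> "PhyloTree":
        """Drop the root; a degree-2 root is suppressed, merging its two
        incident edges into one whose length is the sum.  Total edge length
        and every leaf-set split are preserved."""
        if self.n < 2:
            raise ValidationError("cannot unroot a tree with fewer than 2 taxa")
        if not self.is_rooted:
            return self
        r = self.root
        if self.degree(r) != 2:
            t = self._copy()
            t._start = r
            t.root = None
            t.root_edge_length = None
            return t
        (c1, e1), (c2, e2) = self._nbr[r]
        merged = self._elen[e1] + self._elen[e2]
        vmap = [-1] * self.num_vertices
        k = 0
        for v in range(self.num_vertices):
            if v != r:
                vmap[v] = k
                k += 1
        emap = [-1] * self.num_edges
        eu: list[int] = []
        ev: list[int] = []
        elen: list[float] = []
        for e in range(self.num_edges):
            if e in (e1, e2):
                continue
            emap[e] = len(elen)
            eu.append(vmap[self._eu[e]])
            ev.append(vmap[self._ev[e]])
            elen.append(self._elen[e])
        enew = len(elen)
        eu.append(vmap[c1])
        ev.append(vmap[c2])
        elen.append(merged)
        nbr: list[list[tuple[int, int]]] = [[] for _ in range(k)]
        for v in range(self.num_vertices):
            if v == r:
                continue
            for w, e in self._nbr[v]:
                if w == r:
                    continue
                nbr[vmap[v]].append((vmap[w], emap[e]))
        # the merged edge goes last so a DFS from c1 still yields the input
        # Newick leaf order
        nbr[vmap[c1]].append((vmap[c2], enew))
        nbr[vmap[c2]].append((vmap[c1], enew))
        leaves = [vmap[v] for v in self._leaves]
        leaf_label = {vmap[v]: lab for v, lab in self._leaf_label.items()}
        return PhyloTree(nbr, eu, ev, elen, leaves, leaf_label, None, None, vmap[c1])

    def rooted_at(self, v: int) -> "PhyloTree":
        """Return a rooted copy with vertex ``v`` as root (``v`` must not be a
        leaf unless n == 2's endpoints are all there is)."""
        if self.is_leaf_vertex(v) and self.num_vertices > 2:
            raise ValidationError("cannot root at a leaf vertex")
        t = self._copy()
        t.root = v
        t._start = v
        t.root_edge_length = None
        return t

    def rooted_on_edge(self, e: int, fraction: float = 0.5) -> "PhyloTree":
        """Return a rooted copy whose (degree-2) root subdivides edge ``e``,
        at ``fraction`` of the edge length from endpoint ``_eu[e]``."""
        if not (0.0 <= fraction <= 1.0):
            raise ValidationError("fraction must be in [0, 1]")
        u, w = self._eu[e], self._ev[e]
        L = self._elen[e]
        t = self._copy()
        rnew = t.num_vertices
        t._nbr.append([])
        # reuse edge slot e for u--root, add a new edge root--w
        t._eu[e], t._ev[e] = u, rnew
        t._elen[e] = L * fraction
        e2 = t.num_edges
        t._eu.append(rnew)
        t._ev.append(w)
        t._elen.append(L * (1.0 - fraction))
        t._nbr[u] = [(rnew, e) if (x, ee) == (w, e) else (x, ee) for x, ee in t._nbr[u]]
        t._nbr[w] = [(rnew, e2) if (x, ee) == (u, e) else (x, ee) for x, ee in t._nbr[w]]
        t._nbr[rnew] = [(u, e), (w, e2)]
        t.root = rnew
        t._start = rnew
        t.root_edge_length = None
        return t

    def restricted_to(self, taxa: Iterable[str]) -> "PhyloTree":
        """Prune to the given taxa, suppressing the unifurcations that arise
        and summing merged branch lengths."""
        keep = set(taxa)
        unknown = keep - set(self.taxa)
        if unknown:
            raise TaxonSetError(f"unknown taxa: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValidationError("restriction must retain at least 2 taxa")
        order, pv, pe = self._orientation()
        frag: dict[int, tuple[str, float]] = {}
        for v in reversed(order):
            if v in self._leaf_label:
                lab = self._leaf_label[v]
                if lab in keep:
                    frag[v] = (_quote_label(lab), 0.0)
                continue
            parts = []
            for w, e in self._nbr[v]:
                if e == pe[v]:
                    continue
                if w in frag:
                    s, extra = frag[w]
                    parts.append((s, self._elen[pe[w]] + extra))
            if not parts:
                continue
            if len(parts) == 1:
                s, extra = parts[0]
                frag[v] = (s, extra)
            else:
                inner = ",".join(f"{s}:{_fmt_len(L)}" for s, L in parts)
                frag[v] = (f"({inner})", 0.0)
        top = order[0]
        s, _ = frag[top]
        pruned = parse_newick(s + ";")
        return pruned if self.is_rooted else pruned.unrooted()

    def as_newick(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------- Split
@dataclass(frozen=True)
class Split:
    """Bipartition of the taxon set induced by deleting one edge, addressed
    from a reference taxon ``taxon``: ``block`` is the side containing it."""

    edge: int
    taxon: str
    block: frozenset[str]
    co_block: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.block)

    @property
    def co_size(self) -> int:
        return len(self.co_block)


# ------------------------------------------------------------------- parsing
def _clade_hint(node) -> str:
    tips = [l.taxon.label for l in node.leaf_iter() if l.taxon is not None][:3]
    return "clade containing " + ", ".join(repr(t) for t in tips)


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick tree string into a rooted :class:`PhyloTree`.

    Every edge must carry a branch length except the optional root stem,
    which is stored on ``root_edge_length`` but excluded from all scores and
    from ``total_length``.  Internal node labels are accepted and ignored;
    leaf labels are unquoted, surrounding whitespace is trimmed, and
    underscores are preserved as-is.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "uplicate" in msg or "ultiple occurrences" in msg:
            raise ValidationError(f"duplicate leaf label: {msg}") from None
        raise NewickParseError(msg) from None

    seed = dtree.seed_node
    nbr: list[list[tuple[int, int]]] = []
    eu: list[int] = []
    ev: list[int] = []
    elen: list[float] = []
    leaves: list[int] = []
    leaf_label: dict[int, str] = {}
    seen: set[str] = set()

    stack = [(seed, -1)]
    while stack:
        node, pid = stack.pop()
        vid = len(nbr)
        nbr.append([])
        if pid >= 0:
            L = node.edge.length
            if L is None:
                raise ValidationError(
                    f"missing branch length on the {_clade_hint(node)}"
                )
            L = float(L)
            if not math.isfinite(L) or L < 0.0:
                raise ValidationError(
                    f"negative or non-finite branch length {L!r} on the {_clade_hint(node)}"
                )
            eid = len(elen)
            eu.append(pid)
            ev.append(vid)
            elen.append(L)
            nbr[pid].append((vid, eid))
            nbr[vid].append((pid, eid))
        children = node.child_nodes()
        if not children:
            lab = node.taxon.label if node.taxon is not None else node.label
            if lab is None or not str(lab).strip():
                raise ValidationError("unlabelled leaf")
            lab = str(lab).strip()
            if lab in seen:
                raise ValidationError(f"duplicate leaf label: {lab!r}")
            seen.add(lab)
            leaves.append(vid)
            leaf_label[vid] = lab
        else:
            for ch in reversed(children):
                stack.append((ch, vid))

    # the explicit stack (children pushed reversed) visits nodes in pre-order,
    # so vertex ids are pre-order and `leaves` is in Newick left-to-right order
    root_len = None if seed.edge.length is None else float(seed.edge.length)
    tree = PhyloTree(nbr, eu, ev, elen, leaves, leaf_label, 0, root_len, 0)
    tree.validate()
    return tree


# ------------------------------------------------------------------- writing
def _fmt_len(x: float) -> str:
    return repr(float(x))


def _quote_label(lab: str) -> str:
    if _PLAIN_LABEL.match(lab):
        return lab
    return "'" + lab.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Serialise to Newick with branch lengths; re-parsing yields an
    isomorphic tree with equal lengths.

    An unrooted tree is written from an internal vertex (a trifurcation or
    polytomy at the top); the two-taxon unrooted tree, which has no internal
    vertex, is written as a cherry with the single edge split in half.
    """
    if tree.is_rooted:
        r = tree.root
    else:
        r = tree._start
        if tree.is_leaf_vertex(r):
            if tree.num_vertices == 2:
                (a, b) = tree._leaves
                h = tree._elen[0] / 2.0
                return (
                    f"({_quote_label(tree.label_of(a))}:{_fmt_len(h)},"
                    f"{_quote_label(tree.label_of(b))}:{_fmt_len(h)});"
                )
            r = tree._nbr[r][0][0]

    out: list[str] = []
    stack: list[tuple[str, object, int]] = [("node", r, -1)]
    while stack:
        kind, a, pe = stack.pop()
        if kind == "text":
            out.append(a)  # type: ignore[arg-type]
            continue
        v = a  # type: ignore[assignment]
        children = [(w, e) for (w, e) in tree._nbr[v] if e != pe]
        suffix = f":{_fmt_len(tree._elen[pe])}" if pe >= 0 else ""
        if not children:
            out.append(_quote_label(tree.label_of(v)) + suffix)
            continue
        out.append("(")
        stack.append(("text", ")" + suffix, -1))
        seq: list[tuple[str, object, int]] = []
        for i, (w, e) in enumerate(children):
            if i:
                seq.append(("text", ",", -1))
            seq.append(("node", w, e))
        stack.extend(reversed(seq))
    tail = ""
    if tree.is_rooted and tree.root_edge_length is not None:
        tail = f":{_fmt_len(tree.root_edge_length)}"
    return "".join(out) + tail + ";"


# ---------------------------------------------------------------- operations
def unroot(tree: PhyloTree) -> PhyloTree:
    """Module-level alias for :meth:`PhyloTree.unrooted`."""
    return tree.unrooted()


def phylogenetic_diversity(tree: PhyloTree, taxa: Iterable[str]) -> float:
    """PD of a taxon subset: total length of the smallest subtree of the
    (unrooted) tree connecting the subset.  Empty and singleton subsets have
    PD 0; a stored root-stem length is never counted."""
    subset = set(taxa)
    unknown = subset - set(tree.taxa)
    if unknown:
        raise TaxonSetError(f"unknown taxa in subset: {sorted(unknown)}")
    k = len(subset)
    if k <= 1:
        return 0.0
    marked = {tree.vertex_of(lab) for lab in subset}
    order, pv, pe = tree._orientation()
    cnt = [0] * tree.num_vertices
    total = 0.0
    for v in reversed(order):
        if v in marked:
            cnt[v] += 1
        e = pe[v]
        if e >= 0:
            if 0 < cnt[v] < k:
                total += tree._elen[e]
            cnt[pv[v]] += cnt[v]
    return total


def split_of_edge(tree: PhyloTree, edge: int, x: str) -> Split:
    """The bipartition induced by ``edge``, addressed from taxon ``x``."""
    xv = tree.vertex_of(x)
    u, w = tree.edge_endpoints(edge)
    # leaves on w's side of the edge
    side: set[str] = set()
    stack = [(w, u)]
    while stack:
        v, par = stack.pop()
        if v in tree._leaf_label:
            side.add(tree._leaf_label[v])
        for nb, e in tree._nbr[v]:
            if nb != par and e != edge:
                stack.append((nb, v))
    other = set(tree.taxa) - side
    if x in side:
        return Split(edge, x, frozenset(side), frozenset(other))
    return Split(edge, x, frozenset(other), frozenset(side))
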