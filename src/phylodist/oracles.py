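"""Definitional brute-force oracles (testing only).

These evaluate the subset-sum definitions of the Shapley value and HED
literally, by enumerating all taxon subsets, plus the permutation-average
form of the Shapley value.  They are deliberately independent of the
incremental score code: PD is recomputed here from leaf-to-leaf edge paths
rather than from split counts.  Exponential in n, hard-capped at n = 12;
never used on real data.
"""

from __future__ import annotations

import math
from itertools import permutations

import pandas as pd

from .errors import ValidationError
from .tree import PhyloTree

__all__ = [
    "MAX_ORACLE_N",
    "MAX_PERMUTATION_N",
    "PathUnionPD",
    "shapley_exhaustive",
    "shapley_permutation",
    "hed_exhaustive",
]

MAX_ORACLE_N = 12
MAX_PERMUTATION_N = 7


class PathUnionPD:
    """PD by unioning leaf-to-leaf edge paths: the minimal subtree spanning a
    leaf set Y is the union of the paths from one member to all others.
    Subset values are cached per bitmask (taxa in tree order)."""

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        self.taxa = tree.taxa
        self._bit = {lab: i for i, lab in enumerate(self.taxa)}
        self._leafv = [tree.vertex_of(lab) for lab in self.taxa]
        self._paths: dict[tuple[int, int], frozenset[int]] = {}
        self._cache: dict[int, float] = {}

    def _path_edges(self, i: int, j: int) -> frozenset[int]:
        key = (i, j) if i < j else (j, i)
        hit = self._paths.get(key)
        if hit is not None:
            return hit
        t = self.tree
        a, b = self._leafv[key[0]], self._leafv[key[1]]
        prev: dict[int, tuple[int, int]] = {a: (-1, -1)}
        stack = [a]
        while stack:
            v = stack.pop()
            if v == b:
                break
            pv, _ = prev[v]
            for w, e in t._nbr[v]:
                if w != pv:
                    prev[w] = (v, e)
                    stack.append(w)
        edges = set()
        v = b
        while v != a:
            pv, e = prev[v]
            edges.add(e)
            v = pv
        fs = frozenset(edges)
        self._paths[key] = fs
        return fs

    def pd_mask(self, mask: int) -> float:
        if mask.bit_count() <= 1:
            return 0.0
        hit = self._cache.get(mask)
        if hit is not None:
            return hit
        members = [i for i in range(len(self.taxa)) if mask >> i & 1]
        first = members[0]
        edges: set[int] = set()
        for j in members[1:]:
            edges |= self._path_edges(first, j)
        val = sum(self.tree._elen[e] for e in edges)
        self._cache[mask] = val
        return val

    def pd(self, taxa) -> float:
        mask = 0
        for lab in taxa:
            mask |= 1 << self._bit[lab]
        return self.pd_mask(mask)


def _check_cap(tree: PhyloTree, cap: int, what: str) -> None:
    if tree.n > cap:
        raise ValidationError(
            f"{what} enumerates subsets and refuses n > {cap} (got n = {tree.n})"
        )


def shapley_exhaustive(tree: PhyloTree, x: str | None = None):
    """Shapley value by literal subset enumeration: for every subset Z
    containing x, weight (|Z|-1)! (n-|Z|)! / n! times the marginal PD of x.
    Factorials stay in exact integer arithmetic; one division at the end.
    Returns a float for one taxon, or a Series over all taxa."""
    _check_cap(tree, MAX_ORACLE_N, "shapley_exhaustive")
    t = tree.unrooted() if tree.is_rooted else tree
    calc = PathUnionPD(t)
    n = t.n
    fact = [math.factorial(k) for k in range(n + 1)]
    taxa = t.taxa if x is None else (x,)
    out = {}
    for lab in taxa:
        bit = 1 << calc._bit[lab]
        total = 0.0
        for mask in range(1 << n):
            if not mask & bit:
                continue
            z = mask.bit_count()
            w = fact[z - 1] * fact[n - z]
            total += w * (calc.pd_mask(mask) - calc.pd_mask(mask & ~bit))
        out[lab] = total / fact[n]
    if x is not None:
        return out[x]
    return pd.Series(out, dtype=float).reindex(list(t.taxa)).rename_axis("taxon").rename("shapley")


def shapley_permutation(tree: PhyloTree, x: str | None = None):
    """Second independent Shapley oracle: the marginal PD contribution of
    each taxon averaged over all n! arrival orders."""
    _check_cap(tree, MAX_PERMUTATION_N, "shapley_permutation")
    t = tree.unrooted() if tree.is_rooted else tree
    calc = PathUnionPD(t)
    n = t.n
    marg = [0.0] * n
    for perm in permutations(range(n)):
        mask = 0
        prev = 0.0
        for idx in perm:
            mask |= 1 << idx
            cur = calc.pd_mask(mask)
            marg[idx] += cur - prev
            prev = cur
    nfact = math.factorial(n)
    out = {lab: marg[i] / nfact for i, lab in enumerate(t.taxa)}
    if x is not None:
        return out[x]
    return pd.Series(out, dtype=float).reindex(list(t.taxa)).rename_axis("taxon").rename("shapley")


def hed_exhaustive(tree: PhyloTree, p, x: str | None = None):
    """HED by literal enumeration over all subsets Z of X - {x}: survival
    weight prod(1-p over Z) * prod(p over the rest) times the marginal PD of
    x on top of Z.  Empty products are 1; PD of sets of size <= 1 is 0."""
    _check_cap(tree, MAX_ORACLE_N, "hed_exhaustive")
    t = tree.unrooted() if tree.is_rooted else tree
    if hasattr(p, "probs"):
        p = p.probs
    calc = PathUnionPD(t)
    n = t.n
    pvec = [float(p[lab]) for lab in t.taxa]
    taxa = t.taxa if x is None else (x,)
    out = {}
    for lab in taxa:
        xi = calc._bit[lab]
        bit = 1 << xi
        others = [i for i in range(n) if i != xi]
        total = 0.0
        for sub in range(1 << (n - 1)):
            mask = 0
            weight = 1.0
            for k, i in enumerate(others):
                if sub >> k & 1:
                    mask |= 1 << i
                    weight *= 1.0 - pvec[i]
                else:
                    weight *= pvec[i]
            if weight == 0.0:
                continue
            total += weight * (calc.pd_mask(mask | bit) - calc.pd_mask(mask))
        out[lab] = total
    if x is not None:
        return out[x]
    return pd.Series(out, dtype=float).reindex(list(t.taxa)).rename_axis("taxon").rename("hed")
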