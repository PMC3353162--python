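"""Synthetic inputs: Yule trees, random extinction probabilities, fixtures.

Everything here is a pure function of its parameters and seed, so test
inputs are fully reproducible.  The Yule (pure-birth) simulator conditions
on the number of tips: lineages split at exponential waiting times until
``n_tips`` are alive, then one further waiting time sets the final epoch so
that the tree is exactly ultrametric.  Units are arbitrary (all indices are
scale-equivariant), with the birth rate defaulting to 1.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .iucn import CategoryValueSet, ExtinctionMap, builtin_value_set, CATEGORIES
from .tree import PhyloTree, parse_newick

__all__ = [
    "yule_tree",
    "random_probabilities",
    "basal_clade_fixture",
    "balanced_newick",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> PhyloTree:
    """A rooted, binary, ultrametric pure-birth tree with exactly ``n_tips``
    leaves (labelled ``t1..tN`` in Newick order) and no root stem."""
    if n_tips < 2:
        raise ValidationError(f"a Yule tree needs at least 2 tips, got {n_tips}")
    if not (birth_rate > 0):
        raise ValidationError("birth rate must be positive")
    rng = _rng(seed)
    # node bookkeeping: children[i] and end-time (split time for internals,
    # final epoch for tips); node 0 is the initial lineage
    children: list[list[int]] = [[]]
    end: list[float] = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node = active[i]
        end[node] = t
        a, b = len(children), len(children) + 1
        children.append([])
        children.append([])
        end.extend([0.0, 0.0])
        children[node] = [a, b]
        active[i] = a
        active.append(b)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        end[node] = t_end

    # assemble a PhyloTree directly (pre-order ids, Newick child order)
    nbr: list[list[tuple[int, int]]] = []
    eu: list[int] = []
    ev: list[int] = []
    elen: list[float] = []
    leaves: list[int] = []
    leaf_label: dict[int, str] = {}
    stack = [(0, -1)]
    tip_no = 0
    vid_to_node: dict[int, int] = {}
    while stack:
        node, pid = stack.pop()
        vid = len(nbr)
        nbr.append([])
        if pid >= 0:
            eid = len(elen)
            eu.append(pid)
            ev.append(vid)
            elen.append(end[node] - end[vid_to_node[pid]])
            nbr[pid].append((vid, eid))
            nbr[vid].append((pid, eid))
        vid_to_node[vid] = node
        if children[node]:
            for ch in reversed(children[node]):
                stack.append((ch, vid))
        else:
            tip_no += 1
            leaves.append(vid)
            leaf_label[vid] = f"t{tip_no}"
    tree = PhyloTree(nbr, eu, ev, elen, leaves, leaf_label, 0, None, 0)
    tree.validate()
    return tree


def random_probabilities(
    taxa,
    scheme: str = "uniform01",
    seed=None,
    n_zeros: int = 0,
    value_set: CategoryValueSet | str | None = None,
) -> ExtinctionMap:
    """Random extinction probabilities for a taxon set.

    ``uniform01`` draws p ~ U[0, 1]; ``category_sample`` draws one of the
    five IUCN categories uniformly per taxon and maps it through
    ``value_set`` (default ``isaac``).  ``n_zeros`` additionally forces that
    many taxa (chosen at random) to exactly p = 0, which exercises the
    zero-probability HED path.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValidationError("empty taxon set")
    if not (0 <= n_zeros <= len(taxa)):
        raise ValidationError(
            f"n_zeros must be in [0, {len(taxa)}], got {n_zeros}"
        )
    rng = _rng(seed)
    if scheme == "uniform01":
        vals = rng.uniform(0.0, 1.0, size=len(taxa))
        probs = dict(zip(taxa, vals.tolist()))
        prov = {t: "direct" for t in taxa}
        name = "custom"
    elif scheme == "category_sample":
        vs = builtin_value_set("isaac") if value_set is None else value_set
        if isinstance(vs, str):
            vs = builtin_value_set(vs)
        cats = rng.integers(len(CATEGORIES), size=len(taxa))
        probs = {t: vs[CATEGORIES[c]] for t, c in zip(taxa, cats)}
        prov = {t: f"category:{CATEGORIES[c]}" for t, c in zip(taxa, cats)}
        name = vs.name
    else:
        raise ValidationError(
            f"unknown scheme {scheme!r}; use 'uniform01' or 'category_sample'"
        )
    if n_zeros:
        for t in rng.choice(len(taxa), size=n_zeros, replace=False):
            probs[taxa[int(t)]] = 0.0
            prov[taxa[int(t)]] = "forced-zero"
    return ExtinctionMap(probs, prov, name)


def balanced_newick(labels, edge_length: float = 1.0) -> str:
    """Newick fragment (no trailing semicolon) for a balanced clade over the
    given labels with every internal edge of the given length."""
    labels = list(labels)
    if len(labels) == 1:
        return labels[0]
    mid = len(labels) // 2
    left = balanced_newick(labels[:mid], edge_length)
    right = balanced_newick(labels[mid:], edge_length)
    return f"({left}:{edge_length},{right}:{edge_length})"


def basal_clade_fixture(
    k_basal: int, n_rest: int, stem_length: float = 50.0
) -> PhyloTree:
    """A rooted tree whose root joins a small clade (``basal1..k``) and a
    large balanced clade (``sp1..n``) by two long stem edges.

    Mimics a small, anciently diverged sister group at the base of a large
    radiation: the deep stem contributes to the (unrooted) Shapley value of
    the basal tips but is shared away to almost nothing in their FP scores,
    so every basal tip ends up with Shapley > FP.
    """
    if k_basal < 1 or n_rest < 3:
        raise ValidationError("need k_basal >= 1 and n_rest >= 3")
    basal = balanced_newick([f"basal{i+1}" for i in range(k_basal)])
    rest = balanced_newick([f"sp{i+1}" for i in range(n_rest)])
    return parse_newick(f"({basal}:{stem_length},{rest}:{stem_length});")
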