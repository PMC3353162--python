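"""Multi-tree scoring: streaming accumulation of per-taxon mean and SD.

Tree samples (e.g. a Bayesian posterior over resolutions of a polytomy-rich
supertree) are scored one tree at a time; only the running moments are kept,
so memory is independent of the number of trees.  All trees in a batch must
share one taxon set — a mismatch is a hard error unless ``intersect=True``,
in which case every tree is pruned to the common taxa first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import TaxonSetError, ValidationError
from .scores import score_table
from .tree import PhyloTree, parse_newick

__all__ = [
    "iter_newick",
    "read_trees",
    "score_batch",
    "BatchResult",
    "CompareReport",
    "compare_report",
]


def iter_newick(source) -> Iterator[PhyloTree]:
    """Trees from a multi-tree Newick source (one tree per line): a path, a
    file-like object, or a string containing the Newick text itself."""
    if isinstance(source, str) and ";" in source:
        lines: Iterable[str] = source.splitlines()
    elif hasattr(source, "read"):
        lines = source
    else:
        with open(source) as fh:
            lines = fh.readlines()
    for line in lines:
        line = line.strip()
        if line and not line.startswith("#"):
            yield parse_newick(line)


def read_trees(source) -> list[PhyloTree]:
    return list(iter_newick(source))


@dataclass
class BatchResult:
    """Across-tree per-taxon moments of the requested scores.

    ``means``/``sds`` are DataFrames indexed by taxon (row order = leaf order
    of the first tree) with one column per score; SDs are sample standard
    deviations (ddof=1), reported as 0 for a single tree.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    n_trees: int
    scores: tuple[str, ...]
    per_tree: list[pd.DataFrame] | None = None

    def table(self) -> pd.DataFrame:
        """Aggregated wide table: <score>_mean and <score>_sd per column."""
        cols = {}
        for c in self.means.columns:
            cols[f"{c}_mean"] = self.means[c]
            cols[f"{c}_sd"] = self.sds[c]
        return pd.DataFrame(cols)


def score_batch(
    trees,
    scores: Sequence[str] = ("fp", "shapley"),
    p=None,
    intersect: bool = False,
    keep_per_tree: bool = False,
) -> BatchResult:
    """Score every tree of a batch and accumulate per-taxon mean and SD.

    ``trees`` may be a list of :class:`PhyloTree` or anything accepted by
    :func:`iter_newick`.  ``hed``/``edge`` scores require extinction
    probabilities ``p`` covering the (common) taxon set.
    """
    scores = tuple(scores)
    if not isinstance(trees, (list, tuple)):
        trees = read_trees(trees)
    if not trees:
        raise ValidationError("empty tree batch")
    if intersect:
        common = set(trees[0].taxa)
        for t in trees[1:]:
            common &= set(t.taxa)
        if len(common) < 2:
            raise ValidationError("fewer than 2 taxa shared by all trees")
        trees = [
            t if set(t.taxa) == common else t.restricted_to(common) for t in trees
        ]
    ref_taxa = list(trees[0].taxa)
    ref_set = set(ref_taxa)

    count = 0
    mean: np.ndarray | None = None
    m2: np.ndarray | None = None
    columns: list[str] | None = None
    kept: list[pd.DataFrame] = []
    for i, t in enumerate(trees):
        if set(t.taxa) != ref_set:
            raise TaxonSetError(
                f"tree {i} has a different taxon set than tree 0; symmetric "
                f"difference: {sorted(set(t.taxa) ^ ref_set)} "
                "(pass intersect=True to score on the shared taxa)"
            )
        df = score_table(t, scores, p=p).reindex(ref_taxa)
        if keep_per_tree:
            kept.append(df)
        x = df.to_numpy(dtype=float)
        count += 1
        if mean is None:
            columns = list(df.columns)
            mean = x.copy()
            m2 = np.zeros_like(x)
        else:
            delta = x - mean
            mean += delta / count
            m2 += delta * (x - mean)
    assert mean is not None and m2 is not None and columns is not None
    sd = np.sqrt(m2 / (count - 1)) if count > 1 else np.zeros_like(m2)
    idx = pd.Index(ref_taxa, name="taxon")
    return BatchResult(
        means=pd.DataFrame(mean, index=idx, columns=columns),
        sds=pd.DataFrame(sd, index=idx, columns=columns),
        n_trees=count,
        scores=scores,
        per_tree=kept if keep_per_tree else None,
    )


@dataclass
class CompareReport:
    """Pairwise Pearson correlations among mean scores (and the mean pendant
    edge length) plus the taxa whose ranks differ most between score pairs."""

    correlations: pd.DataFrame
    outliers: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def r(self, a: str, b: str) -> float:
        return float(self.correlations.loc[a, b])


def compare_report(result: BatchResult, top_k: int = 5) -> CompareReport:
    """Correlation structure of a batch's mean scores.

    Needs at least two value columns and at least 3 taxa (correlation is
    degenerate below that).  Outliers are ranked by absolute rank difference
    between each pair of scores.
    """
    df = result.means
    if df.shape[1] < 2:
        raise ValidationError("compare_report needs at least two score columns")
    if df.shape[0] < 3:
        raise ValidationError("correlations need at least 3 taxa")
    corr = df.corr(method="pearson")
    ranks = df.rank()
    outliers: dict[tuple[str, str], pd.DataFrame] = {}
    cols = list(df.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            diff = (ranks[a] - ranks[b]).abs().sort_values(ascending=False)
            top = diff.head(top_k)
            outliers[(a, b)] = pd.DataFrame(
                {
                    "rank_diff": top,
                    a: df.loc[top.index, a],
                    b: df.loc[top.index, b],
                }
            )
    return CompareReport(corr, outliers)
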