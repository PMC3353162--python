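"""Extinction probabilities from IUCN Red List categories.

The five indicative categories (CR, EN, VU, NT, LC) are translated to
probabilities of extinction through a named value set.  Two standard sets
are built in:

* ``isaac``  — 0.4 / 0.2 / 0.1 / 0.05 / 0.025 (risk doubles with each rank);
* ``iucn100`` — 0.999 / 0.667 / 0.1 / 0.01 / 0.0001.

Data-deficient (DD) taxa can be imputed with the weighted mean of the mapped
taxa, pinned to a chosen category, or given a fixed value.  Extinct and
extinct-in-the-wild codes are rejected: prune those tips instead of scoring
them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import TaxonSetError, ValidationError

__all__ = [
    "CATEGORIES",
    "CategoryValueSet",
    "ExtinctionMap",
    "builtin_value_set",
    "map_categories",
    "read_status_table",
    "combine_runs",
]

CATEGORIES = ("CR", "EN", "VU", "NT", "LC")
_REJECTED = {"EX", "EW"}


@dataclass(frozen=True)
class CategoryValueSet:
    """Probability of extinction per indicative IUCN category; values must
    strictly decrease from CR down to LC and lie in (0, 1]."""

    name: str
    values: dict[str, float]

    def __post_init__(self):
        missing = [c for c in CATEGORIES if c not in self.values]
        if missing:
            raise ValidationError(f"value set {self.name!r} missing {missing}")
        seq = [self.values[c] for c in CATEGORIES]
        if any(not (0.0 < v <= 1.0) for v in seq):
            raise ValidationError("category values must lie in (0, 1]")
        if any(later >= earlier for earlier, later in zip(seq, seq[1:])):
            raise ValidationError(
                "category values must strictly decrease from CR to LC"
            )

    def __getitem__(self, category: str) -> float:
        return self.values[category.upper()]


_BUILTIN = {
    "isaac": CategoryValueSet(
        "isaac", {"CR": 0.4, "EN": 0.2, "VU": 0.1, "NT": 0.05, "LC": 0.025}
    ),
    "iucn100": CategoryValueSet(
        "iucn100", {"CR": 0.999, "EN": 0.667, "VU": 0.1, "NT": 0.01, "LC": 0.0001}
    ),
}


def builtin_value_set(name: str) -> CategoryValueSet:
    """One of the built-in category value sets (``isaac`` or ``iucn100``)."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown value set {name!r}; valid names: {sorted(_BUILTIN)}"
        ) from None


@dataclass
class ExtinctionMap:
    """Per-taxon probability of extinction with provenance.

    ``provenance[x]`` is one of ``direct``, ``category:<C>`` or
    ``dd-imputed``; ``value_set_name`` records which category value set (if
    any) produced the probabilities.
    """

    probs: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)
    value_set_name: str = "custom"

    def __post_init__(self):
        bad = [t for t, v in self.probs.items() if not (0.0 <= float(v) <= 1.0)]
        if bad:
            raise ValidationError(f"probabilities outside [0, 1] for: {bad}")
        self.probs = {t: float(v) for t, v in self.probs.items()}
        if not self.provenance:
            self.provenance = {t: "direct" for t in self.probs}

    def __getitem__(self, taxon: str) -> float:
        return self.probs[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.probs

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.probs)

    def positive_taxa(self) -> tuple[str, ...]:
        """Taxa with strictly positive extinction probability."""
        return tuple(t for t, v in self.probs.items() if v > 0.0)

    def check_covers(self, taxa) -> None:
        missing = [t for t in taxa if t not in self.probs]
        if missing:
            raise TaxonSetError(f"no extinction probability for taxa: {missing}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.probs, name="p", dtype=float).rename_axis("taxon")

    @classmethod
    def uniform(cls, taxa, p: float) -> "ExtinctionMap":
        return cls({t: p for t in taxa})

    @classmethod
    def from_probabilities(cls, probs: Mapping[str, float]) -> "ExtinctionMap":
        return cls(dict(probs))


def _parse_dd_policy(policy, value_set: CategoryValueSet):
    """Returns a function mapping the list of non-DD probabilities to the
    value assigned to every DD taxon."""
    if isinstance(policy, (int, float)):
        policy = f"fixed:{policy}"
    policy = str(policy)
    if policy == "weighted_mean":
        def impute(non_dd: list[float]) -> float:
            if not non_dd:
                raise ValidationError(
                    "weighted_mean imputation needs at least one non-DD taxon"
                )
            return sum(non_dd) / len(non_dd)
        return impute
    if policy.startswith("as_category:"):
        cat = policy.split(":", 1)[1].upper()
        if cat not in CATEGORIES:
            raise ValidationError(
                f"as_category policy needs one of {CATEGORIES}, got {cat!r}"
            )
        return lambda non_dd: value_set[cat]
    if policy.startswith("fixed:"):
        v = float(policy.split(":", 1)[1])
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"fixed DD value must be in [0, 1], got {v}")
        return lambda non_dd: v
    raise ValidationError(
        f"unknown DD policy {policy!r}; use 'weighted_mean', "
        "'as_category:<C>' or 'fixed:<v>'"
    )


def map_categories(
    status: Mapping[str, str],
    value_set: CategoryValueSet | str,
    dd_policy="weighted_mean",
) -> ExtinctionMap:
    """Map per-taxon IUCN category codes to extinction probabilities.

    ``dd_policy`` decides what data-deficient taxa receive: the (count-)
    weighted mean of all mapped taxa, a chosen category's value
    (``"as_category:NT"``), or a fixed number (``"fixed:0.07"``).
    """
    if isinstance(value_set, str):
        value_set = builtin_value_set(value_set)
    impute = _parse_dd_policy(dd_policy, value_set)
    probs: dict[str, float] = {}
    provenance: dict[str, str] = {}
    dd: list[str] = []
    non_dd_values: list[float] = []
    for taxon, code in status.items():
        c = str(code).strip().upper()
        if c in _REJECTED:
            raise ValidationError(
                f"taxon {taxon!r} has category {c}: extinct taxa are not "
                "scored; prune those tips from the tree instead"
            )
        if c == "DD":
            dd.append(taxon)
            probs[taxon] = -1.0  # placeholder, filled below
            continue
        if c not in CATEGORIES:
            raise ValidationError(
                f"taxon {taxon!r} has unknown category code {code!r}"
            )
        v = value_set[c]
        probs[taxon] = v
        provenance[taxon] = f"category:{c}"
        non_dd_values.append(v)
    if dd:
        v = impute(non_dd_values)
        for taxon in dd:
            probs[taxon] = v
            provenance[taxon] = "dd-imputed"
    return ExtinctionMap(probs, provenance, value_set.name)


def read_status_table(source) -> pd.DataFrame:
    """Read a delimited status table (TSV/CSV, ``#`` comments) with columns
    ``taxon`` and either ``category`` or ``p``.  Returns the cleaned frame;
    feed it to :func:`status_to_map`."""
    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "taxon" not in df.columns or not ({"category", "p"} & set(df.columns)):
        raise ValidationError(
            "status table needs a 'taxon' column and a 'category' or 'p' column"
        )
    df["taxon"] = df["taxon"].astype(str).str.strip()
    if df["taxon"].duplicated().any():
        dup = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValidationError(f"duplicate taxa in status table: {dup}")
    return df


def status_to_map(
    df: pd.DataFrame, value_set="isaac", dd_policy="weighted_mean"
) -> ExtinctionMap:
    """Build an :class:`ExtinctionMap` from a frame produced by
    :func:`read_status_table` (direct ``p`` column wins over categories)."""
    if "p" in df.columns:
        return ExtinctionMap.from_probabilities(
            dict(zip(df["taxon"], df["p"].astype(float)))
        )
    return map_categories(
        dict(zip(df["taxon"], df["category"])), value_set, dd_policy
    )


def combine_runs(tables):
    """Per-taxon arithmetic mean of score tables from runs that differ only
    in their extinction-probability assumptions (e.g. DD-as-NT vs DD-as-VU).
    Accepts Series or DataFrames over identical taxon sets."""
    tables = list(tables)
    if not tables:
        raise ValidationError("combine_runs needs at least one table")
    ref = tables[0]
    for i, t in enumerate(tables[1:], start=2):
        if set(t.index) != set(ref.index):
            raise TaxonSetError(
                f"table {i} has a different taxon set than table 1: "
                f"{sorted(set(t.index) ^ set(ref.index))}"
            )
    aligned = [t.reindex(ref.index) for t in tables]
    out = sum(aligned[1:], start=aligned[0].copy()) / len(aligned)
    return out
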