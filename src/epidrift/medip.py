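"""MeDIP tag-set analysis: thresholding, three-way Venn sections, heat-map
ordering.

A tag (one locus of the tiling array) is called methylation-enriched in a
group when its log2 precipitated/input peak ratio is strictly greater than
the threshold (default 2).  The called sets of three groups are decomposed
into the 7 disjoint Venn sections; the top-N tags of a reference group are
ordered with their ratios in the other groups for heat-map comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["call_tags", "venn_sections", "top_tags_matrix", "VennSections"]


@dataclass(frozen=True)
class VennSections:
    """Counts of the 7 disjoint sections of three sets, plus the union.

    Section keys are flag strings in group order: "100" = only the first
    group, "110" = first and second but not third, "111" = shared by all.
    """

    groups: tuple[str, str, str]
    counts: dict

    @property
    def union(self) -> int:
        return sum(self.counts.values())

    @property
    def triple(self) -> int:
        return self.counts["111"]

    def group_total(self, g) -> int:
        """Total tags of one group: the sum of its four sections."""
        i = self.groups.index(g)
        return sum(c for key, c in self.counts.items() if key[i] == "1")

    def shared_fraction(self) -> float:
        """Fraction of the union shared by all three groups."""
        u = self.union
        return self.triple / u if u else 0.0

    def as_dict(self) -> dict:
        d = {f"section_{k}": v for k, v in self.counts.items()}
        d["union"] = self.union
        d["shared_fraction"] = self.shared_fraction()
        for g in self.groups:
            d[f"total_{g}"] = self.group_total(g)
        return d


def call_tags(table: pd.DataFrame, threshold: float = 2.0) -> dict:
    """Per-group sets of tag ids with log2 ratio strictly above threshold.

    ``table`` is long-format with columns tag_id, group, log2_ratio.  A tag
    with a missing (NaN) ratio for a group is excluded from that group's
    set with a warning.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    missing = table.log2_ratio.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} tag/group ratios missing; those tags are "
            "excluded from the affected group's set"
        )
    called = table[~missing & (table.log2_ratio > threshold)]
    sets = {g: set() for g in pd.unique(table.group)}
    for g, sub in called.groupby("group", observed=True):
        sets[g] = set(sub.tag_id)
    return sets


def venn_sections(sets: dict) -> VennSections:
    """Decompose three tag-id sets into their 7 disjoint Venn sections."""
    if len(sets) != 3:
        raise ValueError("exactly three sets are required")
    names = tuple(sets.keys())
    a, b, c = (sets[n] for n in names)
    universe = a | b | c
    counts = {f"{i}{j}{k}": 0 for i in "01" for j in "01" for k in "01"
              if (i, j, k) != ("0", "0", "0")}
    for t in universe:
        key = f"{int(t in a)}{int(t in b)}{int(t in c)}"
        counts[key] += 1
    return VennSections(groups=names, counts=counts)


def top_tags_matrix(
    table: pd.DataFrame, reference_group, n: int = 500
) -> pd.DataFrame:
    """The n tags with the highest log2 ratios in the reference group,
    with the corresponding ratios in every group.

    Rows are sorted by the reference group's ratio, descending; ties are
    broken by tag_id (lexicographic, ascending) for determinism.
    """
    wide = table.pivot_table(
        index="tag_id", columns="group", values="log2_ratio", aggfunc="first"
    )
    if reference_group not in wide.columns:
        raise ValueError(f"unknown reference group {reference_group!r}")
    if n > len(wide):
        raise ValueError(f"n={n} exceeds table size {len(wide)}")
    # stable sort on a lexicographically pre-sorted index breaks ties by tag_id
    order = wide.sort_index(kind="mergesort").sort_values(
        reference_group, ascending=False, kind="mergesort"
    )
    out = order.head(n)
    out.columns.name = None
    return out
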