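"""GO-category over/under-representation among significant selection tests.

For one foreground branch, each category is tested with a two-sided
Fisher exact test on the 2x2 table of (significant, non-significant) x
(in category, not in category) gene counts.  Branch-test results are
scanned separately for genes with significantly higher and lower dN/dS
than the background; branch-site results form a positive-selection
class.  BH correction is applied across the whole scan at FDR 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .selection_tests import TestRecord, bh_correct

__all__ = [
    "AnnotationMap",
    "ContingencyTable",
    "build_contingency",
    "fisher_exact_two_sided",
    "enrichment_scan",
    "CLASSES",
]

#: enrichment classes: branch-site positives, and branch tests split by direction
CLASSES = ("positive_selection", "higher_dNdS", "lower_dNdS")


@dataclass
class AnnotationMap:
    """Gene-to-category assignments plus readable category names."""

    gene_to_categories: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def categories(self) -> list[str]:
        cats = set()
        for cs in self.gene_to_categories.values():
            cats |= cs
        return sorted(cats)

    def genes_in(self, category: str) -> set[str]:
        return {g for g, cs in self.gene_to_categories.items() if category in cs}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=["gene_id", "category"],
            usecols=[0, 1], dtype=str,
        )
        mapping: dict[str, set[str]] = {}
        for row in frame.itertuples(index=False):
            mapping.setdefault(row.gene_id, set()).add(row.category)
        return cls(gene_to_categories=mapping)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene_id": g, "category": c}
            for g in sorted(self.gene_to_categories)
            for c in sorted(self.gene_to_categories[g])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


@dataclass
class ContingencyTable:
    """Counts (a, b; c, d) = (sig&in, sig&out; nonsig&in, nonsig&out)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _class_filter(records: list[TestRecord], cls: str) -> tuple[set[str], set[str]]:
    """Split a branch's gene universe into (class-significant, rest)."""
    if cls == "positive_selection":
        fam = [r for r in records if r.test_type == "branch_site"]
        sig = {r.gene_id for r in fam if r.significant}
    elif cls in ("higher_dNdS", "lower_dNdS"):
        want = "foreground_higher" if cls == "higher_dNdS" else "foreground_lower"
        fam = [r for r in records if r.test_type == "branch"]
        sig = {r.gene_id for r in fam if r.significant and r.direction == want}
    else:
        raise ValueError(f"unknown enrichment class {cls!r}")
    universe = {r.gene_id for r in fam}
    return sig, universe - sig


def build_contingency(
    category: str,
    records: list[TestRecord],
    annotations: AnnotationMap,
    cls: str = "positive_selection",
) -> ContingencyTable:
    """2x2 counts for one category on one branch's tested gene universe.

    ``records`` must all share one foreground.  For the directional
    branch-test classes, a gene significant in the *other* direction
    counts as non-significant here.  An unannotated category simply
    yields zero in-category cells.
    """
    foregrounds = {r.foreground for r in records}
    if len(foregrounds) > 1:
        raise ValueError(f"records span several foregrounds: {sorted(foregrounds)}")
    sig, nonsig = _class_filter(records, cls)
    in_cat = annotations.genes_in(category)
    return ContingencyTable(
        a=len(sig & in_cat),
        b=len(sig - in_cat),
        c=len(nonsig & in_cat),
        d=len(nonsig - in_cat),
    )


def fisher_exact_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact test (minimum-likelihood rule).

    The p-value sums hypergeometric probabilities of all tables with the
    same margins that are no more probable than the observed one — the
    convention of the statistical environment this reproduces.  The odds
    ratio is the sample value ad/bc (inf or NaN for zero cells).
    """
    if table.total == 0:
        raise ValueError("all-zero contingency table")
    oddsratio, p = fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(oddsratio), float(p)


def enrichment_scan(
    categories: list[str],
    records: list[TestRecord],
    annotations: AnnotationMap,
    fdr: float = 0.05,
    classes: tuple[str, ...] = CLASSES,
    per_class_correction: bool = False,
) -> pd.DataFrame:
    """Fisher-exact over/under-representation scan with BH control.

    One row per (category, class); ``direction`` is called from the odds
    ratio's side.  BH is applied across all rows of the scan by default
    (per class when ``per_class_correction``).  Significance tiers mirror
    common rendering: p < 0.05 / 0.01 / 0.001, and p below the BH
    threshold q.
    """
    present = {r.test_type for r in records}
    rows = []
    for cls in classes:
        needed = "branch_site" if cls == "positive_selection" else "branch"
        if needed not in present:
            continue
        for cat in categories:
            table = build_contingency(cat, records, annotations, cls=cls)
            if table.total == 0:
                continue
            odds, p = fisher_exact_two_sided(table)
            if np.isnan(odds):
                direction = "none"
            elif odds > 1:
                direction = "over"
            elif odds < 1:
                direction = "under"
            else:
                direction = "none"
            rows.append(
                {
                    "category": cat,
                    "name": annotations.names.get(cat, ""),
                    "class": cls,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "odds_ratio": odds,
                    "direction": direction,
                    "p": p,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=["category", "name", "class", "a", "b", "c", "d",
                 "odds_ratio", "direction", "p"],
    )
    if frame.empty:
        frame["q"] = []
        frame["significant"] = []
        frame["tier"] = []
        return frame
    if per_class_correction:
        frame["q"] = np.nan
        frame["significant"] = False
        for cls in frame["class"].unique():
            mask = frame["class"] == cls
            q, sig = bh_correct(frame.loc[mask, "p"].tolist(), fdr=fdr)
            frame.loc[mask, "q"] = q
            frame.loc[mask, "significant"] = sig
    else:
        q, sig = bh_correct(frame["p"].tolist(), fdr=fdr)
        frame["q"] = q
        frame["significant"] = sig

    def tier(row):
        if row.significant:
            return "p<q"
        if row.p < 0.001:
            return "p<0.001"
        if row.p < 0.01:
            return "p<0.01"
        if row.p < 0.05:
            return "p<0.05"
        return ""

    frame["tier"] = frame.apply(tier, axis=1)
    return frame
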