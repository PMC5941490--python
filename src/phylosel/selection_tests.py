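"""Branch and branch-site likelihood-ratio tests with FDR control.

A branch test compares a single gene-wide dN/dS (one_ratio) against a
model granting the designated foreground branch its own dN/dS
(two_ratio).  A branch-site test compares model A's null (site classes
with omega <= 1) against the alternative that adds a class of sites with
omega2 >= 1 on the foreground branch.  Both LRT statistics are referred
to chi-square with 1 df, and p-values are corrected per foreground
branch and per test family with the Benjamini–Hochberg procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .codon_engine import fit_parameters
from .trees import PhyloTree

__all__ = [
    "TestRecord",
    "TestSummary",
    "branch_test",
    "branch_site_test",
    "lrt_pvalue",
    "lrt_statistic",
    "bh_correct",
    "correct_records",
    "summarize_tests",
    "records_to_frame",
    "summaries_to_frame",
]


@dataclass
class TestRecord:
    """One gene x foreground likelihood-ratio test."""

    __test__ = False  # not a pytest class, despite the name

    gene_id: str
    foreground: str
    test_type: str  # "branch" | "branch_site"
    lnL0: float
    lnL1: float
    lrt_stat: float
    p: float
    q: float = np.nan
    significant: bool = False
    direction: str = "not_applicable"  # foreground_higher | foreground_lower
    foreground_omega: float = np.nan
    background_omega: float = np.nan
    positive_fraction: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if self.lrt_stat < 0:
            raise ValueError("lrt_stat must be >= 0")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class TestSummary:
    """Per-foreground tallies in the style of a branch/branch-site summary table."""

    __test__ = False  # not a pytest class, despite the name

    foreground: str
    test_type: str
    n_tested: int
    n_significant: int
    n_foreground_higher: int
    n_foreground_lower: int
    pct_significant: float  # one-decimal rendering, e.g. 1.6
    pct_higher: int  # whole-number rendering, e.g. 75
    pct_lower: int
    median_foreground_omega: float
    median_background_omega: float
    n_unique_to_branch: int


def lrt_statistic(lnL0: float, lnL1: float) -> float:
    if not (np.isfinite(lnL0) and np.isfinite(lnL1)):
        raise ValueError("log-likelihoods must be finite")
    return max(0.0, 2.0 * (lnL1 - lnL0))


def lrt_pvalue(lnL0: float, lnL1: float, boundary_mixture: bool = False) -> float:
    """Upper-tail chi2(1 df) p-value of the LRT statistic 2*(lnL1 - lnL0).

    ``boundary_mixture=True`` uses the 50:50 point-mass/chi2_1 mixture
    appropriate when the alternative's extra parameter sits on a boundary
    (offered as an option; the chi2_1 reference is the default).
    """
    stat = lrt_statistic(lnL0, lnL1)
    p = float(chi2.sf(stat, df=1))
    if boundary_mixture:
        p = 1.0 if stat == 0 else 0.5 * p
    return min(p, 1.0)


def _direction(fg_omega: float, bg_omega: float) -> str:
    return "foreground_higher" if fg_omega > bg_omega else "foreground_lower"


def branch_test(
    alignment: CodonAlignment,
    tree: PhyloTree,
    foreground: str | Iterable[str],
    gene_id: str = "",
    *,
    n_starts: int = 3,
    seed: int = 0,
    return_fits: bool = False,
):
    """Gene-wide dN/dS shift test: one_ratio (null) vs two_ratio (alt)."""
    fg = tree.resolve_branch(foreground)
    null = fit_parameters(alignment, tree, "one_ratio", n_starts=n_starts, seed=seed)
    alt = fit_parameters(
        alignment, tree, "two_ratio", fg, n_starts=n_starts, seed=seed + 1, init=null
    )
    fg_w = alt.params.omega_map["FOREGROUND"]
    bg_w = alt.params.omega_map["BACKGROUND"]
    rec = TestRecord(
        gene_id=gene_id,
        foreground=fg,
        test_type="branch",
        lnL0=null.log_likelihood,
        lnL1=max(alt.log_likelihood, null.log_likelihood),
        lrt_stat=lrt_statistic(null.log_likelihood, max(alt.log_likelihood, null.log_likelihood)),
        p=lrt_pvalue(null.log_likelihood, alt.log_likelihood),
        direction=_direction(fg_w, bg_w),
        foreground_omega=fg_w,
        background_omega=bg_w,
        converged=null.converged and alt.converged,
    )
    return (rec, null, alt) if return_fits else rec


def branch_site_test(
    alignment: CodonAlignment,
    tree: PhyloTree,
    foreground: str | Iterable[str],
    gene_id: str = "",
    *,
    n_starts: int = 3,
    seed: int = 0,
    boundary_mixture: bool = False,
    return_fits: bool = False,
):
    """Episodic positive-selection test: model A null (omega2 = 1) vs alternative."""
    fg = tree.resolve_branch(foreground)
    null = fit_parameters(alignment, tree, "modelA_null", fg, n_starts=n_starts, seed=seed)
    alt = fit_parameters(
        alignment, tree, "modelA_alt", fg, n_starts=n_starts, seed=seed + 1, init=null
    )
    mix = alt.params.site_mixture
    rec = TestRecord(
        gene_id=gene_id,
        foreground=fg,
        test_type="branch_site",
        lnL0=null.log_likelihood,
        lnL1=max(alt.log_likelihood, null.log_likelihood),
        lrt_stat=lrt_statistic(null.log_likelihood, max(alt.log_likelihood, null.log_likelihood)),
        p=lrt_pvalue(null.log_likelihood, alt.log_likelihood, boundary_mixture=boundary_mixture),
        positive_fraction=mix.positive_fraction,
        converged=null.converged and alt.converged,
    )
    return (rec, null, alt) if return_fits else rec


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------


def bh_correct(
    pvalues: Sequence[float], fdr: float = 0.05, mode: str = "step_up"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg control at rate ``fdr``.

    Returns ``(q, significant)`` aligned with the input order, where
    ``q_i = (rank_i / m) * fdr`` is the rank-dependent threshold of p_i
    (ties broken by stable input order).  ``mode="step_up"`` rejects all
    p-values up to the largest rank k with p_(k) <= q_k (the canonical
    procedure); ``mode="rank_threshold"`` rejects exactly those tests with
    p_i strictly below their own threshold q_i.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = ranks / m * fdr
    if mode == "step_up":
        significant = multipletests(p, alpha=fdr, method="fdr_bh")[0]
    elif mode == "rank_threshold":
        significant = p < q
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'step_up' or 'rank_threshold'")
    return q, significant


def correct_records(
    records: list[TestRecord], fdr: float = 0.05, mode: str = "step_up"
) -> list[TestRecord]:
    """Apply BH independently within each (foreground, test family)."""
    out = list(records)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(out):
        groups.setdefault((rec.foreground, rec.test_type), []).append(i)
    for idx in groups.values():
        q, sig = bh_correct([out[i].p for i in idx], fdr=fdr, mode=mode)
        for j, i in enumerate(idx):
            out[i] = replace(out[i], q=float(q[j]), significant=bool(sig[j]))
    return out


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def _median_or_nan(values: list[float]) -> float:
    return float(np.median(values)) if values else np.nan


def summarize_tests(
    records: list[TestRecord],
    n_trees_tested: dict[str, int] | None = None,
) -> list[TestSummary]:
    """Tally significant tests per foreground (and per test family).

    ``n_trees_tested`` overrides the denominator (number of gene trees
    tested per foreground); by default it is the record count.  Direction
    splits and omega medians are taken over significant branch tests;
    ``n_unique_to_branch`` counts genes significant on no other
    foreground within the same test family.
    """
    out: list[TestSummary] = []
    families = sorted({(r.foreground, r.test_type) for r in records})
    sig_genes: dict[tuple[str, str], set[str]] = {
        fam: {r.gene_id for r in records if (r.foreground, r.test_type) == fam and r.significant}
        for fam in families
    }
    for fg, ttype in families:
        fam = [r for r in records if r.foreground == fg and r.test_type == ttype]
        sig = [r for r in fam if r.significant]
        higher = [r for r in sig if r.direction == "foreground_higher"]
        lower = [r for r in sig if r.direction == "foreground_lower"]
        n_tested = len(fam)
        if n_trees_tested and fg in n_trees_tested:
            n_tested = n_trees_tested[fg]
        others = set().union(
            *(genes for f, genes in sig_genes.items() if f[1] == ttype and f[0] != fg),
            set(),
        )
        unique = sum(1 for r in sig if r.gene_id not in others)
        pct_sig = round(100.0 * len(sig) / n_tested, 1) if n_tested else 0.0
        pct_hi = int(round(100.0 * len(higher) / len(sig))) if sig else 0
        pct_lo = int(round(100.0 * len(lower) / len(sig))) if sig else 0
        out.append(
            TestSummary(
                foreground=fg,
                test_type=ttype,
                n_tested=n_tested,
                n_significant=len(sig),
                n_foreground_higher=len(higher),
                n_foreground_lower=len(lower),
                pct_significant=pct_sig,
                pct_higher=pct_hi,
                pct_lower=pct_lo,
                median_foreground_omega=_median_or_nan(
                    [r.foreground_omega for r in sig if np.isfinite(r.foreground_omega)]
                ),
                median_background_omega=_median_or_nan(
                    [r.background_omega for r in sig if np.isfinite(r.background_omega)]
                ),
                n_unique_to_branch=unique,
            )
        )
    return out


def records_to_frame(records: list[TestRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summaries_to_frame(summaries: list[TestSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])
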