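"""Robustness of selection tests to alignment uncertainty.

Significant tests are re-evaluated over an ensemble of alternative
alignments of the same sequences — either externally supplied samples
(e.g. from a Bayesian joint alignment sampler) or internally generated
gap-shift perturbations — and judged by two criteria: a p-value below
0.05 on at least 95% of alignments, and an LRT statistic exceeding the
chi-square threshold implied by the test's original BH q-value on every
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import chi2, kendalltau

from .alignment import CodonAlignment
from .selection_tests import TestRecord, branch_site_test, branch_test
from .trees import PhyloTree

__all__ = [
    "AlignmentEnsemble",
    "RobustnessVerdict",
    "perturb_alignment",
    "make_ensemble",
    "load_ensemble",
    "robust_test",
    "kendall_concordance",
]


@dataclass
class AlignmentEnsemble:
    """Alternative alignments of one gene's (fixed) ungapped sequences."""

    gene_id: str
    alignments: list[CodonAlignment]
    source: str = "perturbed_internal"  # or "sampled_external"
    seed: int | None = None

    def __post_init__(self):
        if not self.alignments:
            raise ValueError("ensemble must contain at least one alignment")
        ref = self.alignments[0]
        for aln in self.alignments[1:]:
            if set(aln.taxa) != set(ref.taxa):
                raise ValueError("all ensemble alignments must share the same taxa")
            for taxon in ref.taxa:
                if aln.ungapped(taxon) != ref.ungapped(taxon):
                    raise ValueError(
                        f"{self.gene_id}: ungapped sequence of {taxon} differs "
                        "between ensemble members"
                    )


@dataclass
class RobustnessVerdict:
    """Outcome of re-testing one gene across an alignment ensemble."""

    gene_id: str
    foreground: str
    test_type: str
    n_alignments: int
    n_used: int  # converged re-tests (the denominator)
    frac_p_below_05: float
    passes_95pct: bool
    frac_p_below_05_strict: float  # non-converged counted as non-significant
    passes_95pct_strict: bool
    frac_lrt_above_q_threshold: float
    passes_q_criterion: bool  # every used alignment exceeds the q-implied LRT threshold
    original_q: float


def perturb_alignment(alignment: CodonAlignment, seed: int, max_shift: int = 2) -> CodonAlignment:
    """Jitter gap placement while preserving every row's ungapped sequence.

    Each contiguous gap block (in codon units) slides left or right by
    0..``max_shift`` codons, chosen uniformly, independently per row —
    a cheap stand-in for alignment uncertainty concentrated around
    indels.  Ungapped alignments are returned unchanged; the output is a
    deterministic function of (alignment, seed).
    """
    rng = np.random.default_rng(seed)
    new_rows = []
    for row in alignment.rows:
        units = [row[i : i + 3] for i in range(0, len(row), 3)]
        is_gap = [all(ch in "-." for ch in u) for u in units]
        blocks = []
        i = 0
        while i < len(units):
            if is_gap[i]:
                j = i
                while j < len(units) and is_gap[j]:
                    j += 1
                blocks.append((i, j))
                i = j
            else:
                i += 1
        prev_end = 0  # rightmost occupied position of the previous (moved) block
        for b, (start, end) in enumerate(blocks):
            shift = int(rng.integers(0, max_shift + 1))
            go_left = rng.random() < 0.5
            next_start = blocks[b + 1][0] if b + 1 < len(blocks) else len(units)
            if go_left:
                d = min(shift, start - prev_end)
                if d:
                    # rotate [start-d, end): the d codons jump past the block
                    units[start - d : end] = units[start:end] + units[start - d : start]
                prev_end = end - d
            else:
                d = min(shift, next_start - end)
                if d:
                    units[start : end + d] = units[end : end + d] + units[start:end]
                prev_end = end + d
        new_rows.append("".join(units))
    return CodonAlignment(list(alignment.taxa), new_rows)


def make_ensemble(
    alignment: CodonAlignment, gene_id: str, n: int = 100, seed: int = 0
) -> AlignmentEnsemble:
    """Internal perturbation ensemble of ``n`` gap-jittered alignments."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    alns = [perturb_alignment(alignment, int(s % (2**31 - 1))) for s in child_seeds]
    return AlignmentEnsemble(
        gene_id=gene_id, alignments=alns, source="perturbed_internal", seed=seed
    )


def load_ensemble(directory: str | Path, gene_id: str) -> AlignmentEnsemble:
    """Load an external ensemble from ``<dir>/<gene>.<k>.fasta`` files."""
    directory = Path(directory)
    paths = sorted(
        directory.glob(f"{gene_id}.*.fasta"),
        key=lambda p: int(p.name.split(".")[-2]),
    )
    if not paths:
        raise FileNotFoundError(f"no {gene_id}.<k>.fasta files under {directory}")
    alns = [CodonAlignment.from_fasta(p) for p in paths]
    return AlignmentEnsemble(gene_id=gene_id, alignments=alns, source="sampled_external")


def robust_test(
    ensemble: AlignmentEnsemble,
    tree: PhyloTree,
    foreground: str,
    test_type: str,
    original_q: float,
    *,
    alpha: float = 0.05,
    frac_required: float = 0.95,
    n_starts: int = 1,
    seed: int = 0,
    cache: dict | None = None,
) -> tuple[RobustnessVerdict, list[TestRecord]]:
    """Re-run one test across an alignment ensemble and apply both
    robustness criteria.

    Non-converged re-tests are excluded from the main denominator (and
    logged in the verdict); the strict variant counts them as
    non-significant.  ``cache`` (keyed by alignment content) lets
    ensembles with repeated alignments avoid refitting.
    """
    if test_type not in ("branch", "branch_site"):
        raise ValueError("test_type must be 'branch' or 'branch_site'")
    runner = branch_test if test_type == "branch" else branch_site_test
    lrt_threshold = float(chi2.isf(original_q, df=1)) if 0 < original_q < 1 else np.inf
    records: list[TestRecord] = []
    cache = cache if cache is not None else {}
    for i, aln in enumerate(ensemble.alignments):
        key = (aln.content_key(), test_type, foreground)
        rec = cache.get(key)
        if rec is None:
            rec = runner(
                aln, tree, foreground, gene_id=ensemble.gene_id,
                n_starts=n_starts, seed=seed + i,
            )
            cache[key] = rec
        records.append(rec)
    used = [r for r in records if r.converged]
    n_used = len(used)
    n_below = sum(1 for r in used if r.p < alpha)
    frac = n_below / n_used if n_used else np.nan
    frac_strict = n_below / len(records)
    above = [r.lrt_stat > lrt_threshold for r in used]
    frac_above = float(np.mean(above)) if used else np.nan
    verdict = RobustnessVerdict(
        gene_id=ensemble.gene_id,
        foreground=foreground,
        test_type=test_type,
        n_alignments=len(records),
        n_used=n_used,
        frac_p_below_05=float(frac),
        passes_95pct=bool(n_used and frac >= frac_required),
        frac_p_below_05_strict=float(frac_strict),
        passes_95pct_strict=bool(frac_strict >= frac_required),
        frac_lrt_above_q_threshold=frac_above,
        passes_q_criterion=bool(used and all(above)),
        original_q=original_q,
    )
    return verdict, records


def kendall_concordance(x, y) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with a two-sided p-value.

    Used to compare two estimators of the proportion of positively
    selected sites across genes.  Returns (nan, nan) when either input
    is constant (tau undefined).  Exact p-values are used for small
    tie-free samples, the normal approximation otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)
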