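"""Ortholog quality control before selection testing.

Codon alignments are rebuilt from protein alignments and coding
sequences, orthogroups are restricted to exactly one sequence per
species, gene trees must match the species-tree topology, and
contaminant or paralogous sequences are flagged by their minimum
patristic distance on the dS-scaled gene tree: a Beta distribution is
fitted (method of moments) to the pooled minimum-dS values, and any
sequence beyond its 99th percentile is removed, excluding its gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from scipy.stats import beta as beta_dist

from .alignment import CodonAlignment, GAP_CHARS
from .trees import PhyloTree, topology_equal

__all__ = [
    "Orthogroup",
    "DistanceReport",
    "map_codons",
    "single_copy_groups",
    "topology_matches",
    "min_patristic_ds",
    "beta_outlier_filter",
    "quality_subset",
]


@dataclass
class Orthogroup:
    """One gene cluster: per-species members, protein alignment, and CDS."""

    group_id: str
    members: dict[str, list[str]]  # species -> sequence ids
    protein_alignment: dict[str, str] = field(default_factory=dict)  # seq id -> gapped AA row
    cds: dict[str, str] = field(default_factory=dict)  # seq id -> ungapped coding sequence

    def species_counts(self) -> dict[str, int]:
        return {sp: len(ids) for sp, ids in self.members.items()}


@dataclass
class DistanceReport:
    """Outcome of the minimum-patristic-dS Beta percentile filter."""

    min_ds: dict[str, float]
    beta_alpha: float
    beta_beta: float
    cutoff: float
    removed: set[str]
    warning: str = ""


def map_codons(
    protein_alignment: dict[str, str], cds_map: dict[str, str]
) -> CodonAlignment:
    """Back-translate a gapped protein alignment into a codon alignment.

    Each residue is replaced by its source codon and each protein gap by
    a three-base gap, so the output is exactly three times the protein
    alignment length.  The ungapped CDS must translate (standard code) to
    the ungapped protein row; mismatches are reported by position.
    """
    taxa, rows = [], []
    for name, prot_row in protein_alignment.items():
        if name not in cds_map:
            raise KeyError(f"no coding sequence for {name!r}")
        cds = cds_map[name].upper().replace("U", "T")
        residues = [aa for aa in prot_row if aa not in GAP_CHARS]
        if len(cds) != 3 * len(residues):
            raise ValueError(
                f"{name}: CDS length {len(cds)} is not 3x residue count {len(residues)}"
            )
        translated = str(Seq(cds).translate())
        for i, (aa, ref) in enumerate(zip(translated, residues), start=1):
            if aa == "*":
                raise ValueError(f"{name}: internal stop codon at residue {i}")
            if aa.upper() != ref.upper() and ref.upper() != "X" and aa != "X":
                raise ValueError(
                    f"{name}: translation mismatch at residue {i}: {aa}!={ref}"
                )
        out = []
        k = 0
        for aa in prot_row:
            if aa in GAP_CHARS:
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        taxa.append(name)
        rows.append("".join(out))
    return CodonAlignment(taxa, rows)


def single_copy_groups(groups: list[Orthogroup], species: list[str]) -> list[Orthogroup]:
    """Keep groups with exactly one sequence from every listed species."""
    if not species:
        raise ValueError("species list must be non-empty")
    return [
        g
        for g in groups
        if all(len(g.members.get(sp, [])) == 1 for sp in species)
        and all(sp in species for sp in g.members if g.members[sp])
    ]


def topology_matches(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    taxon_map: dict[str, str] | None = None,
) -> bool:
    """True iff the gene tree induces the species tree's bipartitions.

    ``taxon_map`` maps sequence ids on the gene tree to species names.
    Branch lengths and rooting are ignored.
    """
    return topology_equal(gene_tree, species_tree, taxon_map=taxon_map)


def min_patristic_ds(tree: PhyloTree) -> dict[str, float]:
    """Minimum patristic distance to any other leaf, on a dS-scaled tree."""
    names = tree.leaf_names
    if len(names) < 2:
        raise ValueError("need at least two leaves for patristic distances")
    for bid, length in tree.branch_lengths.items():
        if length < 0:
            raise ValueError(f"negative dS on branch {bid}")
    order, mat = tree.patristic_matrix()
    np.fill_diagonal(mat, np.inf)
    return {name: float(mat[i].min()) for i, name in enumerate(order)}


def beta_outlier_filter(
    min_ds_values: dict[str, float], percentile: float = 0.99
) -> DistanceReport:
    """Flag nearest-neighbour dS outliers against a moment-fitted Beta.

    Values >= 1 lie outside the Beta support and are exactly the gross
    contamination the filter targets: they are removed up front and
    excluded from moment estimation.  The Beta shape parameters come from
    the sample mean m and variance v, ``alpha = m(m(1-m)/v - 1)`` and
    ``beta = (1-m)(m(1-m)/v - 1)``; values strictly above the
    ``percentile`` quantile of that Beta are removed.
    """
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    if len(min_ds_values) < 2:
        raise ValueError("need at least two values to fit a Beta")
    names = sorted(min_ds_values)
    values = np.array([min_ds_values[n] for n in names], dtype=float)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError("min dS values must be finite and non-negative")

    gross = {n for n, v in min_ds_values.items() if v >= 1.0}
    body = values[values < 1.0]
    if body.size < 2:
        return DistanceReport(
            min_ds=dict(min_ds_values),
            beta_alpha=np.nan,
            beta_beta=np.nan,
            cutoff=np.nan,
            removed=gross,
            warning="fewer than two values below 1; Beta not fitted",
        )
    m = float(body.mean())
    v = float(body.var(ddof=1))
    if v < 1e-12:
        return DistanceReport(
            min_ds=dict(min_ds_values),
            beta_alpha=np.nan,
            beta_beta=np.nan,
            cutoff=np.nan,
            removed=gross,
            warning="zero variance in min dS values; no percentile outliers flagged",
        )
    if not (0.0 < m < 1.0):
        raise ValueError(
            f"mean min-dS {m:.4f} outside (0,1); rescale distances or use the "
            "gross (>=1) removal alone"
        )
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        return DistanceReport(
            min_ds=dict(min_ds_values),
            beta_alpha=np.nan,
            beta_beta=np.nan,
            cutoff=np.nan,
            removed=gross,
            warning="variance too large for a Beta moment fit; only >=1 values removed",
        )
    alpha = m * common
    bshape = (1.0 - m) * common
    cutoff = float(beta_dist.ppf(percentile, alpha, bshape))
    removed = gross | {n for n, v_ in min_ds_values.items() if v_ > cutoff}
    return DistanceReport(
        min_ds=dict(min_ds_values),
        beta_alpha=alpha,
        beta_beta=bshape,
        cutoff=cutoff,
        removed=removed,
    )


def quality_subset(
    depths: np.ndarray, phreds: np.ndarray, min_depth: int = 20, min_phred: int = 14
) -> bool:
    """True iff every site of the focal sequence has depth >= 20 and
    phred >= 14 (the high-accuracy orthogroup subset rule)."""
    depths = np.asarray(depths)
    phreds = np.asarray(phreds)
    if depths.size == 0 or phreds.size == 0:
        raise ValueError("depth and phred tracks must cover the sequence")
    if depths.shape != phreds.shape:
        raise ValueError("depth and phred tracks differ in length")
    return bool(depths.min() >= min_depth and phreds.min() >= min_phred)
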