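"""Heterozygosity, PSMC-input preparation, and whole-genome window statistics.

Site calls are 1-based diploid positions with per-allele read depths.
The heterozygosity filters follow the study design this package
reimplements: bi-allelic sites with depth >= 20, base quality >= 20 and
minor-allele read fraction >= 0.1, restricted to autosomes (a PSMC
variant uses depth bounds 10–50, or 15–70 for a deeper genome).  Bins of
100 bp are compressed to K/T/N characters for PSMC input, segments are
capped at 10,000 bins, and PSMC-scaled output is converted to years and
Ne with mu = 1.91e-9 per year and a one-year generation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCall",
    "ChromHetSummary",
    "PsmcfaRecord",
    "FilterReport",
    "filter_sites",
    "het_per_kb",
    "false_positive_rate",
    "make_psmcfa",
    "write_psmcfa",
    "read_psmcfa",
    "scale_time",
    "window_stats",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_vcf_sites",
    "write_vcf_sites",
    "read_bed",
]

DEFAULT_SEX_CHROMS = frozenset({"Z", "W", "chrZ", "chrW"})
DEFAULT_MU_PER_YEAR = 1.91e-9
DEFAULT_GEN_YEARS = 1.0


@dataclass
class SiteCall:
    """One diploid position: alleles with read depths, total depth, quality."""

    chrom: str
    pos: int  # 1-based
    alleles: list[tuple[str, int]]
    total_depth: int
    base_quality: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if any(d < 0 for _, d in self.alleles):
            raise ValueError("allele depths must be >= 0")
        if sum(d for _, d in self.alleles) > self.total_depth:
            raise ValueError("allele depths exceed total depth")


@dataclass
class ChromHetSummary:
    chrom: str
    callable_bases: int
    het_bases: int

    @property
    def het_per_kb(self) -> float:
        return 1000.0 * self.het_bases / self.callable_bases


@dataclass
class PsmcfaRecord:
    """One PSMC input segment: one K/T/N character per 100 bp bin."""

    name: str
    bins: str

    def __post_init__(self):
        if set(self.bins) - set("KTN"):
            raise ValueError("bins must be over the alphabet {K, T, N}")


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    n_not_biallelic: int = 0
    n_depth: int = 0
    n_quality: int = 0
    n_maf: int = 0
    n_unmapped_scaffold: int = 0
    n_sex_chrom: int = 0


def filter_sites(
    sites: list[SiteCall],
    min_depth: int = 20,
    max_depth: int | None = None,
    min_qual: int = 20,
    min_maf: float = 0.1,
    chrom_map: dict[str, str] | None = None,
    autosomes_only: bool = False,
    sex_chroms: frozenset[str] = DEFAULT_SEX_CHROMS,
) -> tuple[list[SiteCall], FilterReport]:
    """Retain high-confidence heterozygous sites.

    A site passes iff it shows exactly two alleles with positive depth,
    total depth within ``[min_depth, max_depth]``, base quality at least
    ``min_qual`` and minor-allele read fraction at least ``min_maf``.
    With ``autosomes_only``, the scaffold must map (via ``chrom_map``) to
    a non-sex chromosome; unmapped scaffolds are dropped and counted.
    """
    if min_depth <= 0 or min_qual < 0:
        raise ValueError("thresholds must be positive")
    report = FilterReport(n_input=len(sites))
    kept: list[SiteCall] = []
    for site in sites:
        if autosomes_only:
            if chrom_map is not None:
                chrom = chrom_map.get(site.chrom)
                if chrom is None:
                    report.n_unmapped_scaffold += 1
                    continue
            else:
                chrom = site.chrom
            if chrom in sex_chroms:
                report.n_sex_chrom += 1
                continue
        observed = [(b, d) for b, d in site.alleles if d > 0]
        if len(observed) != 2:
            report.n_not_biallelic += 1
            continue
        if site.total_depth < min_depth or (
            max_depth is not None and site.total_depth > max_depth
        ):
            report.n_depth += 1
            continue
        if site.base_quality < min_qual:
            report.n_quality += 1
            continue
        minor = min(d for _, d in observed)
        if minor / site.total_depth < min_maf:
            report.n_maf += 1
            continue
        kept.append(site)
    report.n_retained = len(kept)
    return kept, report


def het_per_kb(
    het_sites: list[SiteCall], callable_lengths: dict[str, int]
) -> tuple[list[ChromHetSummary], ChromHetSummary]:
    """Heterozygous bases per kilobase, per chromosome and pooled."""
    for chrom, length in callable_lengths.items():
        if length <= 0:
            raise ValueError(f"callable length for {chrom} must be > 0")
    counts: dict[str, int] = {c: 0 for c in callable_lengths}
    for site in het_sites:
        if site.chrom not in counts:
            raise KeyError(f"het site on {site.chrom} with no callable length")
        counts[site.chrom] += 1
    per_chrom = [
        ChromHetSummary(chrom=c, callable_bases=callable_lengths[c], het_bases=counts[c])
        for c in sorted(callable_lengths)
    ]
    total = ChromHetSummary(
        chrom="genome",
        callable_bases=sum(callable_lengths.values()),
        het_bases=sum(counts.values()),
    )
    return per_chrom, total


def false_positive_rate(
    calls: list[SiteCall] | set[tuple[str, int]],
    truth_regions: list[tuple[str, int, int]],
    truth_het_positions: set[tuple[str, int]],
) -> float:
    """Percent of truth-homozygous positions called heterozygous.

    ``truth_regions`` are 0-based half-open intervals with fully known
    genotypes (e.g. Sanger-sequenced introns); ``truth_het_positions``
    are the genuinely heterozygous (chrom, 1-based pos) pairs inside
    them.  Returns NaN when the truth set contains no homozygous
    position overlapping the calls' coordinate space.
    """
    if isinstance(calls, set):
        called = calls
    else:
        called = {(c.chrom, c.pos) for c in calls}
    n_hom = 0
    n_false = 0
    for chrom, start, end in truth_regions:
        for pos in range(start + 1, end + 1):  # 1-based positions in the interval
            if (chrom, pos) in truth_het_positions:
                continue
            n_hom += 1
            if (chrom, pos) in called:
                n_false += 1
    if n_hom == 0:
        return float("nan")
    return 100.0 * n_false / n_hom


# --------------------------------------------------------------------------
# PSMC input
# --------------------------------------------------------------------------


def make_psmcfa(
    het_sites: list[SiteCall],
    sequence_lengths: dict[str, int],
    bin_size: int = 100,
    max_bins_per_segment: int = 10_000,
    missing_mask: dict[str, list[tuple[int, int]]] | None = None,
) -> list[PsmcfaRecord]:
    """Compress per-site heterozygosity into PSMC's K/T/N bin alphabet.

    Bin k covers 1-based positions ``(k-1)*bin_size+1 .. k*bin_size``; it
    is K if it contains at least one retained heterozygous site, N if
    more than 90% of its positions are masked as missing (a het call
    inside a fully masked bin still wins and is logged), and T
    otherwise.  A trailing partial bin is dropped, and chromosomes are
    split into records of at most ``max_bins_per_segment`` bins.
    """
    by_chrom: dict[str, list[int]] = {c: [] for c in sequence_lengths}
    for site in het_sites:
        if site.chrom not in sequence_lengths:
            raise KeyError(f"site on {site.chrom!r} with unknown sequence length")
        if site.pos > sequence_lengths[site.chrom]:
            raise ValueError(
                f"{site.chrom}:{site.pos} beyond length {sequence_lengths[site.chrom]}"
            )
        by_chrom[site.chrom].append(site.pos)

    records: list[PsmcfaRecord] = []
    for chrom in sorted(sequence_lengths):
        length = sequence_lengths[chrom]
        n_bins = length // bin_size  # trailing partial bin dropped
        if n_bins == 0:
            continue
        het_bins = np.zeros(n_bins, dtype=bool)
        for pos in by_chrom[chrom]:
            b = (pos - 1) // bin_size
            if b < n_bins:
                het_bins[b] = True
        masked = np.zeros(n_bins, dtype=np.int32)
        if missing_mask and chrom in missing_mask:
            cover = np.zeros(n_bins * bin_size, dtype=bool)
            for start, end in missing_mask[chrom]:
                cover[max(start, 0) : min(end, n_bins * bin_size)] = True
            masked = cover.reshape(n_bins, bin_size).sum(axis=1).astype(np.int32)
        n_flag = masked > 0.9 * bin_size
        overruled = int(np.sum(n_flag & het_bins))
        if overruled:
            logger.warning(
                "%s: %d heterozygous bin(s) inside masked regions kept as K", chrom, overruled
            )
        chars = np.where(het_bins, "K", np.where(n_flag, "N", "T"))
        full = "".join(chars)
        segments = [
            full[i : i + max_bins_per_segment]
            for i in range(0, len(full), max_bins_per_segment)
        ]
        for i, seg in enumerate(segments, start=1):
            name = chrom if len(segments) == 1 else f"{chrom}_{i}"
            records.append(PsmcfaRecord(name=name, bins=seg))
    return records


def write_psmcfa(records: list[PsmcfaRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.bins), id=r.name, description="") for r in records
    ]
    SeqIO.write(seq_records, path, "fasta")  # biopython wraps at 60 columns


def read_psmcfa(path: str | Path) -> list[PsmcfaRecord]:
    return [
        PsmcfaRecord(name=rec.id, bins=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def scale_time(
    times: np.ndarray,
    lambdas: np.ndarray,
    theta0: float,
    mu: float = DEFAULT_MU_PER_YEAR,
    gen_years: float = DEFAULT_GEN_YEARS,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Rescale PSMC-style coalescent-unit output to years and Ne.

    ``theta0`` is the per-bin scaled mutation rate reported by PSMC, so
    ``N0 = theta0 / (4 mu g bin_size)``; each interval then has
    ``Ne = N0 * lambda`` and ``years = 2 N0 t g``.
    """
    if mu <= 0 or gen_years <= 0:
        raise ValueError("mu and generation time must be positive")
    if theta0 <= 0:
        raise ValueError("theta0 must be positive")
    times = np.asarray(times, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    n0 = theta0 / (4.0 * mu * gen_years * bin_size)
    return pd.DataFrame(
        {"years": 2.0 * n0 * times * gen_years, "Ne": n0 * lambdas}
    )


# --------------------------------------------------------------------------
# 100-kb window statistics
# --------------------------------------------------------------------------


def window_stats(
    aligned: np.ndarray,
    mismatch: np.ndarray,
    gc_ref: np.ndarray,
    gc_query: np.ndarray,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-window alignment fraction, divergence and GC for a genome pair.

    Inputs are per-position boolean tracks over one chromosome (0-based):
    whether the position is covered by the pairwise alignment, whether it
    mismatches, and whether each genome shows G/C there.  Windows are
    half-open ``[k*window, (k+1)*window)``; divergence is mismatches per
    aligned base (gaps and missing data excluded) and NaN when a window
    has no aligned base.  GC is computed over aligned bases only.
    """
    aligned = np.asarray(aligned, dtype=bool)
    n = aligned.size
    for name, arr in (("mismatch", mismatch), ("gc_ref", gc_ref), ("gc_query", gc_query)):
        if np.asarray(arr).size != n:
            raise ValueError(f"{name} track length mismatch")
    idx = np.arange(n) // window
    n_win = int(idx[-1]) + 1 if n else 0
    denom = np.bincount(idx, minlength=n_win).astype(float)
    n_aligned = np.bincount(idx, weights=aligned, minlength=n_win)
    n_mis = np.bincount(idx, weights=np.asarray(mismatch, bool) & aligned, minlength=n_win)
    n_gc_r = np.bincount(idx, weights=np.asarray(gc_ref, bool) & aligned, minlength=n_win)
    n_gc_q = np.bincount(idx, weights=np.asarray(gc_query, bool) & aligned, minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        frame = pd.DataFrame(
            {
                "start": np.arange(n_win) * window,
                "end": np.minimum((np.arange(n_win) + 1) * window, n),
                "fraction_aligned": n_aligned / denom,
                "divergence": np.where(n_aligned > 0, n_mis / np.maximum(n_aligned, 1), np.nan),
                "gc_ref": np.where(n_aligned > 0, n_gc_r / np.maximum(n_aligned, 1), np.nan),
                "gc_query": np.where(n_aligned > 0, n_gc_q / np.maximum(n_aligned, 1), np.nan),
            }
        )
    return frame


# --------------------------------------------------------------------------
# IO: simple TSV site dialect and BED
# --------------------------------------------------------------------------


def write_sites_tsv(sites: list[SiteCall], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "alleles": ",".join(f"{b}:{d}" for b, d in s.alleles),
            "total_depth": s.total_depth,
            "base_quality": s.base_quality,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "alleles", "total_depth", "base_quality"]).to_csv(
        path, sep="\t", index=False
    )


def read_sites_tsv(path: str | Path) -> list[SiteCall]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sites = []
    for row in frame.itertuples(index=False):
        alleles = []
        for token in str(row.alleles).split(","):
            base, depth = token.split(":")
            alleles.append((base, int(depth)))
        sites.append(
            SiteCall(
                chrom=row.chrom,
                pos=int(row.pos),
                alleles=alleles,
                total_depth=int(row.total_depth),
                base_quality=int(row.base_quality),
            )
        )
    return sites


def write_vcf_sites(sites: list[SiteCall], path: str | Path) -> None:
    """Write calls as a minimal two-allele VCF (CHROM POS REF ALT QUAL DP/AD)."""
    chroms = sorted({s.chrom for s in sites})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample",
    ]
    for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
        observed = [(b, d) for b, d in s.alleles if d > 0] or s.alleles[:1]
        ref, ref_d = observed[0]
        alts = observed[1:] or [(".", 0)]
        alt_field = ",".join(b for b, _ in alts)
        ad = ",".join(str(d) for _, d in [observed[0]] + alts)
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{ref}\t{alt_field}\t{s.base_quality}\t.\t"
            f"DP={s.total_depth}\tAD\t{ad}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_sites(path: str | Path) -> list[SiteCall]:
    """Read the VCF subset (CHROM POS REF ALT QUAL, INFO/DP, FORMAT/AD)."""
    import pysam

    sites: list[SiteCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[next(iter(rec.samples))] if rec.samples else None
            ad = sample["AD"] if sample is not None and "AD" in sample else None
            bases = [rec.ref] + [a for a in (rec.alts or []) if a not in (None, ".")]
            if ad is None:
                ad = [0] * len(bases)
            alleles = [(b, int(d)) for b, d in zip(bases, ad)]
            depth = int(rec.info.get("DP", sum(d for _, d in alleles)))
            qual = int(rec.qual) if rec.qual is not None else 0
            sites.append(
                SiteCall(
                    chrom=rec.chrom, pos=rec.pos, alleles=alleles,
                    total_depth=depth, base_quality=qual,
                )
            )
    return sites


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    frame = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    return [(r.chrom, int(r.start), int(r.end)) for r in frame.itertuples(index=False)]
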