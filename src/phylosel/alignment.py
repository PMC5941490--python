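"""In-frame codon alignments and their FASTA/PHYLIP IO."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import encode_codon

GAP_CHARS = set("-.")


@dataclass
class CodonAlignment:
    """A gapped, in-frame codon alignment.

    ``rows[i]`` is the gapped nucleotide sequence of ``taxa[i]``; all rows
    have equal length, a multiple of three.  Every non-gap triplet must be
    a sense codon or an ambiguity (treated as missing); internal stop
    codons are rejected at construction.
    """

    taxa: list[str]
    rows: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if not self.rows:
            raise ValueError("empty alignment")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("rows have unequal lengths")
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        self.rows = [r.upper() for r in self.rows]
        self._codes = None
        self.codes()  # validates: raises on internal stop codons

    @property
    def site_count(self) -> int:
        """Number of codon columns."""
        return len(self.rows[0]) // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codes(self) -> np.ndarray:
        """(n_taxa, site_count) int matrix of sense-codon states; -1 = missing."""
        if self._codes is None:
            mat = np.empty((self.n_taxa, self.site_count), dtype=np.int16)
            for i, row in enumerate(self.rows):
                for s in range(self.site_count):
                    codon = row[3 * s : 3 * s + 3]
                    if set(codon) & GAP_CHARS:
                        mat[i, s] = -1
                    else:
                        try:
                            mat[i, s] = encode_codon(codon)
                        except ValueError as exc:
                            raise ValueError(
                                f"{self.taxa[i]} codon site {s + 1}: {exc}"
                            ) from exc
            self._codes = mat
        return self._codes

    def ungapped(self, taxon: str) -> str:
        row = self.rows[self.taxa.index(taxon)]
        return "".join(ch for ch in row if ch not in GAP_CHARS)

    def subset_taxa(self, names: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(n) for n in names]
        return CodonAlignment(list(names), [self.rows[i] for i in idx])

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_fasta(cls, source: str | Path | io.TextIOBase) -> "CodonAlignment":
        records = list(SeqIO.parse(source, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {source!r}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    @classmethod
    def from_phylip(cls, source: str | Path | io.TextIOBase) -> "CodonAlignment":
        aln = AlignIO.read(source, "phylip-relaxed")
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    def to_fasta(self, path: str | Path | io.TextIOBase) -> None:
        records = [
            SeqRecord(Seq(row), id=name, description="")
            for name, row in zip(self.taxa, self.rows)
        ]
        SeqIO.write(records, path, "fasta")

    def content_key(self) -> tuple:
        """Hashable identity of the alignment content (used for fit caching)."""
        return tuple(zip(self.taxa, self.rows))
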