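"""Standard genetic code and codon bookkeeping for dN/dS machinery.

The 61 sense codons of the standard nuclear code are the state space of
every codon substitution model in this package.  Codons are indexed in
lexicographic order (AAA, AAC, ...) with the three stop codons removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: unordered pairs that differ by a purine<->purine or pyrimidine<->pyrimidine change
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code restricted to its 61 sense codons.

    Attributes
    ----------
    table:
        Map from codon string to one-letter amino acid, with ``"*"`` for
        the three stop codons.
    sense_codons:
        The 61 non-stop codons, lexicographically ordered; their position
        in this list is the integer state used throughout the likelihood
        engine.
    """

    table: dict[str, str]
    sense_codons: tuple[str, ...]
    codon_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if len(self.sense_codons) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(self.sense_codons)}")
        if not self.codon_index:
            object.__setattr__(
                self, "codon_index", {c: i for i, c in enumerate(self.sense_codons)}
            )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa == "*")

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.table[c1] == self.table[c2]


def standard_code() -> GeneticCode:
    """Build the standard nuclear code from Biopython's table 1."""
    bio = CodonTable.unambiguous_dna_by_id[1]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = "*"
    # fill any codon biopython leaves implicit (none for table 1, but be safe)
    for codon in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)):
        table.setdefault(codon, "*")
    sense = tuple(c for c in sorted(table) if table[c] != "*")
    return GeneticCode(table=table, sense_codons=sense)


STANDARD_CODE = standard_code()
N_SENSE = 61


@lru_cache(maxsize=1)
def codon_change_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute the 61x61 structure of single-nucleotide codon changes.

    Returns ``(single, transition, synonymous)`` boolean matrices over the
    sense-codon state space: whether codons i and j differ at exactly one
    position, whether that change is a transition, and whether it is
    synonymous.  Multi-nucleotide changes are False in all three.
    """
    code = STANDARD_CODE
    n = N_SENSE
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            synonymous[i, j] = code.is_synonymous(ci, cj)
    return single, transition, synonymous


def encode_codon(codon: str) -> int:
    """Map a codon string to its sense-codon state, or -1 for missing data.

    Gapped or ambiguous codons (any character outside ACGT) are treated as
    fully missing.  Stop codons raise, since in-frame coding sequence must
    not contain internal stops.
    """
    codon = codon.upper().replace("U", "T")
    if any(ch not in NUCLEOTIDES for ch in codon):
        return -1
    idx = STANDARD_CODE.codon_index.get(codon)
    if idx is None:
        raise ValueError(f"internal stop codon {codon!r}")
    return idx
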