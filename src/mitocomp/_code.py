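"""Invertebrate mitochondrial genetic code (NCBI translation table 5).

All codon-level statistics in this package are computed under table 5:
UGA encodes Trp, AGA/AGG encode Ser, AUA encodes Met, and only UAA/UAG
are stop codons, leaving 62 sense codons.

Synonymous families follow the field convention of splitting the 8-codon
serine family into its UCN and AGN halves (they are not interconvertible
by a single third-position change and are conventionally reported
separately), which leaves a single 6-fold family (Leu), eight 4-fold
families and twelve 2-fold families — 21 families in total.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

TABLE_ID = 5
_TABLE = unambiguous_dna_by_id[TABLE_ID]

#: codon (DNA, upper) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

BASES = "ACGT"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMP)[::-1]


def family_of(codon: str) -> str:
    """Synonymous-family label of a sense codon (Ser split into S_UCN/S_AGN)."""
    aa = CODON_TO_AA[codon]
    if aa == "S":
        return "S_AGN" if codon.startswith("AG") else "S_UCN"
    return aa


@lru_cache(maxsize=1)
def synonymous_families() -> dict[str, tuple[str, ...]]:
    """family label -> sorted tuple of its sense codons."""
    fams: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        fams.setdefault(family_of(codon), []).append(codon)
    return {f: tuple(sorted(c)) for f, c in fams.items()}


@lru_cache(maxsize=1)
def degeneracy_classes() -> dict[int, tuple[str, ...]]:
    """degeneracy (family size) -> family labels of that size."""
    out: dict[int, list[str]] = {}
    for fam, codons in synonymous_families().items():
        out.setdefault(len(codons), []).append(fam)
    return {k: tuple(sorted(v)) for k, v in out.items()}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(dna: str) -> str:
    """Translate complete codons of an in-frame sequence; '*' for stops."""
    aas = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        aas.append("*" if codon in STOP_CODONS else CODON_TO_AA.get(codon, "X"))
    return "".join(aas)
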