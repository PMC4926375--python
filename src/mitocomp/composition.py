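"""Nucleotide composition and strand-asymmetry (skew) statistics.

Strand bias is measured with the usual skew pair

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on the major strand (or on a gene's coding strand when applied
to an extracted gene).  A negative AT-skew is a T-skew, a negative
GC-skew a C-skew.  N bases are excluded from numerators and
denominators; a skew whose denominator is zero is reported as missing
(NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genome_io import GeneSequence, Mitogenome, PartitionSet, codon_position_split

__all__ = ["CompositionSummary", "summarize", "partition_composition"]


@dataclass(frozen=True)
class CompositionSummary:
    label: str
    a: int
    c: int
    g: int
    t: int
    n: int

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.n

    @property
    def at_content(self) -> float:
        denom = self.length - self.n
        return (self.a + self.t) / denom if denom else math.nan

    @property
    def gc_content(self) -> float:
        denom = self.length - self.n
        return (self.g + self.c) / denom if denom else math.nan

    @property
    def at_skew(self) -> float:
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else math.nan

    @property
    def gc_skew(self) -> float:
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else math.nan

    def as_row(self) -> dict:
        return {
            "partition": self.label, "length": self.length,
            "A": self.a, "C": self.c, "G": self.g, "T": self.t, "N": self.n,
            "at_content": self.at_content, "gc_content": self.gc_content,
            "at_skew": self.at_skew, "gc_skew": self.gc_skew,
        }


def summarize(seq: str, label: str = "") -> CompositionSummary:
    """Base counts, A+T / G+C content and skews of one sequence."""
    if not seq:
        raise ValueError("cannot summarise an empty sequence")
    return CompositionSummary(
        label, seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T"),
        seq.count("N"),
    )


def _pooled(genes: list[GeneSequence]) -> str:
    return "".join(g.dna for g in genes)


def partition_composition(
    pset: PartitionSet,
    genome: Mitogenome | None = None,
    per_gene_positions: bool = False,
) -> pd.DataFrame:
    """Composition table over the standard partitions of one genome.

    Rows: whole genome (when ``genome`` is given), pooled PCGs, PCGs by
    strand, pooled tRNAs, pooled rRNAs, AT-rich region, and codon
    positions 1/2/3 for each PCG strand class.  Codon positions pool
    bases across genes by default; ``per_gene_positions`` adds per-gene
    position rows as well.
    """
    summaries: list[CompositionSummary] = []
    if genome is not None:
        summaries.append(summarize(genome.sequence, "whole_genome"))
    groups: list[tuple[str, list[GeneSequence]]] = [
        ("PCGs", pset.pcgs),
        ("PCGs_major", pset.pcgs_major),
        ("PCGs_minor", pset.pcgs_minor),
        ("tRNAs", pset.trnas),
        ("rRNAs", pset.rrnas),
    ]
    for label, genes in groups:
        if genes:
            summaries.append(summarize(_pooled(genes), label))
    if pset.at_rich:
        summaries.append(summarize(pset.at_rich, "AT_rich"))
    for label, genes in (("PCGs_major", pset.pcgs_major),
                         ("PCGs_minor", pset.pcgs_minor)):
        if not genes:
            continue
        for k, sub in enumerate(codon_position_split(genes), start=1):
            summaries.append(summarize(sub, f"{label}_pos{k}"))
        if per_gene_positions:
            for g in genes:
                for k, sub in enumerate(codon_position_split([g]), start=1):
                    summaries.append(summarize(sub, f"{g.name}_pos{k}"))
    df = pd.DataFrame([s.as_row() for s in summaries])
    df.insert(0, "genome", pset.genome_id)
    return df
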