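"""Per-gene synonymous / nonsynonymous substitution rates (NG86).

Implements the Nei-Gojobori (1986) pathway-counting method under the
invertebrate mitochondrial code with Jukes-Cantor distance correction:

* each codon position contributes a synonymous-site fraction equal to
  the share of its three possible single-nucleotide changes that leave
  the amino acid unchanged (s + n = 3 per codon; changes creating a
  stop codon are counted as nonsynonymous);
* codon pairs differing at several positions are resolved over all
  minimal mutation pathways with equal weighting, pathways through stop
  codons excluded (all pathways are used if every one is blocked);
* proportions p = Sd/S, Nd/N are corrected with
  d = -(3/4) ln(1 - 4p/3); p >= 3/4 is flagged as saturated.

Gene-level Ka/Ks are means over all in-group pairwise comparisons, and
omega is the ratio of those means (not the mean of per-pair ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import pandas as pd

from ._code import BASES, CODON_TO_AA, is_stop
from .genome_io import GeneSequence

__all__ = [
    "PairwiseRates",
    "SubstitutionRates",
    "syn_nonsyn_sites",
    "pairwise_ka_ks",
    "gene_rates",
    "rates_table",
]


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of one sense codon.

    Changes producing a stop codon count as nonsynonymous so that
    s + n == 3 exactly.
    """
    if codon not in CODON_TO_AA:
        raise ValueError(f"{codon}: not a sense codon under the mitochondrial code")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    results = []
    blocked = []
    for order in permutations(diffs):
        cur = a
        sd = nd = 0
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                via_stop = True
            if CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt) and not (
                is_stop(cur) or is_stop(nxt)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if via_stop else results).append((sd, nd))
    use = results or blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class PairwiseRates:
    ka: float
    ks: float
    omega: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    codons: int
    flags: tuple[str, ...] = ()


def _coding(seq: GeneSequence | str) -> str:
    return seq.coding if isinstance(seq, GeneSequence) else str(seq).upper()


def pairwise_ka_ks(a: GeneSequence | str, b: GeneSequence | str) -> PairwiseRates:
    """NG86 Ka/Ks between two codon-aligned coding sequences.

    Codon pairs containing gaps, N, or a stop codon in either sequence
    are dropped pairwise.  ``omega`` is NaN when Ks is zero or either
    distance is saturated.
    """
    sa, sb = _coding(a), _coding(b)
    if len(sa) != len(sb):
        raise ValueError("sequences must be codon-aligned to equal length")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    used = 0
    for i in range(0, len(sa) - len(sa) % 3, 3):
        ca, cb = sa[i : i + 3], sb[i : i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue  # stop codons carry no rate information
        used += 1
        s1, n1 = syn_nonsyn_sites(ca)
        s2, n2 = syn_nonsyn_sites(cb)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        if ca != cb:
            dsd, dnd = _pathway_counts(ca, cb)
            sd += dsd
            nd += dnd
    flags: list[str] = []
    if used == 0:
        return PairwiseRates(math.nan, math.nan, math.nan, 0.0, 0.0, 0.0, 0.0, 0,
                             ("no_codons",))
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = _jc(ps)
    ka = _jc(pn)
    if math.isnan(ks) or math.isnan(ka):
        flags.append("saturated")
    omega = ka / ks if ks and not math.isnan(ks) and not math.isnan(ka) else math.nan
    return PairwiseRates(ka, ks, omega, s_sites, n_sites, sd, nd, used,
                         tuple(flags))


@dataclass
class SubstitutionRates:
    gene: str
    ka: float
    ks: float
    omega: float
    n_pairs: int
    flags: tuple[str, ...] = ()
    pairs: list[tuple[str, str, PairwiseRates]] = field(default_factory=list)


def gene_rates(
    alignments: dict[str, dict[str, GeneSequence | str]],
    ingroup: list[str] | None = None,
) -> list[SubstitutionRates]:
    """Per-gene mean Ka, Ks and omega over all in-group pairwise
    comparisons.

    ``alignments`` maps gene name -> {taxon id -> codon-aligned coding
    sequence}.  Saturated pairs are excluded from the means and
    recorded in the flags; omega is ratio-of-means.
    """
    out: list[SubstitutionRates] = []
    for gene, rows in alignments.items():
        taxa = [t for t in rows if ingroup is None or t in ingroup]
        if len(taxa) < 2:
            raise ValueError(f"{gene}: need at least two in-group sequences")
        kas, kss = [], []
        pairs = []
        n_saturated = 0
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                pr = pairwise_ka_ks(rows[taxa[i]], rows[taxa[j]])
                pairs.append((taxa[i], taxa[j], pr))
                if "saturated" in pr.flags or "no_codons" in pr.flags:
                    n_saturated += 1
                    continue
                kas.append(pr.ka)
                kss.append(pr.ks)
        flags: list[str] = []
        if n_saturated:
            flags.append(f"saturated_pairs:{n_saturated}")
        if not kas:
            out.append(SubstitutionRates(gene, math.nan, math.nan, math.nan, 0,
                                         ("all_pairs_saturated",), pairs))
            continue
        mka = sum(kas) / len(kas)
        mks = sum(kss) / len(kss)
        omega = mka / mks if mks > 0 else math.nan
        if mks == 0:
            flags.append("ks_zero")
        out.append(SubstitutionRates(gene, mka, mks, omega, len(kas),
                                     tuple(flags), pairs))
    return out


def rates_table(rates: list[SubstitutionRates]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene": r.gene, "ka": r.ka, "ks": r.ks, "omega": r.omega,
         "n_pairs": r.n_pairs, "flags": ";".join(r.flags)}
        for r in rates
    ])
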