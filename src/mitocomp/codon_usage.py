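"""Codon-usage bias statistics under the invertebrate mitochondrial code.

Implements the classic bias repertoire for mitochondrial protein-coding
genes: relative synonymous codon usage (RSCU), codon-family third-base
shares (NNA/NNU/NNC/NNG), the pooled share of the four AT-rich codons
(UUU, UUA, AUU, AUA), Wright's effective number of codons (ENC), the
codon bias index (CBI), G+C content of all codon positions and of third
positions (GC3), and least-squares correlations between any of these
per-genome quantities.

Definitions
-----------
RSCU(c)  = observed(c) * family_size / sum of family counts
ENC      = sum over degeneracy classes of  N_class / mean(F-hat)_class,
           F-hat = (n * sum p_i^2 - 1) / (n - 1)   (Wright 1990)
CBI      = (N_pref - N_rand) / (N_total - N_rand), N_rand being the
           preferred-codon count expected under uniform synonymous usage

Stop codons are excluded from every statistic.  The serine family is
split into its UCN and AGN halves (see :mod:`mitocomp._code`), giving
21 synonymous families and 62 sense codons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _st

from ._code import (CODON_TO_AA, SENSE_CODONS, degeneracy_classes, family_of,
                    is_stop, synonymous_families)
from .genome_io import GeneSequence

__all__ = [
    "CodonUsageTable",
    "CorrelationResult",
    "count_codons",
    "rscu",
    "enc",
    "cbi",
    "correlate",
    "preferred_codons",
    "AT_RICH_CODONS",
    "usage_long_table",
    "summary_row",
]

AT_RICH_CODONS = ("TTT", "TTA", "ATT", "ATA")  # UUU(F), UUA(L), AUU(I), AUA(M)


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    label: str = ""
    genetic_code: int = 5

    def __post_init__(self) -> None:
        full = dict.fromkeys(SENSE_CODONS, 0)
        full.update({c: int(n) for c, n in self.counts.items() if not is_stop(c)})
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def family_end_shares(self) -> dict[str, float]:
        tot = self.total
        ends = {"A": 0, "T": 0, "C": 0, "G": 0}
        for codon, n in self.counts.items():
            ends[codon[2]] += n
        key = {"A": "NNA", "T": "NNU", "C": "NNC", "G": "NNG"}
        return {key[b]: (ends[b] / tot if tot else math.nan) for b in "ATCG"}

    @property
    def at_rich4_share(self) -> float:
        tot = self.total
        return sum(self.counts[c] for c in AT_RICH_CODONS) / tot if tot else math.nan

    @property
    def gc(self) -> float:
        tot = self.total
        if not tot:
            return math.nan
        gc = sum(n * sum(b in "GC" for b in codon) for codon, n in self.counts.items())
        return gc / (3 * tot)

    @property
    def gc3(self) -> float:
        tot = self.total
        if not tot:
            return math.nan
        return sum(n for codon, n in self.counts.items() if codon[2] in "GC") / tot

    @property
    def rscu(self) -> dict[str, float]:
        return rscu(self)

    @property
    def enc(self) -> float:
        return enc(self)

    @property
    def cbi(self) -> float:
        return cbi(self)


def count_codons(genes: list[GeneSequence], label: str = "") -> CodonUsageTable:
    """Count complete sense codons of PCGs in coding orientation.

    The frame offset of each gene is applied, incomplete terminal codons
    are dropped, stop codons and codons containing N are excluded.
    """
    counts: dict[str, int] = {}
    for g in genes:
        if g.kind != "PCG":
            raise ValueError(f"{g.name}: codon counting applies to PCGs only")
        s = g.coding
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if "N" in codon or is_stop(codon):
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts, label=label)


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """RSCU per sense codon; families with zero usage yield NaN."""
    out: dict[str, float] = {}
    for fam, codons in synonymous_families().items():
        tot = sum(table.counts[c] for c in codons)
        for c in codons:
            out[c] = table.counts[c] * len(codons) / tot if tot else math.nan
    return out


def enc(table: CodonUsageTable) -> float:
    """Wright's effective number of codons.

    Per-family codon homozygosity F-hat is averaged within each
    degeneracy class (2-, 4- and 6-fold under table 5 with the serine
    family split); an empty class is imputed with the mean F-hat of the
    non-empty classes.  The value is capped at the 62 sense codons.
    """
    fams = synonymous_families()
    classes = degeneracy_classes()
    fhat_by_class: dict[int, list[float]] = {k: [] for k in classes}
    any_codons = False
    for fam, codons in fams.items():
        n = sum(table.counts[c] for c in codons)
        if n > 0:
            any_codons = True
        if n < 2:
            continue
        sum_p2 = sum((table.counts[c] / n) ** 2 for c in codons)
        fhat = (n * sum_p2 - 1) / (n - 1)
        if fhat > 0:
            fhat_by_class[len(codons)].append(fhat)
    if not any_codons:
        raise ValueError("ENC undefined: no codons counted")
    means = {k: (sum(v) / len(v) if v else math.nan) for k, v in fhat_by_class.items()}
    available = [m for m in means.values() if not math.isnan(m)]
    if not available:
        raise ValueError("ENC undefined: no synonymous family has usable counts")
    fallback = sum(available) / len(available)
    value = 0.0
    for k, fam_names in classes.items():
        mean_f = means[k] if not math.isnan(means[k]) else fallback
        value += len(fam_names) / mean_f
    return min(value, float(len(SENSE_CODONS)))


def preferred_codons(ending: str = "A") -> frozenset[str]:
    """Codons with the given third base, one set drawn from every
    multi-codon family (the default A-enders are the majority preference
    of major-strand mitochondrial PCGs; use ``ending='T'`` for the
    U-ending preference of minor-strand genes)."""
    out = set()
    for fam, codons in synonymous_families().items():
        if len(codons) < 2:
            continue
        out.update(c for c in codons if c[2] == ending.upper().replace("U", "T"))
    return frozenset(out)


def cbi(table: CodonUsageTable, preferred: frozenset[str] | None = None) -> float:
    """Codon bias index: 0 under uniform synonymous usage, 1 when only
    preferred codons are used."""
    if preferred is None:
        preferred = preferred_codons("A")
    if not preferred:
        raise ValueError("preferred codon set is empty")
    n_pref = n_total = 0
    n_rand = 0.0
    for fam, codons in synonymous_families().items():
        if len(codons) < 2:
            continue  # families without synonymous choice carry no bias signal
        fam_n = sum(table.counts[c] for c in codons)
        fam_pref = sum(table.counts[c] for c in codons if c in preferred)
        k_pref = sum(c in preferred for c in codons)
        n_total += fam_n
        n_pref += fam_pref
        n_rand += fam_n * k_pref / len(codons)
    if n_total == 0 or n_total == n_rand:
        return math.nan
    return (n_pref - n_rand) / (n_total - n_rand)


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    n: int
    pearson_r: float
    slope: float
    intercept: float

    @property
    def r_squared(self) -> float:
        return self.pearson_r ** 2


def correlate(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult | None:
    """Least-squares fit and Pearson correlation of two paired vectors.

    Returns None (with a warning) when either vector has zero variance
    or fewer than 3 points.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        warnings.warn(f"correlation {x_label}~{y_label}: fewer than 3 points")
        return None
    if len(set(x)) == 1 or len(set(y)) == 1:
        warnings.warn(f"correlation {x_label}~{y_label}: zero variance")
        return None
    res = _st.linregress(x, y)
    return CorrelationResult(x_label, y_label, len(x), float(res.rvalue),
                             float(res.slope), float(res.intercept))


# ---------------------------------------------------------------------------
# tabular exports

def usage_long_table(table: CodonUsageTable) -> pd.DataFrame:
    r = rscu(table)
    rows = [{"scope": table.label, "codon": c, "aa": CODON_TO_AA[c],
             "family": family_of(c), "count": table.counts[c], "rscu": r[c]}
            for c in SENSE_CODONS]
    return pd.DataFrame(rows)


def summary_row(table: CodonUsageTable, preferred: frozenset[str] | None = None) -> dict:
    shares = table.family_end_shares
    return {
        "scope": table.label, "codons": table.total,
        "enc": enc(table), "cbi": cbi(table, preferred),
        "gc": table.gc, "gc3": table.gc3,
        "at_rich4_share": table.at_rich4_share, **shares,
    }
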