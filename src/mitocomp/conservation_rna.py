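"""Alignment-column conservation scoring for RNA gene families.

The statistic is %INUC — the percentage of alignment columns in which
every compared genome carries the same (non-gap) nucleotide.  Given a
structure mask labelling columns by cloverleaf region (acceptor stem,
DHU arm/loop, anticodon arm/loop, T-psi-C arm/loop, connectors) or by
rRNA helix id, conservation is also summarised per structural region,
pooling identical-column counts over all families that share a label.

Alignments are consumed as inputs (aligned FASTA); no folding or
alignment construction is performed here.  A default 71-column
cloverleaf mask is packaged (``resources/cloverleaf_mask.txt``) and any
mask can be supplied in the same "start end label" text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import pandas as pd

__all__ = [
    "AlignedFamily",
    "ConservationProfile",
    "read_aligned_fasta",
    "read_mask",
    "default_cloverleaf_mask",
    "score_family",
    "region_summary",
    "strand_conservation_bias",
]

GAP_CHARS = frozenset("-.")


@dataclass
class AlignedFamily:
    gene: str
    sequences: dict[str, str]  # genome id -> aligned row
    structure_mask: list[str] | None = None  # per-column region label

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: ragged alignment rows {sorted(lengths)}")
        if self.structure_mask is not None and self.sequences:
            if len(self.structure_mask) != next(iter(lengths)):
                raise ValueError(
                    f"{self.gene}: mask length {len(self.structure_mask)} != "
                    f"alignment length {next(iter(lengths))}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


@dataclass
class ConservationProfile:
    gene: str
    is_identical: list[bool]  # per scored column
    scored_columns: list[int]  # 0-based indices of non-all-gap columns
    per_region: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def inuc(self) -> float:
        if not self.is_identical:
            raise ValueError(f"{self.gene}: no scorable columns")
        return sum(self.is_identical) / len(self.is_identical)

    def region_fraction(self, region: str) -> float:
        ident, total = self.per_region[region]
        return ident / total


def read_aligned_fasta(path: str | Path, gene: str | None = None) -> AlignedFamily:
    """Read one aligned FASTA file into an :class:`AlignedFamily`."""
    path = Path(path)
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks).upper()
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    return AlignedFamily(gene or path.stem, seqs)


def read_mask(path: str | Path, length: int | None = None) -> list[str]:
    """Read a "start end label" mask file into a per-column label list."""
    spans = []
    max_end = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        start_s, end_s, label = line.split(maxsplit=2)
        start, end = int(start_s), int(end_s)
        if not 1 <= start <= end:
            raise ValueError(f"bad mask span: {line!r}")
        spans.append((start, end, label))
        max_end = max(max_end, end)
    n = length or max_end
    mask = ["unassigned"] * n
    for start, end, label in spans:
        for i in range(start - 1, min(end, n)):
            mask[i] = label
    return mask


def default_cloverleaf_mask() -> list[str]:
    """The packaged 71-column tRNA cloverleaf mask."""
    with _ilres.as_file(
        _ilres.files("mitocomp.resources").joinpath("cloverleaf_mask.txt")
    ) as p:
        return read_mask(p)


def score_family(fam: AlignedFamily) -> ConservationProfile:
    """Score one aligned family.

    A column is identical iff every row carries the same non-gap base;
    columns that are gaps in every row are excluded from denominators.
    """
    if len(fam.sequences) < 2:
        raise ValueError(f"{fam.gene}: need at least two rows to score")
    rows = list(fam.sequences.values())
    identical: list[bool] = []
    scored: list[int] = []
    for col in range(fam.length):
        chars = {r[col] for r in rows}
        if chars <= GAP_CHARS:
            continue  # all-gap column
        scored.append(col)
        identical.append(len(chars) == 1 and not chars & GAP_CHARS)
    profile = ConservationProfile(fam.gene, identical, scored)
    if fam.structure_mask is not None:
        regions: dict[str, list[int]] = {}
        for idx, col in enumerate(scored):
            regions.setdefault(fam.structure_mask[col], []).append(idx)
        profile.per_region = {
            reg: (sum(identical[i] for i in idxs), len(idxs))
            for reg, idxs in regions.items()
        }
    return profile


def region_summary(profiles: list[ConservationProfile]) -> dict[str, float]:
    """Pooled per-region conservation over all families.

    Fractions are identical-column counts over total columns carrying
    each region label, pooled across families (column-weighted).
    """
    ident: dict[str, int] = {}
    total: dict[str, int] = {}
    for p in profiles:
        for reg, (i, t) in p.per_region.items():
            ident[reg] = ident.get(reg, 0) + i
            total[reg] = total.get(reg, 0) + t
    return {reg: ident[reg] / total[reg] for reg in total}


def strand_conservation_bias(
    inuc_by_gene: dict[str, float],
    strand_by_gene: dict[str, str],
    high_cutoff: float = 0.75,
    low_band: tuple[float, float] = (0.4, 0.6),
) -> dict:
    """Summarise %INUC by coding strand.

    Reports the mean %INUC per strand, the families above the high
    conservation cutoff, and the families inside the ~50% band.
    """
    per_strand: dict[str, list[float]] = {"major": [], "minor": []}
    for gene, v in inuc_by_gene.items():
        per_strand[strand_by_gene[gene]].append(v)
    for strand, vals in per_strand.items():
        if not vals:
            raise ValueError(f"no families on the {strand} strand")
    return {
        "major_mean": sum(per_strand["major"]) / len(per_strand["major"]),
        "minor_mean": sum(per_strand["minor"]) / len(per_strand["minor"]),
        "high": sorted(g for g, v in inuc_by_gene.items() if v > high_cutoff),
        "mid": sorted(g for g, v in inuc_by_gene.items()
                      if low_band[0] <= v <= low_band[1]),
    }


def conservation_table(profiles: list[ConservationProfile],
                       strand_by_gene: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"gene": p.gene, "columns": len(p.is_identical),
               "identical": sum(p.is_identical), "inuc": p.inuc}
        if strand_by_gene:
            row["strand"] = strand_by_gene.get(p.gene, "")
        rows.append(row)
    return pd.DataFrame(rows)
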