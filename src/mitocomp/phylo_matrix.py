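"""Concatenated, partitioned phylogenetic datasets.

Builds the four standard mitogenomic supermatrices from per-gene
alignments:

* ``PCG``     — the 13 protein-coding genes;
* ``mtDNA``   — all 37 coding genes (PCGs + tRNAs + rRNAs);
* ``PCG12`` / ``mtDNA12`` — the same with third codon positions removed.

Character sets partition every column exactly: one charset per codon
position per PCG block (``ND2_pos1`` = ``start-end\\3`` ranges) and one
pooled ``RNA`` charset; per-gene block spans are kept separately as
provenance.  Alignment construction is out of scope — aligned FASTA
per gene is consumed as input.  Exports are relaxed PHYLIP and NEXUS
(with charsets and a commented Bayesian-analysis stub), byte-stable
across reruns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import PCG_NAMES, canonical_gene_order

__all__ = [
    "SupermatrixDataset",
    "concatenate",
    "strip_third_positions",
    "write_phylip",
    "write_nexus",
    "read_nexus",
]

DATASET_NAMES = ("PCG", "mtDNA", "PCG12", "mtDNA12")


@dataclass
class SupermatrixDataset:
    name: str
    taxa: list[str]
    rows: dict[str, str]  # taxon -> aligned row
    charsets: dict[str, list[tuple[int, int, int]]]  # name -> (start,end,step), 1-based
    gene_blocks: dict[str, tuple[int, int]]  # provenance: gene -> block span
    gene_order: list[str] = field(default_factory=list)

    @property
    def nchar(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def charset_columns(self, name: str) -> set[int]:
        cols: set[int] = set()
        for start, end, step in self.charsets[name]:
            cols.update(range(start, end + 1, step))
        return cols


def _select_genes(alignments: dict[str, dict[str, str]], name: str) -> list[str]:
    wanted_kinds = {"PCG"} if name.startswith("PCG") else {"PCG", "tRNA", "rRNA"}
    order = [g for g, kind, _ in canonical_gene_order() if kind in wanted_kinds]
    return [g for g in order if g in alignments]


def concatenate(alignments: dict[str, dict[str, str]],
                name: str = "PCG") -> SupermatrixDataset:
    """Concatenate per-gene alignments into a named dataset.

    ``alignments`` maps gene -> {taxon -> aligned sequence}.  Genes are
    taken in the canonical insect gene order; every alignment must
    cover the same taxon set, and PCG alignments must be codon-complete
    (length divisible by 3).
    """
    if name not in ("PCG", "mtDNA"):
        raise ValueError(f"build PCG or mtDNA and derive {name} by stripping")
    genes = _select_genes(alignments, name)
    if not genes:
        raise ValueError("no usable gene alignments supplied")
    taxa = sorted(alignments[genes[0]])
    for g in genes:
        missing = set(taxa) ^ set(alignments[g])
        if missing:
            raise ValueError(f"{g}: taxon set mismatch ({sorted(missing)})")
        lengths = {len(s) for s in alignments[g].values()}
        if len(lengths) != 1:
            raise ValueError(f"{g}: ragged alignment")
        if g in PCG_NAMES and next(iter(lengths)) % 3:
            raise ValueError(f"{g}: PCG alignment length not a codon multiple")
    rows = {t: "".join(alignments[g][t] for g in genes) for t in taxa}
    charsets: dict[str, list[tuple[int, int, int]]] = {}
    gene_blocks: dict[str, tuple[int, int]] = {}
    rna_ranges: list[tuple[int, int, int]] = []
    pos = 1
    for g in genes:
        glen = len(alignments[g][taxa[0]])
        gene_blocks[g] = (pos, pos + glen - 1)
        if g in PCG_NAMES:
            for k in range(3):
                charsets[f"{g}_pos{k+1}"] = [(pos + k, pos + glen - 3 + k, 3)]
        else:
            rna_ranges.append((pos, pos + glen - 1, 1))
        pos += glen
    if rna_ranges:
        charsets["RNA"] = rna_ranges
    return SupermatrixDataset(name, taxa, rows, charsets, gene_blocks, genes)


def strip_third_positions(ds: SupermatrixDataset) -> SupermatrixDataset:
    """Remove third codon positions from every PCG block (RNA untouched)."""
    if ds.name.endswith("12"):
        raise ValueError(f"{ds.name}: third positions already removed")
    keep: list[int] = []  # 0-based columns retained, in order
    charsets: dict[str, list[tuple[int, int, int]]] = {}
    gene_blocks: dict[str, tuple[int, int]] = {}
    rna_ranges: list[tuple[int, int, int]] = []
    pos = 1
    for g in ds.gene_order:
        start, end = ds.gene_blocks[g]
        glen = end - start + 1
        if g in PCG_NAMES:
            for c in range(start - 1, end, 3):
                keep.extend((c, c + 1))
            new_len = glen // 3 * 2
            for k in range(2):
                charsets[f"{g}_pos{k+1}"] = [(pos + k, pos + new_len - 2 + k, 2)]
        else:
            keep.extend(range(start - 1, end))
            new_len = glen
            rna_ranges.append((pos, pos + new_len - 1, 1))
        gene_blocks[g] = (pos, pos + new_len - 1)
        pos += new_len
    if rna_ranges:
        charsets["RNA"] = rna_ranges
    rows = {t: "".join(row[c] for c in keep) for t, row in ds.rows.items()}
    return SupermatrixDataset(ds.name + "12", list(ds.taxa), rows, charsets,
                              gene_blocks, list(ds.gene_order))


# ---------------------------------------------------------------------------
# exports

def _sanitize(taxa: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for t in taxa:
        s = re.sub(r"[^A-Za-z0-9_.]", "_", t)
        if s in out.values():
            raise ValueError(f"taxon name collision after sanitisation: {s}")
        out[t] = s
    return out


def write_phylip(ds: SupermatrixDataset, path: str | Path) -> None:
    names = _sanitize(ds.taxa)
    width = max(len(n) for n in names.values()) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(ds.taxa)} {ds.nchar}\n")
        for t in ds.taxa:
            fh.write(f"{names[t]:<{width}}{ds.rows[t]}\n")


_BI_STUB = """\
[ Suggested Bayesian settings for externally run analyses:
  partitions as the charsets above; GTR+I+G for RNA and codon
  positions 1-2, GTR for codon position 3; 4 MCMC chains,
  1,000,000 generations, sampling every 100, 25% burn-in. ]
"""


def write_nexus(ds: SupermatrixDataset, path: str | Path) -> None:
    names = _sanitize(ds.taxa)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(ds.taxa)} NCHAR={ds.nchar};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t in ds.taxa:
            fh.write(f"    {names[t]}  {ds.rows[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for cname in ds.charsets:
            ranges = " ".join(
                (f"{s}-{e}\\{step}" if step > 1 else (f"{s}-{e}" if e > s else f"{s}"))
                for s, e, step in ds.charsets[cname]
            )
            fh.write(f"  CHARSET {cname} = {ranges};\n")
        fh.write("END;\n\n")
        fh.write(_BI_STUB)


def read_nexus(path: str | Path) -> SupermatrixDataset:
    """Re-read a NEXUS file written by :func:`write_nexus`."""
    text = Path(path).read_text()
    rows: dict[str, str] = {}
    in_matrix = False
    for line in text.splitlines():
        s = line.strip()
        if s.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if s == ";":
                in_matrix = False
                continue
            if s:
                name, seq = s.split()
                rows[name] = rows.get(name, "") + seq
    charsets: dict[str, list[tuple[int, int, int]]] = {}
    for m in re.finditer(r"CHARSET\s+(\S+)\s*=\s*([^;]+);", text):
        ranges = []
        for tok in m.group(2).split():
            step = 1
            if "\\" in tok:
                tok, step_s = tok.split("\\")
                step = int(step_s)
            if "-" in tok:
                a, b = tok.split("-")
            else:
                a = b = tok
            ranges.append((int(a), int(b), step))
        charsets[m.group(1)] = ranges
    name = Path(path).stem
    return SupermatrixDataset(name, sorted(rows), rows, charsets, {}, [])
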