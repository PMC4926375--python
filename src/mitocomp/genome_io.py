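"""Parsing and slicing of annotated mitochondrial genomes.

A mitogenome is a circular DNA molecule carrying (in insects) 13
protein-coding genes, 22 tRNAs, two rRNAs and one AT-rich control
region.  This module reads GenBank flat files into a typed
:class:`Mitogenome`, normalises gene labels through a packaged synonym
table, and extracts genes in coding orientation — minor-strand genes
are reverse-complemented, and truncated stop codons (a bare T or TA at
the 3' end, completed to UAA by polyadenylation in vivo) are recorded
rather than edited into the sequence.

Coordinates are 1-based inclusive internally (GenBank convention).
Spans that wrap the origin of the circular molecule are unwrapped by
concatenating suffix + prefix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._code import TABLE_ID, revcomp

__all__ = [
    "Mitogenome",
    "GeneFeature",
    "GeneSequence",
    "PartitionSet",
    "ParseError",
    "GeneLookupError",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "AT_RICH_NAME",
    "canonical_gene_order",
    "canonical_name",
    "parse_genbank",
    "write_genbank",
    "write_fasta",
    "extract_gene",
    "classify_codons",
    "codon_position_split",
    "partition_set",
    "feature_table",
]

PCG_NAMES = frozenset(
    {"ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
     "COX1", "COX2", "COX3", "ATP6", "ATP8", "CYTB"}
)
RRNA_NAMES = frozenset({"16S rRNA", "12S rRNA"})
AT_RICH_NAME = "AT-rich region"

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed or unsupported input record."""


class GeneLookupError(KeyError):
    """Requested gene is absent from the genome's feature table."""


@dataclass(frozen=True)
class GeneFeature:
    name: str
    kind: str  # PCG | tRNA | rRNA | AT_rich | intergenic
    strand: str  # major | minor
    start: int  # 1-based inclusive, major-strand coordinates
    end: int  # 1-based inclusive
    wraps_origin: bool = False
    codon_start_offset: int = 0  # PCGs only, 0..2

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for a wrapped span")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class Mitogenome:
    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise GeneLookupError(
            f"gene {name!r} not found in {self.id}; available: "
            + ", ".join(sorted({f.name for f in self.features}))
        )

    def span_sequence(self, feat: GeneFeature) -> str:
        """Major-strand sequence of a feature span (wrap-aware)."""
        if feat.wraps_origin:
            return self.sequence[feat.start - 1 :] + self.sequence[: feat.end]
        return self.sequence[feat.start - 1 : feat.end]


@dataclass(frozen=True)
class GeneSequence:
    name: str
    kind: str
    strand: str
    dna: str  # coding orientation (minor-strand genes reverse-complemented)
    stop_completion: str = "complete"  # complete | T | TA
    codon_start_offset: int = 0

    def __len__(self) -> int:
        return len(self.dna)

    @property
    def coding(self) -> str:
        """Frame-adjusted sequence (codon_start offset applied)."""
        return self.dna[self.codon_start_offset :]


@dataclass
class PartitionSet:
    genome_id: str
    pcgs_major: list[GeneSequence]
    pcgs_minor: list[GeneSequence]
    trnas: list[GeneSequence]
    rrnas: list[GeneSequence]
    at_rich: str | None
    intergenic_spacers: list[tuple[tuple[str, str], str]]

    @property
    def pcgs(self) -> list[GeneSequence]:
        return self.pcgs_major + self.pcgs_minor

    def spacer(self, left: str, right: str) -> str | None:
        for (a, b), seq in self.intergenic_spacers:
            if (a, b) == (left, right):
                return seq
        return None


# ---------------------------------------------------------------------------
# gene-name normalisation

TRNA_NAMES = frozenset(
    {"trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG", "trnH",
     "trnI", "trnK", "trnM", "trnF", "trnP", "trnT", "trnW", "trnY", "trnV",
     "trnL_UUR", "trnL_CUN", "trnS_AGN", "trnS_UCN"}
)

_NORM_RE = re.compile(r"[\s\-_()^*']+")


def _norm(name: str) -> str:
    return _NORM_RE.sub("", name.lower())


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = _ilres.files("mitocomp.resources").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        syn, canon = line.split("\t")
        table[_norm(syn)] = canon
    return table


_SYNONYMS: dict[str, str] | None = None


def canonical_name(raw: str) -> str | None:
    """Map an annotation label to its canonical gene name, or None."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS.get(_norm(raw))


def canonical_gene_order() -> list[tuple[str, str, str]]:
    """(name, kind, strand) rows of the packaged insect gene order."""
    rows = []
    text = _ilres.files("mitocomp.resources").joinpath("gene_order.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, kind, strand = line.split("\t")
        rows.append((name, kind, strand))
    return rows


# ---------------------------------------------------------------------------
# GenBank I/O

_KIND_BY_FTYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}

MIN_AT_RICH_GAP = 50  # bp; unannotated 12S rRNA -> trnI gaps at least this long become AT_rich


def parse_genbank(path: str | Path) -> Mitogenome:
    """Parse a GenBank flat file into a :class:`Mitogenome`.

    Annotated gene labels are canonicalised through the synonym table;
    unknown labels are kept with kind ``intergenic`` and a warning.  If
    no control region is annotated, the gap between 12S rRNA and trnI
    (>= 50 bp) is labelled as the AT-rich region.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with locus info
        raise ParseError(f"{path}: malformed GenBank record: {exc}") from exc

    seq = str(record.seq).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(
            f"{path}: ambiguity characters other than N are not supported: "
            + ",".join(sorted(bad))
        )

    circular = record.annotations.get("topology", "circular") == "circular"
    feats: list[GeneFeature] = []
    for sf in record.features:
        if sf.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        raw = _feature_label(sf)
        canon = canonical_name(raw) if raw else None
        if sf.type in _KIND_BY_FTYPE:
            kind = _KIND_BY_FTYPE[sf.type]
            if canon is None:
                warnings.warn(
                    f"{record.id}: unknown gene label {raw!r}; kept as intergenic"
                )
                kind, canon = "intergenic", raw or "unknown"
        else:  # misc_feature / D-loop
            if canon == AT_RICH_NAME:
                kind = "AT_rich"
            else:
                kind, canon = "intergenic", canon or (raw or "misc")
        start, end, wraps = _location_bounds(sf, len(seq))
        offset = 0
        if kind == "PCG":
            offset = int(sf.qualifiers.get("codon_start", ["1"])[0]) - 1
        strand = "minor" if sf.location.strand == -1 else "major"
        # control region reported in major orientation regardless of annotation
        if kind == "AT_rich":
            strand = "major"
        feats.append(GeneFeature(canon, kind, strand, start, end, wraps, offset))

    feats.sort(key=lambda f: (f.start, f.end))
    genome = Mitogenome(record.id or path.stem, seq, circular, feats)
    if not any(f.kind == "AT_rich" for f in genome.features):
        _infer_at_rich(genome)
    return genome


def _feature_label(sf: SeqFeature) -> str:
    for key in ("gene", "product", "note"):
        if key in sf.qualifiers:
            return sf.qualifiers[key][0]
    return ""


def _location_bounds(sf: SeqFeature, genome_len: int) -> tuple[int, int, bool]:
    parts = sf.location.parts
    if len(parts) == 2 and int(parts[0].end) == genome_len and int(parts[1].start) == 0:
        return int(parts[0].start) + 1, int(parts[1].end), True
    return int(sf.location.start) + 1, int(sf.location.end), False


def _infer_at_rich(genome: Mitogenome) -> None:
    """Label the unannotated 12S rRNA -> trnI gap as the AT-rich region."""
    try:
        rrna = genome.feature("12S rRNA")
        trni = genome.feature("trnI")
    except GeneLookupError:
        return
    start = rrna.end + 1
    end = trni.start - 1
    if end >= start:
        gap = end - start + 1
        wraps = False
    else:  # gap wraps the origin
        gap = genome.length - start + 1 + end
        wraps = True
        if end == 0:  # trnI starts at position 1: pure suffix, no wrap
            end = genome.length
            wraps = False
    if gap >= MIN_AT_RICH_GAP:
        genome.features.append(
            GeneFeature(AT_RICH_NAME, "AT_rich", "major", start, end, wraps)
        )
        genome.features.sort(key=lambda f: (f.start, f.end))


_FTYPE_BY_KIND = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                  "AT_rich": "misc_feature", "intergenic": "misc_feature"}


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    """Minimal deterministic GenBank writer (for synthetic records)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="synthetic mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["data_file_division"] = "INV"
    record.annotations["date"] = "01-JAN-2000"  # fixed: byte-stable output
    for f in genome.features:
        strand = -1 if f.strand == "minor" else 1
        loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        ftype = _FTYPE_BY_KIND[f.kind]
        if f.kind == "PCG":
            quals["codon_start"] = [str(f.codon_start_offset + 1)]
            quals["transl_table"] = [str(TABLE_ID)]
        elif f.kind == "AT_rich":
            quals = {"note": [AT_RICH_NAME]}
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def write_fasta(genome: Mitogenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# gene extraction

def extract_gene(genome: Mitogenome, name: str) -> GeneSequence:
    """Extract a gene in coding orientation.

    Minor-strand genes are reverse-complemented.  For PCGs whose length
    is not a codon multiple, the terminal 1-2 nt are inspected for the
    truncated stop codon T/TA.
    """
    feat = genome.feature(name)
    dna = genome.span_sequence(feat)
    if feat.strand == "minor":
        dna = revcomp(dna)
    stop_completion = "complete"
    if feat.kind == "PCG":
        rem = (len(dna) - feat.codon_start_offset) % 3
        if rem == 1 and dna.endswith("T"):
            stop_completion = "T"
        elif rem == 2 and dna.endswith("TA"):
            stop_completion = "TA"
    return GeneSequence(feat.name, feat.kind, feat.strand, dna,
                        stop_completion, feat.codon_start_offset)


def classify_codons(gene: GeneSequence) -> tuple[str, str, str, str]:
    """Return (start codon, stop codon, start class, stop class) of a PCG.

    Start classes: ``ATN``, ``TTG/GTG/GTT`` (alternative invertebrate
    initiators) or ``nonstandard``.  Stop classes: ``TAA``, ``TAG``,
    ``incomplete-T``, ``incomplete-TA`` or ``nonstandard``.
    """
    if gene.kind != "PCG":
        raise ValueError(f"{gene.name}: codon classification applies to PCGs only")
    seq = gene.coding
    if len(seq) < 6:
        raise ValueError(f"{gene.name}: sequence too short to classify codons")
    start = seq[:3]
    if start.startswith("AT"):
        start_class = "ATN"
    elif start in ("TTG", "GTG", "GTT"):
        start_class = "TTG/GTG/GTT"
    else:
        start_class = "nonstandard"
    if gene.stop_completion == "T":
        stop, stop_class = "T", "incomplete-T"
    elif gene.stop_completion == "TA":
        stop, stop_class = "TA", "incomplete-TA"
    else:
        stop = seq[-3:]
        stop_class = stop if stop in ("TAA", "TAG") else "nonstandard"
    return start, stop, start_class, stop_class


def codon_position_split(genes: list[GeneSequence]) -> tuple[str, str, str]:
    """Pool the 1st/2nd/3rd bases of every complete codon across genes.

    Incomplete terminal codons (truncated stops) are excluded; genes are
    concatenated in input order.
    """
    pos = ["", "", ""]
    for g in genes:
        s = g.coding
        n = len(s) - len(s) % 3
        pos[0] += s[0:n:3]
        pos[1] += s[1:n:3]
        pos[2] += s[2:n:3]
    return pos[0], pos[1], pos[2]


# ---------------------------------------------------------------------------
# partitions

def partition_set(genome: Mitogenome) -> PartitionSet:
    """Split a genome into the analysis partitions.

    The AT-rich region is returned in major-strand orientation.
    Intergenic spacers are the >= 1 bp gaps between consecutive
    annotated features (wrap gap included on circular genomes).
    """
    pcgs_major: list[GeneSequence] = []
    pcgs_minor: list[GeneSequence] = []
    trnas: list[GeneSequence] = []
    rrnas: list[GeneSequence] = []
    at_rich: str | None = None
    for f in genome.features:
        if f.kind == "PCG":
            gs = extract_gene(genome, f.name)
            (pcgs_major if f.strand == "major" else pcgs_minor).append(gs)
        elif f.kind == "tRNA":
            trnas.append(extract_gene(genome, f.name))
        elif f.kind == "rRNA":
            rrnas.append(extract_gene(genome, f.name))
        elif f.kind == "AT_rich":
            at_rich = genome.span_sequence(f)

    spacers: list[tuple[tuple[str, str], str]] = []
    feats = [f for f in genome.features if not f.wraps_origin]
    for left, right in zip(feats, feats[1:]):
        if right.start > left.end + 1:
            seq = genome.sequence[left.end : right.start - 1]
            spacers.append(((left.name, right.name), seq))
    if genome.circular and feats:
        last, first = feats[-1], feats[0]
        if last.end < genome.length or first.start > 1:
            seq = genome.sequence[last.end :] + genome.sequence[: first.start - 1]
            if seq:
                spacers.append(((last.name, first.name), seq))
    return PartitionSet(genome.id, pcgs_major, pcgs_minor, trnas, rrnas,
                        at_rich, spacers)


def feature_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Tidy feature table (one row per gene per genome)."""
    rows = []
    for g in genomes:
        for f in g.features:
            start_codon = stop_codon = ""
            if f.kind == "PCG":
                try:
                    start_codon, stop_codon, _, _ = classify_codons(extract_gene(g, f.name))
                except ValueError:
                    pass
            rows.append({
                "genome": g.id, "gene": f.name, "kind": f.kind,
                "strand": f.strand, "start": f.start, "end": f.end,
                "length": f.length(g.length),
                "start_codon": start_codon, "stop_codon": stop_codon,
            })
    return pd.DataFrame(rows)
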