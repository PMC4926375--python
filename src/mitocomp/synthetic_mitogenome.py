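"""Synthetic circular mitogenomes with known ground truth.

The generator emits clades of insect-order mitogenomes carrying the
statistical structure the downstream analyses assume, so every pipeline
stage can be exercised against exact truth without any downloads:

* 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one AT-rich region in
  the ancestral insect gene order; minor-strand genes are generated in
  coding orientation and reverse-complemented into the genome, so
  strand-skew structure emerges as it does in real data;
* PCGs are built codon-wise — an amino-acid sequence is drawn first,
  then codons are drawn from a synonymous-codon distribution whose
  third-base A/T mass (``pos3_at``) and A-vs-T / C-vs-G splits are
  configurable per strand; sequences are valid under the invertebrate
  mitochondrial code (no internal stops), and the clade is derived
  from a common ancestor with synonymous changes favoured;
* the AT-rich region carries planted elements (tandem repeats,
  T-stretches on both strands, (AT)n microsatellites, motifs, a
  perfect-stem hairpin) at recorded coordinates, with guard bases so
  each planted span is exactly maximal;
* the conserved trnS(UCN)-ND1 spacer is planted verbatim.

Everything is driven by one explicit ``numpy`` generator seeded from
the single config seed; the same config reproduces the same bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from ._code import CODON_TO_AA, revcomp, synonymous_families
from .genome_io import (AT_RICH_NAME, GeneFeature, Mitogenome,
                        canonical_gene_order, write_fasta, write_genbank)

__all__ = [
    "SynthConfig",
    "PlantedElement",
    "SyntheticTruth",
    "generate_clade",
    "write_fixture_bundle",
    "default_planted_elements",
    "draw_pcg",
    "simulate_codon_alignment",
]

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: rough amino-acid frequencies of insect mitochondrial proteins
AA_FREQS: dict[str, float] = {
    "L": 0.155, "I": 0.100, "F": 0.095, "S": 0.110, "M": 0.055, "N": 0.050,
    "T": 0.050, "A": 0.045, "G": 0.060, "V": 0.045, "K": 0.035, "Y": 0.030,
    "W": 0.015, "P": 0.040, "E": 0.025, "D": 0.020, "Q": 0.020, "R": 0.020,
    "H": 0.020, "C": 0.010,
}

#: PCG lengths in sense codons (start included, stop excluded)
DEFAULT_PCG_CODONS: dict[str, int] = {
    "ND2": 341, "COX1": 512, "COX2": 229, "ATP8": 53, "ATP6": 225,
    "COX3": 262, "ND3": 117, "ND5": 573, "ND4": 446, "ND4L": 96,
    "ND6": 174, "CYTB": 379, "ND1": 312,
}


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # tandem_repeat | t_stretch_major | t_stretch_minor |
    #            microsatellite_AT | motif | hairpin
    position: str | int = "M"  # 5' | M | 3' | explicit 1-based offset
    params: dict = field(default_factory=dict)


def default_planted_elements() -> list[PlantedElement]:
    """Elements emulating a typical beetle control region: two tandem
    repeats, a long major-strand T-stretch flanked 3' by a hairpin, a
    minor-strand stretch with conserved flanking motifs, and an (AT)n
    microsatellite."""
    return [
        PlantedElement("tandem_repeat", "5'", {"period": 20, "copies": 2.2}),
        PlantedElement("tandem_repeat", "M", {"period": 22, "copies": 1.9}),
        PlantedElement("t_stretch_major", "M", {"length": 14, "flank3": "hairpin"}),
        PlantedElement("microsatellite_AT", "M", {"n": 6}),
        PlantedElement("t_stretch_minor", "3'",
                       {"length": 9, "flank5": "AAAGC", "flank3": "GTAA"}),
    ]


@dataclass
class SynthConfig:
    seed: int = 0
    n_genomes: int = 10
    pcg_codons: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_CODONS))
    trna_length: int = 71
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: {"16S rRNA": 1280, "12S rRNA": 760})
    at_rich_length: int = 1000
    genome_length: int | None = None  # if set, at_rich_length is adjusted to match
    # composition targets (fractions)
    trna_at: float = 0.72
    rrna_at: float = 0.74
    at_rich_at: float = 0.90
    genome_at_target: float | None = None  # calibrated via the AT-rich background
    # codon model
    pos3_at: float = 0.88
    pos3_a_share_major: float = 0.65  # A share of the pos-3 A/T mass, major strand
    pos3_a_share_minor: float = 0.30
    pos3_c_share_major: float = 0.65  # C share of the pos-3 G/C mass, major strand
    pos3_c_share_minor: float = 0.35
    incomplete_stops: dict[str, str] = field(
        default_factory=lambda: {"COX1": "T", "ND4": "TA"})
    # clade substitution process (per derived genome, from the ancestor)
    pcg_syn_rate: float = 0.06  # per-codon probability of a synonymous resample
    pcg_nonsyn_rate: float = 0.004  # per-codon probability of an amino-acid change
    rna_site_rate: float = 0.02
    minor_trna_rate_multiplier: float = 1.0
    at_rich_background_rate: float = 0.01
    element_mutation_rate: float = 0.0  # per-site rate inside planted spans
    spacer_mutations: int = 0  # substitutions applied to each derived spacer
    # planted content
    spacer_trnS_ND1: str = "ATACTAAATTTTATTAA"
    planted_elements: list[PlantedElement] = field(
        default_factory=default_planted_elements)

    def validate(self) -> None:
        for name, v in (("trna_at", self.trna_at), ("rrna_at", self.rrna_at),
                        ("at_rich_at", self.at_rich_at), ("pos3_at", self.pos3_at)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


@dataclass
class SyntheticTruth:
    features: list[GeneFeature]  # shared by every genome (no indels)
    elements: list[dict]  # planted-element records with region + genome coords
    at_rich_span: tuple[int, int]
    partition_at: dict[str, float]  # realized ancestor composition
    config: SynthConfig


# ---------------------------------------------------------------------------
# codon-wise PCG generation

def _codon_weights(pos3_at: float, a_share: float, c_share: float) -> dict[str, float]:
    """Per-codon sampling weight from the third-base preference model."""
    base_w = {
        "A": pos3_at * a_share,
        "T": pos3_at * (1 - a_share),
        "C": (1 - pos3_at) * c_share,
        "G": (1 - pos3_at) * (1 - c_share),
    }
    weights: dict[str, float] = {}
    for fam, codons in synonymous_families().items():
        ends = {c[2] for c in codons}
        norm = sum(base_w[e] for e in ends)
        for c in codons:
            share = base_w[c[2]] / norm
            n_same_end = sum(cc[2] == c[2] for cc in codons)
            weights[c] = share / n_same_end
    return weights


def _family_choice(rng: np.random.Generator, aa: str,
                   weights: dict[str, float]) -> str:
    fams = synonymous_families()
    if aa == "S":
        fam = "S_AGN" if rng.random() < 0.5 else "S_UCN"
    else:
        fam = aa
    codons = fams[fam]
    w = np.array([weights[c] for c in codons])
    return codons[rng.choice(len(codons), p=w / w.sum())]


def draw_pcg(rng: np.random.Generator, n_codons: int, pos3_at: float,
             a_share: float, c_share: float, stop: str = "TAA") -> str:
    """One protein-coding sequence: ATG + codon-wise draws + stop.

    ``stop`` may be 'TAA', 'TAG', or a truncated 'T'/'TA'.
    """
    weights = _codon_weights(pos3_at, a_share, c_share)
    aas = list(AA_FREQS)
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    idx = rng.choice(len(aas), size=max(n_codons - 1, 0), p=probs)
    codons = ["ATG"] + [_family_choice(rng, aas[i], weights) for i in idx]
    return "".join(codons) + stop


def _mutate_pcg(rng: np.random.Generator, dna: str, syn_rate: float,
                nonsyn_rate: float, weights: dict[str, float]) -> str:
    """Codon-wise substitution process (never creates internal stops)."""
    fams = synonymous_families()
    aas = list(AA_FREQS)
    codons = [dna[i : i + 3] for i in range(0, len(dna) - len(dna) % 3, 3)]
    tail = dna[len(codons) * 3 :]
    out = []
    for k, codon in enumerate(codons):
        if k == 0 or codon not in CODON_TO_AA:  # keep start codon and stop
            out.append(codon)
            continue
        r = rng.random()
        if r < syn_rate:
            fam = fams[_fam_label(codon)]
            alts = [c for c in fam if c != codon]
            if alts:
                codon = alts[rng.integers(len(alts))]
        elif r < syn_rate + nonsyn_rate:
            aa = CODON_TO_AA[codon]
            new_aa = aas[rng.integers(len(aas))]
            while new_aa == aa:
                new_aa = aas[rng.integers(len(aas))]
            codon = _family_choice(rng, new_aa, weights)
        out.append(codon)
    return "".join(out) + tail


def _fam_label(codon: str) -> str:
    aa = CODON_TO_AA[codon]
    if aa == "S":
        return "S_AGN" if codon.startswith("AG") else "S_UCN"
    return aa


def _draw_rna(rng: np.random.Generator, length: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _mutate_sites(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# AT-rich region assembly

def _realize_element(rng: np.random.Generator,
                     el: PlantedElement) -> tuple[list[tuple[str, str]], dict]:
    """Realize a planted element as tagged segments plus a truth record.

    Segments are (tag, sequence) pairs concatenated in order; tags are
    ``core``, ``flank5``, ``flank3`` or ``guard``.  Guard bases stop
    the scanners from extending a planted span into the background, so
    recorded coordinates are exactly maximal.
    """
    p = el.params
    rec: dict = {"kind": el.kind, "position": el.position}
    if el.kind == "t_stretch_major":
        length = int(p.get("length", 12))
        core = "T" * length
        rec["length"] = length
        left, right = "A", "A"
    elif el.kind == "t_stretch_minor":
        length = int(p.get("length", 9))
        core = "A" * length
        rec["length"] = length
        left, right = "T", "T"
    elif el.kind == "microsatellite_AT":
        n = int(p.get("n", 5))
        core = "AT" * n
        rec["n"] = n
        left, right = "G", "G"
    elif el.kind == "motif":
        core = p["seq"]
        rec["seq"] = core
        left = right = ""
    elif el.kind == "hairpin":
        core, stem_len, loop_len = _make_hairpin(rng, p.get("stem", 4),
                                                 p.get("loop", 5))
        rec["stem"], rec["loop"] = stem_len, loop_len
        left, right = "A", "A"  # A cannot pair with A: no outward stem growth
    elif el.kind == "tandem_repeat":
        unit = p.get("unit") or _draw_unit(rng, int(p.get("period", 20)),
                                           float(p.get("at", 0.9)))
        copies = float(p.get("copies", 2.0))
        mut = int(p.get("mutations_per_copy", 0))
        core = _make_array(rng, unit, copies, mut)
        rec.update(unit=unit, period=len(unit),
                   copies=round(len(core) / len(unit), 1))
        pp = len(unit)
        left = next(b for b in "GCAT" if b != core[pp - 1])
        # three consecutive period-mismatching bases: the extension
        # scanner stops on a mismatch streak, so the call ends exactly
        # at the array boundary
        right = "".join(
            next(b for b in "GCAT" if b != core[(len(core) + k - pp) % len(core)])
            for k in range(3)
        )
    else:
        raise ValueError(f"unknown planted element kind {el.kind!r}")
    rec["seq"] = core

    segments: list[tuple[str, str]] = []
    if "flank5" in p:
        f5 = p["flank5"]
        rec["flank5"] = f5
        segments.append(("flank5", f5))
        if left and f5 and f5[-1] != _first_run_base(core):
            left = ""  # the motif itself already breaks the run
    if left:
        segments.append(("guard", left))
    segments.append(("core", core))
    if "flank3" in p:
        f3 = p["flank3"]
        if f3 == "hairpin":
            hp, sl, ll = _make_hairpin(rng, p.get("stem", 4), p.get("loop", 5))
            rec["flank3"] = hp
            rec["flank3_stem"], rec["flank3_loop"] = sl, ll
            if right:
                segments.append(("guard", right))
            segments.append(("flank3", hp))
            segments.append(("guard", "A"))  # blocks outward stem extension
            return segments, rec
        rec["flank3"] = f3
        if right and f3 and f3[0] != _first_run_base(core):
            right = ""
        if right:
            segments.append(("guard", right))
        segments.append(("flank3", f3))
        return segments, rec
    if right:
        segments.append(("guard", right))
    return segments, rec


def _first_run_base(core: str) -> str:
    return core[0] if core else ""


def _draw_unit(rng: np.random.Generator, period: int, at: float) -> str:
    for _ in range(200):
        unit = _draw_rna(rng, period, at)
        half = period // 2
        if half and _hamming(unit[:half], unit[half : 2 * half]) >= max(1, half // 3):
            if unit[0] != unit[-1]:
                return unit
    raise RuntimeError("could not draw a non-degenerate repeat unit")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _make_array(rng: np.random.Generator, unit: str, copies: float, mut: int) -> str:
    p = len(unit)
    total = int(round(copies * p))
    n_full = math.ceil(total / p)
    segs = []
    for k in range(n_full):
        seg = list(unit)
        if k > 0 and mut > 0:
            for pos in rng.choice(p, size=min(mut, p), replace=False):
                alts = [b for b in "ACGT" if b != seg[pos]]
                seg[pos] = alts[rng.integers(3)]
        segs.append("".join(seg))
    return "".join(segs)[:total]


def _make_hairpin(rng: np.random.Generator, stem, loop) -> tuple[str, int, int]:
    if isinstance(stem, str):
        stem_seq = stem
    else:
        stem_seq = _draw_rna(rng, int(stem), 0.5)
    if isinstance(loop, str):
        loop_seq = loop
    else:
        loop_seq = _draw_rna(rng, int(loop), 0.8)
        while _WC[loop_seq[0]] == loop_seq[-1]:  # no inward stem extension
            loop_seq = _draw_rna(rng, int(loop), 0.8)
    return stem_seq + loop_seq + revcomp(stem_seq), len(stem_seq), len(loop_seq)


_POS_FRAC = {"5'": 0.08, "M": 0.45, "3'": 0.78}


def _build_at_rich(rng: np.random.Generator, cfg: SynthConfig,
                   background_at: float) -> tuple[str, list[dict]]:
    L = cfg.at_rich_length
    region = list(_draw_rna(rng, L, background_at))
    occupied: list[tuple[int, int]] = []
    records: list[dict] = []
    for el in cfg.planted_elements:
        segments, rec = _realize_element(rng, el)
        block = "".join(s for _, s in segments)
        lead = 0  # offset of the core within the block
        for tag, s in segments:
            if tag == "core":
                break
            lead += len(s)
        if isinstance(el.position, int):
            want = el.position - 1 - lead
        else:
            want = int(_POS_FRAC[el.position] * L)
        off = _place(occupied, want, len(block), L, el)
        region[off : off + len(block)] = block
        cur = off
        for tag, s in segments:
            if tag == "core":
                rec["start"], rec["end"] = cur + 1, cur + len(s)
            elif tag in ("flank5", "flank3"):
                rec[f"{tag}_start"], rec[f"{tag}_end"] = cur + 1, cur + len(s)
            cur += len(s)
        records.append(rec)
    return "".join(region), records


def _place(occupied: list[tuple[int, int]], want: int, size: int, L: int,
           el: PlantedElement) -> int:
    off = max(0, min(want, L - size))
    for _ in range(L):
        span = (off, off + size + 1)  # +1 spacer so guard bases never touch
        if off + size > L:
            break
        if all(span[1] <= s or span[0] >= e for s, e in occupied):
            occupied.append(span)
            return off
        off = max(e for s, e in occupied if not (span[1] <= s or span[0] >= e))
    raise ValueError(f"cannot place planted element {el.kind} (size {size}) "
                     f"in an AT-rich region of {L} bp")


# ---------------------------------------------------------------------------
# clade assembly

def generate_clade(config: SynthConfig) -> tuple[list[Mitogenome], SyntheticTruth]:
    """Generate a clade of related mitogenomes plus their ground truth.

    Deterministic given the config seed.  All genomes share the gene
    order and coordinates (the substitution process has no indels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    order = canonical_gene_order()

    if config.genome_length is not None:
        fixed = _fixed_length(config)
        at_len = config.genome_length - fixed
        if at_len < 2 * 60:
            raise ValueError(
                f"genome_length {config.genome_length} leaves only {at_len} bp "
                "for the AT-rich region")
        config = replace(config, at_rich_length=at_len, genome_length=None)

    # --- ancestor parts, in coding orientation
    anc: dict[str, str] = {}
    for name, kind, strand in order:
        if kind == "PCG":
            stop = config.incomplete_stops.get(name, "TAA")
            a_share = (config.pos3_a_share_major if strand == "major"
                       else config.pos3_a_share_minor)
            c_share = (config.pos3_c_share_major if strand == "major"
                       else config.pos3_c_share_minor)
            anc[name] = draw_pcg(rng, config.pcg_codons[name], config.pos3_at,
                                 a_share, c_share, stop)
        elif kind == "tRNA":
            anc[name] = _draw_rna(rng, config.trna_length, config.trna_at)
        elif kind == "rRNA":
            anc[name] = _draw_rna(rng, config.rrna_lengths[name], config.rrna_at)

    at_bg = _background_at(config, anc, rng)
    at_rich_seq, element_records = _build_at_rich(rng, config, at_bg)
    anc[AT_RICH_NAME] = at_rich_seq

    # --- feature map (identical across the clade)
    features: list[GeneFeature] = []
    pos = 1
    for name, kind, strand in order:
        seq = anc[name]
        if name == "ND1":  # conserved spacer precedes ND1 (after trnS_UCN)
            pos += len(config.spacer_trnS_ND1)
        end = pos + len(seq) - 1
        features.append(GeneFeature(name, kind, strand if kind != "AT_rich" else "major",
                                    pos, end, False, 0))
        pos = end + 1
    genome_len = pos - 1
    at_feat = next(f for f in features if f.kind == "AT_rich")

    # --- genomes
    genomes: list[Mitogenome] = []
    weights_major = _codon_weights(config.pos3_at, config.pos3_a_share_major,
                                   config.pos3_c_share_major)
    weights_minor = _codon_weights(config.pos3_at, config.pos3_a_share_minor,
                                   config.pos3_c_share_minor)
    for g in range(config.n_genomes):
        parts: list[str] = []
        for name, kind, strand in order:
            seq = anc[name]
            if g > 0:  # genome 0 is the ancestor itself
                seq = _derive(rng, name, kind, strand, seq, config,
                              weights_major, weights_minor, element_records)
            if name == "ND1":
                spacer = config.spacer_trnS_ND1
                if g > 0 and config.spacer_mutations:
                    spacer = _substitute_n(rng, spacer, config.spacer_mutations)
                parts.append(spacer)
            parts.append(seq if strand == "major" or kind == "AT_rich"
                         else revcomp(seq))
        sequence = "".join(parts)
        assert len(sequence) == genome_len
        genomes.append(Mitogenome(f"SYN{g+1:02d}", sequence, True, list(features)))

    for rec in element_records:
        rec["genome_start"] = at_feat.start + rec["start"] - 1
        rec["genome_end"] = at_feat.start + rec["end"] - 1

    truth = SyntheticTruth(
        features=features,
        elements=element_records,
        at_rich_span=(at_feat.start, at_feat.end),
        partition_at=_partition_at(anc, order),
        config=config,
    )
    return genomes, truth


def _fixed_length(config: SynthConfig) -> int:
    n = 0
    for name, kind, strand in canonical_gene_order():
        if kind == "PCG":
            stop = config.incomplete_stops.get(name, "TAA")
            n += 3 * config.pcg_codons[name] + len(stop)
        elif kind == "tRNA":
            n += config.trna_length
        elif kind == "rRNA":
            n += config.rrna_lengths[name]
    return n + len(config.spacer_trnS_ND1)


def _background_at(config: SynthConfig, anc: dict[str, str],
                   rng: np.random.Generator) -> float:
    """AT fraction for the AT-rich background, calibrated to hit the
    whole-genome target when one is configured."""
    if config.genome_at_target is None:
        return config.at_rich_at
    drawn = "".join(anc.values()) + config.spacer_trnS_ND1
    at_now = sum(drawn.count(b) for b in "AT")
    total = len(drawn) + config.at_rich_length
    # planted elements are overwhelmingly A/T; treat the whole region as tunable
    need = config.genome_at_target * total - at_now
    frac = need / config.at_rich_length
    return float(min(max(frac, 0.02), 1.0))


def _derive(rng, name, kind, strand, seq, config: SynthConfig,
            w_major, w_minor, element_records) -> str:
    if kind == "PCG":
        w = w_major if strand == "major" else w_minor
        return _mutate_pcg(rng, seq, config.pcg_syn_rate, config.pcg_nonsyn_rate, w)
    if kind == "tRNA":
        rate = config.rna_site_rate
        if strand == "minor":
            rate *= config.minor_trna_rate_multiplier
        return _mutate_sites(rng, seq, rate)
    if kind == "rRNA":
        return _mutate_sites(rng, seq, config.rna_site_rate)
    if kind == "AT_rich":
        protected = np.zeros(len(seq), dtype=bool)
        for rec in element_records:
            protected[rec["start"] - 1 : rec["end"]] = True
            for tag in ("flank5", "flank3"):
                if f"{tag}_start" in rec:
                    protected[rec[f"{tag}_start"] - 1 : rec[f"{tag}_end"]] = True
        chars = list(_mutate_sites(rng, seq, config.at_rich_background_rate))
        for i in np.nonzero(protected)[0]:
            chars[i] = seq[i]
        if config.element_mutation_rate > 0:
            for rec in element_records:
                sub = _mutate_sites(rng, seq[rec["start"] - 1 : rec["end"]],
                                    config.element_mutation_rate)
                chars[rec["start"] - 1 : rec["end"]] = sub
        return "".join(chars)
    return seq


def _substitute_n(rng: np.random.Generator, seq: str, n: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        alts = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alts[rng.integers(3)]
    return "".join(chars)


def _partition_at(anc: dict[str, str], order) -> dict[str, float]:
    def at(s: str) -> float:
        return (s.count("A") + s.count("T")) / len(s)

    pcg = "".join(anc[n] for n, k, s in order if k == "PCG")
    trna = "".join(anc[n] for n, k, s in order if k == "tRNA")
    rrna = "".join(anc[n] for n, k, s in order if k == "rRNA")
    whole = "".join(anc.values())
    return {"PCGs": at(pcg), "tRNAs": at(trna), "rRNAs": at(rrna),
            "AT_rich": at(anc[AT_RICH_NAME]), "whole_genome": at(whole)}


# ---------------------------------------------------------------------------
# small stand-alone simulators for statistical tests

def simulate_codon_alignment(
    rng: np.random.Generator,
    n_codons: int,
    n_taxa: int,
    syn_rate: float,
    nonsyn_rate: float,
    pos3_at: float = 0.88,
    a_share: float = 0.65,
    c_share: float = 0.65,
) -> dict[str, str]:
    """Ancestor + independently derived taxa, as coding DNA strings."""
    anc = draw_pcg(rng, n_codons, pos3_at, a_share, c_share)
    weights = _codon_weights(pos3_at, a_share, c_share)
    return {
        f"t{i+1}": _mutate_pcg(rng, anc, syn_rate, nonsyn_rate, weights)
        for i in range(n_taxa)
    }


# ---------------------------------------------------------------------------
# fixture bundle

def write_fixture_bundle(genomes: list[Mitogenome], truth: SyntheticTruth,
                         outdir: str | Path) -> list[Path]:
    """GenBank + FASTA per genome, truth tables as TSV, config manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for g in genomes:
        gb = outdir / f"{g.id}.gb"
        fa = outdir / f"{g.id}.fasta"
        write_genbank(g, gb)
        write_fasta(g, fa)
        written += [gb, fa]

    feats = outdir / "truth_features.tsv"
    with open(feats, "w") as fh:
        fh.write("gene\tkind\tstrand\tstart\tend\n")
        for f in truth.features:
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{f.start}\t{f.end}\n")
    written.append(feats)

    els = outdir / "truth_elements.tsv"
    with open(els, "w") as fh:
        fh.write("kind\tposition\tstart\tend\tgenome_start\tgenome_end\tdetails\n")
        for rec in truth.elements:
            details = {k: v for k, v in rec.items()
                       if k not in ("kind", "position", "start", "end",
                                    "genome_start", "genome_end")}
            fh.write("\t".join([
                rec["kind"], str(rec["position"]), str(rec["start"]),
                str(rec["end"]), str(rec["genome_start"]),
                str(rec["genome_end"]), json.dumps(details, sort_keys=True),
            ]) + "\n")
    written.append(els)

    manifest = outdir / "config.txt"
    with open(manifest, "w") as fh:
        cfg = asdict(truth.config)
        elements = cfg.pop("planted_elements")
        for key in sorted(cfg):
            fh.write(f"{key} = {json.dumps(cfg[key], sort_keys=True)}\n")
        for i, el in enumerate(elements):
            fh.write(f"planted_element_{i} = {json.dumps(el, sort_keys=True)}\n")
    written.append(manifest)
    return written
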