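"""Rule-based scanner for control-region (AT-rich region) elements.

The mitochondrial control region carries replication/transcription
signals that this module detects with explicit, parameterised rules:

* perfect T-stretches: maximal runs of T on the major strand
  (default >= 10 bp) and of A on the major strand, i.e. T on the minor
  strand (default >= 8 bp);
* (AT)n microsatellites (default n >= 5), both phases scanned, one hit
  per locus;
* tandem repeats: a Hamming-extension scanner over candidate periods
  with per-adjacent-copy identity, copy-number and alignment-score
  thresholds, reporting consensus unit, copy number, AT% and mean
  adjacent-copy identity (the Table-style repeat statistics);
* fixed-offset flanking-motif consensus around an anchor T-stretch,
  with X wildcards at columns below the agreement threshold;
* perfect Watson-Crick stem-loops (default stem >= 4 bp, loop 3-7 nt);
* the conserved spacer motif check for the trnS(UCN)-ND1 intergenic
  gap (motif TACTAA).

All coordinates are 1-based inclusive on the major strand of the
region; BED-style exports are 0-based half-open.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._code import revcomp

__all__ = [
    "TStretchHit",
    "MicrosatelliteHit",
    "RepeatHit",
    "HairpinHit",
    "MotifConsensus",
    "find_t_stretches",
    "find_microsatellites",
    "find_tandem_repeats",
    "flank_consensus",
    "find_hairpins",
    "spacer_motif_check",
    "scan_t_rich_window",
    "hits_to_bed",
]


@dataclass(frozen=True)
class TStretchHit:
    strand: str  # major | minor
    start: int  # 1-based inclusive, major-strand coordinates
    end: int
    length: int


@dataclass(frozen=True)
class MicrosatelliteHit:
    motif: str
    n: int
    start: int
    end: int


@dataclass(frozen=True)
class RepeatHit:
    id: str
    consensus_size: int
    copy_number: float
    start: int
    end: int
    position_class: str  # 5' | M | 3'
    at_percent: float
    percent_matches: float
    consensus: str
    score: int


@dataclass(frozen=True)
class HairpinHit:
    stem_len: int
    loop_len: int
    start: int  # span of the whole stem-loop
    end: int
    perfect_stem: bool = True


@dataclass
class MotifConsensus:
    windows: dict[str, str]  # genome id -> window sequence
    consensus: str
    column_agreement: list[float]
    side: str
    window: int


# ---------------------------------------------------------------------------
# T-stretches

def find_t_stretches(region: str, min_major: int = 10,
                     min_minor: int = 8) -> list[TStretchHit]:
    """Maximal perfect T runs on both strands of a major-strand region.

    Minor-strand stretches are runs of A on the major strand; both are
    reported on major-strand coordinates.
    """
    hits: list[TStretchHit] = []
    for base, strand, min_len in (("T", "major", min_major), ("A", "minor", min_minor)):
        for m in re.finditer(f"{base}+", region):
            length = m.end() - m.start()
            if length >= min_len:
                hits.append(TStretchHit(strand, m.start() + 1, m.end(), length))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# microsatellites

def find_microsatellites(region: str, motif: str = "AT",
                         min_n: int = 5) -> list[MicrosatelliteHit]:
    """Maximal tandem runs of a dinucleotide motif (both phases).

    Overlapping phase variants of the same locus are reported once,
    keeping the longer run (ties: the earlier start).
    """
    if len(motif) != 2:
        raise ValueError("microsatellite motif must be a dinucleotide")
    phases = {motif, motif[1] + motif[0]}
    raw: list[MicrosatelliteHit] = []
    for unit in sorted(phases):
        for m in re.finditer(f"(?:{unit})+", region):
            n = (m.end() - m.start()) // 2
            if n >= min_n:
                raw.append(MicrosatelliteHit(unit, n, m.start() + 1, m.start() + 2 * n))
    raw.sort(key=lambda h: (-h.n, h.start))
    kept: list[MicrosatelliteHit] = []
    for h in raw:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# tandem repeats

MATCH_SCORE = 2
MISMATCH_SCORE = -7


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def position_class(start: int, end: int, region_len: int) -> str:
    """5'/M/3' classification by span midpoint in thirds of the region."""
    mid = (start + end) / 2
    if mid <= region_len / 3:
        return "5'"
    if mid <= 2 * region_len / 3:
        return "M"
    return "3'"


def find_tandem_repeats(
    region: str,
    min_period: int = 10,
    max_period: int = 60,
    min_identity: float = 0.70,
    min_copies: float = 1.8,
    min_score: int = 16,
) -> list[RepeatHit]:
    """Detect tandem repeats by Hamming extension over candidate periods.

    For every period p and left-maximal anchor, the array is extended
    base by base while each base matches the base one period earlier,
    tolerating isolated mismatches but stopping at a run of more than
    ``max_streak`` consecutive mismatches; trailing mismatches are then
    trimmed so the array ends on a match.  A call is reported when copy
    number >= ``min_copies``, mean adjacent-copy identity >=
    ``min_identity`` and the alignment score (+2 per match, -7 per
    mismatch over adjacent-copy comparisons) reaches ``min_score`` —
    the score term keeps single chance 10-mer matches in AT-biased
    sequence from being called.  Overlapping calls whose periods are
    harmonics of each other are merged, keeping the highest (identity,
    then length) call; non-harmonic overlaps (e.g. genuinely nested
    repeat families) are all reported.
    """
    L = len(region)
    candidates: list[RepeatHit] = []
    for p in range(min_period, min(max_period, L // 2) + 1):
        i = 0
        while i + p < L:
            # left-maximality: skip anchors whose array extends left
            if i > 0 and region[i - 1] == region[i - 1 + p]:
                i += 1
                continue
            end, matches, mismatches, pair_ids = _extend_array(region, i, p)
            span_len = end - i
            copy_number = span_len / p
            if pair_ids and copy_number >= min_copies:
                mean_id = sum(pair_ids) / len(pair_ids)
                score = MATCH_SCORE * matches + MISMATCH_SCORE * mismatches
                if mean_id >= min_identity and score >= min_score:
                    consensus = _consensus_unit(region[i:end], p)
                    at = (consensus.count("A") + consensus.count("T")) / p * 100
                    candidates.append(RepeatHit(
                        "", p, round(copy_number, 1), i + 1, end,
                        position_class(i + 1, end, L), round(at, 2),
                        round(mean_id * 100, 2), consensus, score,
                    ))
            i += 1
    hits = _merge_harmonics(candidates)
    hits.sort(key=lambda h: (h.start, h.consensus_size))
    return [RepeatHit(f"R{k+1}", h.consensus_size, h.copy_number, h.start, h.end,
                      h.position_class, h.at_percent, h.percent_matches,
                      h.consensus, h.score)
            for k, h in enumerate(hits)]


def _extend_array(region: str, i: int, p: int,
                  max_streak: int = 2) -> tuple[int, int, int, list[float]]:
    """Greedy rightward extension of a tandem array anchored at i.

    Returns (exclusive end, matches, mismatches, per-adjacent-copy
    identities) of the trimmed array.
    """
    L = len(region)
    j = i + p
    streak = 0
    while j < L:
        if region[j] == region[j - p]:
            streak = 0
        else:
            streak += 1
            if streak > max_streak:
                break
        j += 1
    end = j
    while end > i + p and region[end - 1] != region[end - 1 - p]:
        end -= 1
    matches = sum(region[k] == region[k - p] for k in range(i + p, end))
    mismatches = (end - i - p) - matches
    pair_ids: list[float] = []
    for m0 in range(i + p, end, p):
        m1 = min(m0 + p, end)
        m = sum(region[k] == region[k - p] for k in range(m0, m1))
        pair_ids.append(m / (m1 - m0))
    return end, matches, mismatches, pair_ids


def _consensus_unit(array: str, p: int) -> str:
    cols: list[dict[str, int]] = [dict() for _ in range(p)]
    for idx, ch in enumerate(array):
        d = cols[idx % p]
        d[ch] = d.get(ch, 0) + 1
    return "".join(max(sorted(d), key=lambda b: d[b]) for d in cols)


def _harmonic(p: int, q: int) -> bool:
    lo, hi = sorted((p, q))
    r = hi % lo
    return r <= 1 or r >= lo - 1


def _merge_harmonics(candidates: list[RepeatHit]) -> list[RepeatHit]:
    order = sorted(candidates,
                   key=lambda h: (-h.percent_matches, -(h.end - h.start), h.start))
    kept: list[RepeatHit] = []
    for h in order:
        clash = any(
            h.start <= k.end and k.start <= h.end and
            (h.consensus_size == k.consensus_size or
             _harmonic(h.consensus_size, k.consensus_size))
            for k in kept
        )
        if not clash:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# flanking-motif consensus

def longest_stretch(hits: list[TStretchHit], strand: str = "major") -> TStretchHit | None:
    """Default anchor selector: the longest stretch on the given strand."""
    pool = [h for h in hits if h.strand == strand]
    return max(pool, key=lambda h: (h.length, -h.start)) if pool else None


def flank_consensus(
    regions: dict[str, str],
    side: str,
    window: int,
    threshold: float = 0.8,
    anchor_strand: str = "major",
    min_major: int = 10,
    min_minor: int = 8,
) -> MotifConsensus:
    """Consensus of fixed windows flanking an anchor T-stretch.

    Windows are stacked without alignment at a fixed offset from the
    stretch boundary (``side`` is ``5'`` or ``3'`` on major-strand
    coordinates); columns reaching ``threshold`` agreement emit the
    majority base, others emit X.  Genomes lacking the anchor (or the
    full window) are skipped with a warning.
    """
    if side not in ("5'", "3'"):
        raise ValueError("side must be \"5'\" or \"3'\"")
    windows: dict[str, str] = {}
    for gid, region in regions.items():
        anchor = longest_stretch(find_t_stretches(region, min_major, min_minor),
                                 anchor_strand)
        if anchor is None:
            warnings.warn(f"{gid}: no {anchor_strand}-strand T-stretch; skipped")
            continue
        if side == "5'":
            lo, hi = anchor.start - 1 - window, anchor.start - 1
        else:
            lo, hi = anchor.end, anchor.end + window
        if lo < 0 or hi > len(region):
            warnings.warn(f"{gid}: flank window outside the region; skipped")
            continue
        windows[gid] = region[lo:hi]
    if not windows:
        raise ValueError("anchor T-stretch missing in every genome")
    consensus = []
    agreement = []
    rows = list(windows.values())
    for col in range(window):
        counts: dict[str, int] = {}
        for r in rows:
            counts[r[col]] = counts.get(r[col], 0) + 1
        base = max(sorted(counts), key=lambda b: counts[b])
        frac = counts[base] / len(rows)
        agreement.append(frac)
        consensus.append(base if frac >= threshold else "X")
    return MotifConsensus(windows, "".join(consensus), agreement, side, window)


# ---------------------------------------------------------------------------
# hairpins

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def find_hairpins(flank: str, stem_min: int = 4, loop_min: int = 3,
                  loop_max: int = 7) -> list[HairpinHit]:
    """Perfect Watson-Crick stem-loops in a flanking sequence.

    Exhaustive search for stems of length >= ``stem_min`` enclosing a
    loop of ``loop_min``..``loop_max`` nt; maximal stems only, ordered
    longest-stem-first then smallest-loop (overlapping structures are
    all reported — AT-rich sequence is highly self-complementary and
    alternative foldings are genuine).
    """
    L = len(flank)
    candidates: list[HairpinHit] = []
    for loop in range(loop_min, loop_max + 1):
        for j in range(L - loop + 1):  # 0-based start of the loop
            k = 0  # grow the stem outward around the loop
            while (j - k - 1 >= 0 and j + loop + k < L
                   and _WC.get(flank[j - k - 1]) == flank[j + loop + k]):
                k += 1
            if k >= stem_min:
                candidates.append(HairpinHit(k, loop, j - k + 1, j + loop + k))
    candidates.sort(key=lambda h: (-h.stem_len, h.loop_len, h.start))
    return candidates


# ---------------------------------------------------------------------------
# spacer motif

def spacer_motif_check(spacers: dict[str, str], motif: str = "TACTAA") -> dict:
    """Check the conserved trnS(UCN)-ND1 spacer across genomes.

    Reports per-genome spacer length, presence of ``motif``, and the
    Hamming distance to the column-majority consensus of the modal
    spacer length (None for genomes of a different length).
    """
    if not spacers:
        raise ValueError("no spacers supplied")
    lengths = {g: len(s) for g, s in spacers.items()}
    modal_len = max(sorted(set(lengths.values())),
                    key=lambda n: sum(v == n for v in lengths.values()))
    modal = {g: s for g, s in spacers.items() if len(s) == modal_len}
    consensus = "".join(
        max(sorted({r[c] for r in modal.values()}),
            key=lambda b: sum(r[c] == b for r in modal.values()))
        for c in range(modal_len)
    )
    mismatches = {
        g: (sum(a != b for a, b in zip(s, consensus)) if len(s) == modal_len else None)
        for g, s in spacers.items()
    }
    return {
        "lengths": lengths,
        "motif": motif,
        "motif_present": {g: motif in s for g, s in spacers.items()},
        "consensus": consensus,
        "mismatches": mismatches,
    }


def scan_t_rich_window(region: str, window: int = 10, max_other: int = 2,
                       zone: int = 30, strand: str = "minor") -> dict | None:
    """Thymine-rich (on the given strand) window near the region 3' end.

    Emulates the near-trnI scan: within the last ``zone`` nt of the
    region the best ``window``-nt stretch with at most ``max_other``
    non-T bases on the requested strand is reported (minor-strand T is
    major-strand A).  Returns None when no window qualifies.
    """
    base = "A" if strand == "minor" else "T"
    lo = max(0, len(region) - zone)
    best = None
    for i in range(lo, len(region) - window + 1):
        w = region[i : i + window]
        other = window - w.count(base)
        if other <= max_other and (best is None or other < best["non_t"]):
            best = {"start": i + 1, "end": i + window, "non_t": other,
                    "strand": strand, "window": w}
    return best


# ---------------------------------------------------------------------------
# planted-element verification

def recover_planted_elements(region: str, records: list[dict],
                             **scanner_kwargs) -> tuple[int, int]:
    """Score exact recovery of planted elements by the scanners.

    ``records`` are synthetic-truth element records (region-relative
    1-based coordinates).  Returns (recovered, total); an element
    counts as recovered only when a hit reproduces its coordinates and
    defining lengths exactly.
    """
    stretches = find_t_stretches(region,
                                 scanner_kwargs.get("min_major", 10),
                                 scanner_kwargs.get("min_minor", 8))
    micros = find_microsatellites(region, min_n=scanner_kwargs.get("min_n", 5))
    repeats = find_tandem_repeats(region)
    recovered = total = 0
    for rec in records:
        kind = rec["kind"]
        if kind in ("t_stretch_major", "t_stretch_minor"):
            strand = "major" if kind.endswith("major") else "minor"
            total += 1
            recovered += any(h.strand == strand and h.start == rec["start"]
                             and h.end == rec["end"] for h in stretches)
        elif kind == "microsatellite_AT":
            total += 1
            recovered += any(h.start == rec["start"] and h.end == rec["end"]
                             and h.n == rec["n"] for h in micros)
        elif kind == "tandem_repeat":
            total += 1
            recovered += any(h.start == rec["start"] and h.end == rec["end"]
                             and h.consensus_size == rec["period"]
                             for h in repeats)
        elif kind == "hairpin":
            total += 1
            window = region[rec["start"] - 2 : rec["end"] + 1]
            recovered += any(h.stem_len == rec["stem"] and h.loop_len == rec["loop"]
                             for h in find_hairpins(window))
        if "flank3_stem" in rec:  # hairpin planted 3' of a T-stretch
            total += 1
            window = region[rec["end"] : rec["end"] + 30]
            recovered += any(h.stem_len == rec["flank3_stem"]
                             and h.loop_len == rec["flank3_loop"]
                             for h in find_hairpins(window))
    return recovered, total


# ---------------------------------------------------------------------------
# exports

def hits_to_bed(region_name: str, hits: list) -> pd.DataFrame:
    """0-based half-open BED-like table of any scanner hits."""
    rows = []
    for h in hits:
        kind = type(h).__name__
        name = getattr(h, "id", "") or getattr(h, "motif", "") or kind
        rows.append({"chrom": region_name, "start": h.start - 1, "end": h.end,
                     "name": f"{kind}:{name}"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
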