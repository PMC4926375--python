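"""Control-region element scanners: stretches, microsatellites, repeats,
flank consensus, hairpins, the conserved spacer motif."""

import numpy as np
import pytest

from mitocomp._code import revcomp
from mitocomp.at_rich import (find_hairpins, find_microsatellites,
                              find_t_stretches, find_tandem_repeats,
                              flank_consensus, hits_to_bed,
                              recover_planted_elements, scan_t_rich_window,
                              spacer_motif_check)
from mitocomp.genome_io import partition_set
from mitocomp.synthetic_mitogenome import SynthConfig, generate_clade


def _random_dna(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))


class TestTStretches:
    def test_major_run_with_flanks(self):
        hits = find_t_stretches("G" + "T" * 12 + "G")
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.start, h.end, h.length) == ("major", 2, 13, 12)

    def test_below_threshold_not_reported(self):
        assert find_t_stretches("T" * 9) == []

    def test_minor_strand_threshold_is_eight(self):
        hits = find_t_stretches("G" + "A" * 8 + "G")
        assert [h.strand for h in hits] == ["minor"]

    def test_strand_consistency_under_revcomp(self):
        # symmetric thresholds so the mirrored hit sets are comparable
        rng = np.random.default_rng(1)
        for _ in range(20):
            region = _random_dna(rng, 400, (0.4, 0.1, 0.1, 0.4))
            fwd = find_t_stretches(region, min_major=8, min_minor=8)
            rev = find_t_stretches(revcomp(region), min_major=8, min_minor=8)
            L = len(region)
            mirrored = sorted(
                ("minor" if h.strand == "major" else "major",
                 L - h.end + 1, L - h.start + 1) for h in fwd)
            assert mirrored == sorted((h.strand, h.start, h.end) for h in rev)


class TestMicrosatellites:
    def test_five_units_reported(self):
        hits = find_microsatellites("ATATATATAT")
        assert len(hits) == 1
        assert (hits[0].n, hits[0].start, hits[0].end) == (5, 1, 10)

    def test_four_units_below_threshold(self):
        assert find_microsatellites("ATATATAT") == []

    def test_phase_variants_reported_once(self):
        hits = find_microsatellites("G" + "TA" * 7 + "G")
        assert len(hits) == 1
        assert hits[0].n == 7

    def test_planted_recovery(self, clade_genomes, clade_truth):
        region = partition_set(clade_genomes[0]).at_rich
        rec = next(r for r in clade_truth.elements
                   if r["kind"] == "microsatellite_AT")
        hits = find_microsatellites(region)
        assert any(h.start == rec["start"] and h.end == rec["end"]
                   and h.n == rec["n"] for h in hits)


class TestTandemRepeats:
    def test_perfect_three_copies(self):
        hits = find_tandem_repeats("ACGTACGTACGT", min_period=4)
        assert len(hits) == 1
        h = hits[0]
        assert (h.consensus_size, h.copy_number, h.percent_matches) == (4, 3.0, 100.0)
        assert h.consensus == "ACGT"

    def test_random_sequence_negative_control(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            assert find_tandem_repeats(_random_dna(rng, 500)) == []

    def test_planted_mutated_repeat_recovered(self):
        from mitocomp.synthetic_mitogenome import PlantedElement
        hits_ok = 0
        for seed in range(10):
            cfg = SynthConfig(seed=seed, n_genomes=1, planted_elements=[
                PlantedElement("tandem_repeat", "M",
                               {"period": 22, "copies": 1.9,
                                "mutations_per_copy": 2})])
            genomes, truth = generate_clade(cfg)
            region = partition_set(genomes[0]).at_rich
            rec = truth.elements[0]
            for h in find_tandem_repeats(region):
                if (abs(h.consensus_size - 22) <= 1
                        and abs(h.copy_number - 1.9) <= 0.1
                        and abs(h.start - rec["start"]) <= 2):
                    hits_ok += 1
                    break
        assert hits_ok >= 9

    def test_identity_threshold_monotonicity(self, clade_genomes):
        region = partition_set(clade_genomes[0]).at_rich
        counts = [len(find_tandem_repeats(region, min_identity=t))
                  for t in (0.70, 0.80, 0.90, 1.00)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_hit_spans_index_real_substrings(self, clade_genomes):
        region = partition_set(clade_genomes[0]).at_rich
        for h in find_tandem_repeats(region):
            span = region[h.start - 1 : h.end]
            assert len(span) == h.end - h.start + 1
            # first copy matches the consensus at >= the reported identity
            first = span[: h.consensus_size]
            ident = sum(a == b for a, b in zip(first, h.consensus))
            assert ident / h.consensus_size >= 0.5


class TestFlankConsensus:
    def test_identical_windows(self):
        regions = {f"g{i}": "GG" + "A" * 9 + "GTAA" + "CC" for i in range(3)}
        mc = flank_consensus(regions, "3'", 4, anchor_strand="minor")
        assert mc.consensus == "GTAA"

    def test_wildcard_below_threshold(self):
        # three windows AAAGC/AAATC/AAACC -> AAAXC at 0.8 agreement
        tails = ["AAAGC", "AAATC", "AAACC"]
        regions = {f"g{i}": "GG" + t + "A" * 9 + "G" + "C" * 4
                   for i, t in enumerate(tails)}
        mc = flank_consensus(regions, "5'", 5, anchor_strand="minor")
        assert mc.consensus == "AAAXC"

    def test_planted_flank_motifs_recovered(self, clade_genomes, clade_psets):
        regions = {g.id: clade_psets[g.id].at_rich for g in clade_genomes}
        mc5 = flank_consensus(regions, "5'", 5, anchor_strand="minor")
        mc3 = flank_consensus(regions, "3'", 4, anchor_strand="minor")
        assert mc5.consensus == "AAAGC"
        assert mc3.consensus == "GTAA"

    def test_anchor_missing_everywhere_raises(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                flank_consensus({"g1": "ACGT" * 10}, "3'", 4)


class TestHairpins:
    def test_simple_stem_loop(self):
        hits = find_hairpins("GCGC" + "AAA" + "GCGC")
        assert hits
        assert (hits[0].stem_len, hits[0].loop_len) == (4, 3)
        assert (hits[0].start, hits[0].end) == (1, 11)

    def test_homopolymer_has_no_hairpin(self):
        assert find_hairpins("A" * 11) == []

    def test_planted_stem6_loop5_recovered(self):
        rng = np.random.default_rng(3)
        from mitocomp.synthetic_mitogenome import _make_hairpin
        hp, stem, loop = _make_hairpin(rng, 6, 5)
        flank = "GG" + hp + "GG"
        hits = find_hairpins(flank)
        assert any(h.stem_len == 6 and h.loop_len == 5 and h.start == 3
                   for h in hits)

    def test_ordering_prefers_long_stem_small_loop(self):
        flank = "GCGC" + "AAA" + "GCGC" + "TT" + "GCGCG" + "AAA" + "CGCGC"
        hits = find_hairpins(flank)
        keys = [(-h.stem_len, h.loop_len) for h in hits]
        assert keys == sorted(keys)
        assert any(h.stem_len == 5 and h.loop_len == 3 and h.start == 14
                   for h in hits)


class TestSpacer:
    def test_printed_spacer_length_and_motif(self):
        rep = spacer_motif_check({"Te1": "ATACTAAATTTTATTAA"})
        assert rep["lengths"]["Te1"] == 17
        assert rep["motif_present"]["Te1"] is True

    def test_missing_motif_flagged(self):
        rep = spacer_motif_check({"g": "AAAAAAAAAAAAAAAAA"})
        assert rep["motif_present"]["g"] is False

    def test_one_substitution_from_consensus(self):
        genomes, truth = generate_clade(
            SynthConfig(seed=4, n_genomes=10, spacer_mutations=1))
        spacers = {g.id: partition_set(g).spacer("trnS_UCN", "ND1")
                   for g in genomes}
        rep = spacer_motif_check(spacers)
        mism = [m for m in rep["mismatches"].values() if m is not None]
        assert max(mism) <= 1
        assert rep["consensus"] == truth.config.spacer_trnS_ND1


class TestRecoveryAndExports:
    def test_planted_recovery_full_default_clade(self, clade_genomes, clade_truth):
        region = partition_set(clade_genomes[0]).at_rich
        rec, tot = recover_planted_elements(region, clade_truth.elements)
        assert rec == tot

    def test_bed_is_zero_based_half_open(self):
        hits = find_t_stretches("G" + "T" * 12 + "G")
        bed = hits_to_bed("r", hits)
        assert bed.iloc[0]["start"] == 1 and bed.iloc[0]["end"] == 13

    def test_t_rich_window_near_region_end(self):
        region = "G" * 70 + "AAAATAAAAA" + "GG"
        hit = scan_t_rich_window(region, window=10, max_other=2, zone=15)
        assert hit is not None and hit["non_t"] == 1
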