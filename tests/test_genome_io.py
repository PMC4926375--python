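"""Parsing, extraction and partitioning of annotated mitogenomes."""

import pytest

from mitocomp._code import revcomp, translate
from mitocomp.genome_io import (GeneFeature, GeneLookupError, Mitogenome,
                                ParseError, canonical_name, classify_codons,
                                codon_position_split, extract_gene,
                                feature_table, parse_genbank, partition_set)
from mitocomp.synthetic_mitogenome import SynthConfig, draw_pcg, generate_clade

import numpy as np


def _toy_genome(seq, features):
    return Mitogenome("toy", seq, True, features)


class TestParsing:
    def test_roundtrip_reproduces_truth_features(self, reparsed_genome, small_clade):
        genomes, truth = small_clade
        want = [(f.name, f.kind, f.strand, f.start, f.end) for f in truth.features]
        got = [(f.name, f.kind, f.strand, f.start, f.end)
               for f in reparsed_genome.features]
        assert got == want
        assert reparsed_genome.sequence == genomes[0].sequence

    def test_feature_count_matches_annotation(self, reparsed_genome):
        # 13 PCGs + 22 tRNAs + 2 rRNAs + control region
        assert len(reparsed_genome.features) == 38

    def test_at_rich_is_the_12S_to_trnI_gap(self, reparsed_genome):
        at = reparsed_genome.feature("AT-rich region")
        rrna = reparsed_genome.feature("12S rRNA")
        assert at.start == rrna.end + 1
        assert at.end == reparsed_genome.length  # trnI starts at position 1

    def test_synonym_lookup(self):
        assert canonical_name("COI") == "COX1"
        assert canonical_name("tRNA-Leu(UUR)") == "trnL_UUR"
        assert canonical_name("l-rRNA") == "16S rRNA"
        assert canonical_name("cytochrome b") == "CYTB"
        assert canonical_name("made-up gene") is None

    def test_ambiguity_codes_rejected(self, tmp_path):
        gb = tmp_path / "bad.gb"
        g = Mitogenome("bad", "ACGTRYACGT", True,
                       [GeneFeature("trnI", "tRNA", "major", 1, 10)])
        from mitocomp.genome_io import write_genbank
        write_genbank(g, gb)
        with pytest.raises(ParseError, match="ambiguity"):
            parse_genbank(gb)


class TestExtraction:
    def test_minor_strand_gene_is_reverse_complemented(self):
        g = _toy_genome("TTACAT", [GeneFeature("ND1", "PCG", "minor", 1, 6)])
        assert extract_gene(g, "ND1").dna == "ATGTAA"

    def test_double_revcomp_is_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 200)))
            assert revcomp(revcomp(s)) == s

    def test_incomplete_stop_T(self):
        # length = 1 mod 3, ends in T
        g = _toy_genome("ATGAAAT" + "G",
                        [GeneFeature("COX1", "PCG", "major", 1, 7)])
        gs = extract_gene(g, "COX1")
        assert gs.stop_completion == "T"
        assert classify_codons(gs)[3] == "incomplete-T"

    def test_incomplete_stop_TA(self):
        g = _toy_genome("ATGAAATA", [GeneFeature("COX1", "PCG", "major", 1, 8)])
        gs = extract_gene(g, "COX1")
        assert gs.stop_completion == "TA"
        assert classify_codons(gs)[3] == "incomplete-TA"

    def test_missing_gene_raises_lookup_error(self):
        g = _toy_genome("ACGT", [GeneFeature("trnI", "tRNA", "major", 1, 4)])
        with pytest.raises(GeneLookupError, match="trnI"):
            extract_gene(g, "ND2")

    def test_planted_pcg_recovered_exactly(self, clade_genomes, clade_truth):
        # the generator's coding sequence survives genome assembly + extraction
        genome = clade_genomes[0]
        gs = extract_gene(genome, "ND5")  # minor strand
        assert gs.strand == "minor"
        assert gs.dna.startswith("ATG")
        prot = translate(gs.dna)
        assert prot.endswith("*")
        assert "*" not in prot[:-1]

    @pytest.mark.parametrize("start,cls", [
        ("ATG", "ATN"), ("ATT", "ATN"), ("TTG", "TTG/GTG/GTT"),
        ("GTG", "TTG/GTG/GTT"), ("AAC", "nonstandard"),
    ])
    def test_start_codon_classes(self, start, cls):
        g = _toy_genome(start + "AAATAA",
                        [GeneFeature("ND2", "PCG", "major", 1, 9)])
        assert classify_codons(extract_gene(g, "ND2"))[2] == cls

    def test_stop_class_tag(self):
        g = _toy_genome("ATGAAATAG", [GeneFeature("ND2", "PCG", "major", 1, 9)])
        _, stop, _, stop_class = classify_codons(extract_gene(g, "ND2"))
        assert (stop, stop_class) == ("TAG", "TAG")


class TestCodonPositions:
    def test_direct_indexing(self):
        from mitocomp.genome_io import GeneSequence
        gs = GeneSequence("ND2", "PCG", "major", "ATGGCA")
        assert codon_position_split([gs]) == ("AG", "TC", "GA")

    def test_length_conservation(self, clade_psets):
        ps = clade_psets["SYN01"]
        p1, p2, p3 = codon_position_split(ps.pcgs)
        n_codons = sum(len(g.coding) // 3 for g in ps.pcgs)
        assert len(p1) == len(p2) == len(p3) == n_codons

    def test_planted_pos3_at_content(self):
        rng = np.random.default_rng(5)
        from mitocomp.genome_io import GeneSequence
        dna = draw_pcg(rng, 3500, pos3_at=0.90, a_share=0.65, c_share=0.65)
        gs = GeneSequence("ND2", "PCG", "major", dna)
        p3 = codon_position_split([gs])[2]
        at = (p3.count("A") + p3.count("T")) / len(p3)
        assert abs(at - 0.90) < 0.02


class TestPartitions:
    def test_partition_completeness(self, clade_genomes, clade_psets):
        # genes + spacers tile the genome exactly (no overlaps in synthetic data)
        g = clade_genomes[0]
        ps = clade_psets[g.id]
        gene_len = sum(len(x.dna) for x in ps.pcgs + ps.trnas + ps.rrnas)
        spacer_len = sum(len(s) for _, s in ps.intergenic_spacers)
        assert gene_len + spacer_len + len(ps.at_rich) == g.length

    def test_thirteen_pcgs_split_by_strand(self, clade_psets):
        ps = clade_psets["SYN01"]
        assert len(ps.pcgs) == 13
        assert {g.name for g in ps.pcgs_minor} == {"ND1", "ND4", "ND4L", "ND5"}

    def test_spacer_between_trnS_and_ND1(self, clade_psets, clade_truth):
        ps = clade_psets["SYN01"]
        assert ps.spacer("trnS_UCN", "ND1") == clade_truth.config.spacer_trnS_ND1

    def test_feature_table_columns(self, clade_genomes):
        df = feature_table(clade_genomes[:1])
        assert list(df.columns) == ["genome", "gene", "kind", "strand", "start",
                                    "end", "length", "start_codon", "stop_codon"]
        assert len(df) == 38
        pcgs = df[df.kind == "PCG"]
        assert (pcgs.start_codon == "ATG").all()
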