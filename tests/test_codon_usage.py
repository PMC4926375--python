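"""Codon-usage bias statistics: RSCU, ENC, CBI, correlations."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp._code import SENSE_CODONS, synonymous_families
from mitocomp.codon_usage import (AT_RICH_CODONS, CodonUsageTable, cbi,
                                  correlate, count_codons, enc,
                                  preferred_codons, rscu, summary_row,
                                  usage_long_table)
from mitocomp.genome_io import GeneSequence
from mitocomp.synthetic_mitogenome import draw_pcg


def _oracle_families():
    """Independent family grouping via Biopython translation."""
    fams = {}
    for codon in SENSE_CODONS:
        aa = str(Seq(codon).translate(table=5))
        key = (aa, codon[:2] == "AG") if aa == "S" else aa
        fams.setdefault(key, []).append(codon)
    return fams


def _random_table(rng, max_count=30):
    return CodonUsageTable({c: int(rng.integers(0, max_count))
                            for c in SENSE_CODONS})


class TestCounting:
    def test_stop_codon_excluded(self):
        t = count_codons([GeneSequence("ND2", "PCG", "major", "ATGAAATAA")])
        assert t.counts["ATG"] == 1 and t.counts["AAA"] == 1
        assert t.total == 2

    def test_total_codon_conservation(self, clade_psets):
        ps = clade_psets["SYN01"]
        t = count_codons(ps.pcgs)
        stops = sum(1 for g in ps.pcgs if g.stop_completion == "complete")
        floor_codons = sum(len(g.coding) // 3 for g in ps.pcgs)
        assert t.total == floor_codons - stops  # complete stops counted out

    def test_non_pcg_rejected(self):
        with pytest.raises(ValueError):
            count_codons([GeneSequence("trnI", "tRNA", "major", "ACGACG")])

    def test_family_end_shares_sum_to_one(self, clade_psets):
        t = count_codons(clade_psets["SYN01"].pcgs)
        assert sum(t.family_end_shares.values()) == pytest.approx(1.0)

    def test_at_rich4_share_tracks_codon_model(self):
        rng = np.random.default_rng(3)
        dna = draw_pcg(rng, 4000, pos3_at=0.9, a_share=0.65, c_share=0.65)
        t = count_codons([GeneSequence("ND2", "PCG", "major", dna)])
        assert t.at_rich4_share == pytest.approx(
            sum(t.counts[c] for c in AT_RICH_CODONS) / t.total)


class TestRSCU:
    def test_uniform_family_is_one(self):
        t = CodonUsageTable({c: 5 for c in synonymous_families()["V"]})
        r = rscu(t)
        assert all(r[c] == pytest.approx(1.0) for c in synonymous_families()["V"])

    def test_two_fold_family_counts_3_1(self):
        t = CodonUsageTable({"AAA": 3, "AAG": 1})  # Lys
        r = rscu(t)
        assert r["AAA"] == pytest.approx(1.5)
        assert r["AAG"] == pytest.approx(0.5)

    def test_empty_family_yields_missing(self):
        r = rscu(CodonUsageTable({"AAA": 3}))
        assert math.isnan(r["GGG"])

    def test_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        oracle_fams = _oracle_families()
        for _ in range(100):
            t = _random_table(rng)
            r = rscu(t)
            for codons in oracle_fams.values():
                tot = sum(t.counts[c] for c in codons)
                for c in codons:
                    want = (t.counts[c] * len(codons) / tot) if tot else math.nan
                    if math.isnan(want):
                        assert math.isnan(r[c])
                    else:
                        assert r[c] == pytest.approx(want, abs=1e-12)

    def test_family_sum_equals_family_size(self, clade_psets):
        t = count_codons(clade_psets["SYN01"].pcgs)
        r = rscu(t)
        for fam, codons in synonymous_families().items():
            if sum(t.counts[c] for c in codons):
                assert sum(r[c] for c in codons) == pytest.approx(len(codons))


class TestENC:
    def test_uniform_limit_is_sense_codon_count(self):
        t = CodonUsageTable({c: 100_000 for c in SENSE_CODONS})
        assert enc(t) == pytest.approx(62.0, abs=0.5)

    def test_one_codon_per_family_gives_family_count(self):
        t = CodonUsageTable({codons[0]: 50
                             for codons in synonymous_families().values()})
        assert enc(t) == pytest.approx(21.0)

    def test_bounds_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = CodonUsageTable({c: int(rng.integers(100, 400))
                                 for c in SENSE_CODONS})
            assert 21.0 <= enc(t) <= 62.0

    def test_monotone_in_single_family_bias(self):
        base = {c: 60 for c in SENSE_CODONS}
        vals = []
        fam = synonymous_families()["V"]  # 4-fold valine
        for shift in range(0, 60, 10):
            counts = dict(base)
            counts[fam[0]] += 3 * shift
            for c in fam[1:]:
                counts[c] -= shift
            vals.append(enc(CodonUsageTable(counts)))
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            enc(CodonUsageTable({}))


class TestCBI:
    def test_uniform_usage_gives_zero(self):
        assert cbi(CodonUsageTable({c: 10 for c in SENSE_CODONS})) == \
            pytest.approx(0.0)

    def test_exclusive_preferred_usage_gives_one(self):
        pref = preferred_codons("A")
        assert cbi(CodonUsageTable({c: 10 for c in pref})) == pytest.approx(1.0)

    def test_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(9)
        pref = preferred_codons("A")
        oracle_fams = _oracle_families()
        for _ in range(100):
            t = _random_table(rng)
            n_pref = n_tot = 0
            n_rand = 0.0
            for codons in oracle_fams.values():
                if len(codons) < 2:
                    continue
                fam_n = sum(t.counts[c] for c in codons)
                n_tot += fam_n
                n_pref += sum(t.counts[c] for c in codons if c in pref)
                n_rand += fam_n * sum(c in pref for c in codons) / len(codons)
            want = (n_pref - n_rand) / (n_tot - n_rand)
            assert cbi(t, pref) == pytest.approx(want, abs=1e-12)

    def test_u_ending_preference_set(self):
        pref = preferred_codons("U")
        assert "GTT" in pref and "GTA" not in pref


class TestCorrelation:
    def test_exact_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, [2 * v + 1 for v in x])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_independent_draws_are_uncorrelated(self):
        rng = np.random.default_rng(12)
        res = correlate(rng.normal(size=10_000), rng.normal(size=10_000))
        assert res.r_squared < 0.01

    def test_zero_variance_yields_missing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert correlate([1, 1, 1], [1, 2, 3]) is None

    def test_too_few_points_yields_missing(self):
        with pytest.warns(UserWarning):
            assert correlate([1, 2], [3, 4]) is None


def test_summary_and_long_table_shapes(clade_psets):
    t = count_codons(clade_psets["SYN01"].pcgs, label="SYN01")
    row = summary_row(t)
    assert set(row) >= {"enc", "cbi", "gc", "gc3", "at_rich4_share", "NNA", "NNU"}
    long = usage_long_table(t)
    assert len(long) == 62
    assert long["count"].sum() == t.total
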