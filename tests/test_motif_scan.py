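import numpy as np
import pandas as pd
import pytest

from oracles import naive_scan
from uprhd.motif_scan import (
    DEFAULT_PATTERNS,
    MotifHitTable,
    PromoterRecord,
    combination_counts,
    compile_pattern,
    presence_table,
    read_promoters_fasta,
    scan_promoter,
    write_promoters_fasta,
)
from uprhd.synthetic_data import simulate_promoters


class TestCompilePattern:
    def test_upre_degenerate_last_position(self):
        pat = compile_pattern("TGACGTGR")
        assert pat.length == 8
        assert pat.regex.search("TGACGTGG") and pat.regex.search("TGACGTGA")
        assert not pat.regex.search("TGACGTGC")

    def test_erse1_spacer_expansion(self):
        pat = compile_pattern("CCAATN{9}CCACG")
        assert pat.length == 19
        assert pat.regex.search("CCAAT" + "ACGTACGTA" + "CCACG")

    def test_erse2_width(self):
        assert compile_pattern("ATTGGNCCACG").length == 11

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown consensus symbol"):
            compile_pattern("TGAXGTG")


class TestScanPromoter:
    def test_forward_hit_at_direct_spelling(self):
        rec = PromoterRecord("X", "AATGACGTGGCC", window=(0, 12))
        hits = scan_promoter(rec, compile_pattern("TGACGTGR", name="UPRE"), strands="forward")
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]

    def test_reverse_complement_spelling_needs_both_strands(self):
        rec = PromoterRecord("Y", "CCACGTCATT", window=(0, 10))
        pat = compile_pattern("TGACGTGR", name="UPRE")
        assert [(h.offset, h.strand) for h in scan_promoter(rec, pat)] == [(0, "-")]
        assert scan_promoter(rec, pat, strands="forward") == []

    def test_overlapping_hits_all_reported(self):
        rec = PromoterRecord("Z", "AAAAA", window=(0, 5))
        hits = scan_promoter(rec, compile_pattern("ANA"), strands="forward")
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_sequence_n_never_matches(self):
        rec = PromoterRecord("N1", "TGACGTGG", window=(0, 8))
        pat = compile_pattern("TGACGTGR")
        assert len(scan_promoter(rec, pat)) >= 1
        rec_masked = PromoterRecord("N2", "TGANGTGG", window=(0, 8))
        assert scan_promoter(rec_masked, pat, strands="forward") == []

    def test_offsets_are_tss_relative(self):
        seq = "A" * 1500
        seq = seq[:1000] + "TGACGTGG" + seq[1008:]
        rec = PromoterRecord("T", seq)
        hits = [h for h in scan_promoter(rec, compile_pattern("TGACGTGR")) if h.strand == "+"]
        assert hits[0].offset == 0  # planted right at the TSS

    def test_matches_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(99)
        consensi = list(DEFAULT_PATTERNS.values()) + ["RNR", "ANT"]
        for i in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 200))))
            consensus = consensi[i % len(consensi)]
            rec = PromoterRecord("G", seq, window=(0, len(seq)))
            got = sorted((h.offset, h.strand) for h in scan_promoter(rec, compile_pattern(consensus)))
            assert got == naive_scan(seq, consensus)

    def test_strand_symmetry_under_reverse_complement(self):
        from uprhd.motif_scan import reverse_complement
        rng = np.random.default_rng(5)
        pat = compile_pattern("TGACGTGR")
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            rec = PromoterRecord("A", seq, window=(0, 120))
            rec_rc = PromoterRecord("B", reverse_complement(seq), window=(0, 120))
            assert len(scan_promoter(rec, pat)) == len(scan_promoter(rec_rc, pat))


def test_chance_hit_rate_matches_closed_form():
    """On uniform sequence the expected hit count is analytic per pattern."""
    n_seq, length = 300, 1500
    promoters, _ = simulate_promoters(n_genes=n_seq, window=(-1000, 500),
                                      motif_rates={}, seed=21)
    # per-position, per-strand match probabilities
    rates = {"UPRE": 2 * 0.25**8, "ERSE-I": 0.25**10, "ERSE-II": 0.25**10}
    table = presence_table(promoters)
    for name, p1 in rates.items():
        width = compile_pattern(DEFAULT_PATTERNS[name], name=name).length
        positions = length - width + 1
        expect = n_seq * 2 * positions * p1
        total = table.counts[name].sum()
        assert abs(total - expect) <= 3 * np.sqrt(expect) + 1e-9


class TestPresenceAndCombinations:
    def test_duplicate_gene_ids_rejected(self):
        recs = [PromoterRecord("A", "ACGT", window=(0, 4)), PromoterRecord("A", "ACGT", window=(0, 4))]
        with pytest.raises(ValueError, match="duplicate"):
            presence_table(recs, {"UPRE": "AC"})

    def test_combination_counts_at_least_semantics(self):
        flags = pd.DataFrame(
            {"UPRE": [True, False, True], "ERSE-I": [True, True, True], "ERSE-II": [False, False, True]},
            index=["g1", "g2", "g3"])
        counts = combination_counts(MotifHitTable.from_flags(flags))
        assert counts["ERSE-I+UPRE"] == 2
        assert counts["ERSE-I+ERSE-II+UPRE"] == 1
        assert counts["none"] == 0

    def test_single_pattern_population(self):
        flags = pd.DataFrame({"UPRE": [True] * 4, "ERSE-I": [False] * 4}, index=list("abcd"))
        counts = combination_counts(MotifHitTable.from_flags(flags))
        assert counts["UPRE"] == 4 and counts["ERSE-I+UPRE"] == 0

    def test_empty_table_all_zero(self):
        flags = pd.DataFrame({"UPRE": [], "ERSE-I": []})
        counts = combination_counts(MotifHitTable.from_flags(flags))
        assert set(counts.values()) == {0}


def test_fasta_round_trip(tmp_path):
    promoters, _ = simulate_promoters(n_genes=4, motif_rates={"UPRE": 0.5}, seed=13)
    path = tmp_path / "p.fasta"
    write_promoters_fasta(promoters, path)
    back = read_promoters_fasta(path)
    assert [(r.gene, r.sequence, r.window) for r in back] == [
        (r.gene, r.sequence, r.window) for r in promoters]
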