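"""Sequence-feature tests: kmer/Fisher oracles, PWM scanning, ARE detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

import haloseq as h
from haloseq.features import all_kmers, hur_pwm, read_meme, write_meme


def naive_kmer_counts(sequences, k):
    """Brute-force overlapping substring scan over the full kmer universe."""
    totals = {kmer: 0 for kmer in all_kmers(k)}
    for seq in sequences.values():
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" not in window:
                totals[window] += 1
    return pd.Series(totals)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p as a hypergeometric tail sum over all tables with
    the observed margins, summing outcomes no more probable than observed."""
    n1, n2 = a + b, c + d
    k = a + c
    rv = hypergeom(n1 + n2, n1, k)
    observed = rv.pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        p = rv.pmf(x)
        if p <= observed * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestCountKmers:
    def test_homopolymer_single_occurrence(self):
        presence, totals = h.count_kmers({"g": "AAAAAA"}, 6)
        assert totals["AAAAAA"] == 1
        assert presence.loc["g", "AAAAAA"]
        assert totals.sum() == 1

    def test_overlapping_occurrences_counted(self):
        _, totals = h.count_kmers({"g": "ATTTATTTA"}, 5)
        assert totals["ATTTA"] == 2

    def test_windows_containing_n_are_skipped(self):
        _, totals = h.count_kmers({"g": "AANTTT"}, 3)
        assert totals.sum() == 1  # AAN, ANT, NTT all contain the N
        assert totals["TTT"] == 1

    def test_matches_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(17)
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=60))
            for i in range(100)
        }
        for k in (1, 3, 6):
            _, totals = h.count_kmers(seqs, k)
            oracle = naive_kmer_counts(seqs, k)
            pd.testing.assert_series_equal(totals, oracle, check_names=False)

    def test_strand_specific_counting(self):
        seq = "AAACCC"
        rc = "GGGTTT"
        _, fwd = h.count_kmers({"g": seq}, 3)
        _, rev = h.count_kmers({"g": rc}, 3)
        assert fwd["AAA"] == 1 and rev["AAA"] == 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="k must"):
            h.count_kmers({"g": "ACGT"}, 9)
        with pytest.raises(ValueError, match="empty"):
            h.count_kmers({}, 3)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=40), st.integers(1, 4))
    def test_total_count_equals_window_count(self, seq, k):
        if not seq:
            return
        _, totals = h.count_kmers({"g": seq}, k)
        assert totals.sum() == max(0, len(seq) - k + 1)


class TestKmerEnrichment:
    def test_fisher_matches_hypergeometric_tail_sum(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(23)
        for _ in range(300):
            n1, n2 = rng.integers(1, 31, size=2)
            a = rng.integers(0, n1 + 1)
            c = rng.integers(0, n2 + 1)
            p = fisher_exact([[a, n1 - a], [c, n2 - c]], alternative="two-sided")[1]
            assert p == pytest.approx(fisher_oracle(a, n1 - a, c, n2 - c), abs=1e-10)

    def test_absent_kmer_rows_have_unit_p(self):
        records = h.kmer_enrichment({"t": "ACACAC"}, {"b": "GTGTGT"}, k=4)
        absent = records[(records["a"] == 0) & (records["c"] == 0)]
        assert (absent["pvalue"] == 1.0).all()
        assert len(records) == 4**4

    def test_margins_and_haldane_or_finite(self):
        records = h.kmer_enrichment(
            {"t1": "AAAA", "t2": "CCCC"}, {"b1": "GGGG", "b2": "TTTT", "b3": "ACGT"}, k=2
        )
        assert ((records["a"] + records["b"]) == 2).all()
        assert ((records["c"] + records["d"]) == 3).all()
        assert np.isfinite(records["log2_odds_ratio"]).all()

    def test_bh_discoveries_never_exceed_raw(self):
        rng = np.random.default_rng(29)
        target = {f"t{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(30)}
        background = {f"b{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(60)}
        records = h.kmer_enrichment(target, background, k=3)
        for q in (0.01, 0.05, 0.1):
            assert (records["padj"] < q).sum() <= (records["pvalue"] < q).sum()

    def test_overlapping_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            h.kmer_enrichment({"g": "ACGTACGT"}, {"g": "ACGTACGT"}, k=3)


class TestPWM:
    def test_consensus_scan_single_maximal_hit(self):
        pwm = hur_pwm()
        assert pwm.scan(pwm.consensus, score_fraction=1.0) == 1

    def test_uniform_matrix_is_degenerate_and_hits_everywhere(self):
        uniform = h.PWM("uni", np.full((3, 4), 0.25))
        assert uniform.degenerate
        assert uniform.max_score == 0.0
        assert uniform.scan("ACGTACGT") == 6  # every offset

    def test_scores_match_per_position_product_oracle(self):
        rng = np.random.default_rng(31)
        mat = rng.dirichlet(np.ones(4), size=5)
        pwm = h.PWM("m", mat)
        seq = "ACGTGCATTG"
        probs = pwm._probs
        lo = np.log2(probs / 0.25)
        code = {b: i for i, b in enumerate("ACGT")}
        for offset in range(len(seq) - 5 + 1):
            window = seq[offset : offset + 5]
            expected = sum(lo[i, code[b]] for i, b in enumerate(window))
            threshold = expected / pwm.max_score if pwm.max_score > 0 else None
            if threshold is not None and 0 < threshold <= 1:
                assert pwm.scan(window, score_fraction=min(threshold, 1.0)) >= 1

    def test_malformed_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            h.PWM("bad", np.full((3, 4), 0.3))

    def test_meme_round_trip_and_rna_alphabet(self, tmp_path):
        pwm = hur_pwm()
        path = tmp_path / "motifs.meme"
        write_meme([pwm], path, alphabet="ACGU")
        (loaded,) = read_meme(path)
        assert loaded.motif_id == pwm.motif_id
        np.testing.assert_allclose(loaded.matrix, pwm.matrix, atol=1e-5)

    def test_indicator_pwm_motif_enrichment_equals_consensus_kmer_row(self):
        """A 0/1 indicator PWM scanned at full score behaves exactly like
        presence of its consensus kmer."""
        rng = np.random.default_rng(37)
        consensus = "ACGTA"
        mat = np.zeros((5, 4))
        for i, b in enumerate(consensus):
            mat[i, "ACGT".index(b)] = 1.0
        pwm = h.PWM("ind", mat)
        target = {f"t{i}": "".join(rng.choice(list("ACGT"), 40)) for i in range(40)}
        background = {f"b{i}": "".join(rng.choice(list("ACGT"), 40)) for i in range(80)}
        motif_rec = h.motif_enrichment(target, background, [pwm], score_fraction=1.0)
        kmer_rec = h.kmer_enrichment(target, background, k=5)
        krow = kmer_rec[kmer_rec["feature"] == consensus].iloc[0]
        mrow = motif_rec.iloc[0]
        assert (mrow["a"], mrow["c"]) == (krow["a"], krow["c"])
        assert mrow["pvalue"] == pytest.approx(krow["pvalue"], abs=1e-12)


class TestAREs:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGATTTAGGG", [(3, 8, 1, 1)]),
            ("ATTTATTTATTTA", [(0, 13, 3, 3)]),
            ("GCGCGC", []),
        ],
    )
    def test_printed_toy_strings(self, seq, expected):
        spans = h.detect_ares({"g": seq})
        got = [tuple(r) for r in spans[["start", "end", "n_pentamers", "are_class"]].to_numpy()]
        assert got == expected

    def test_gap_rule_merges_up_to_two_bases(self):
        merged = h.detect_ares({"g": "ATTTAGGATTTA"})  # gap 2
        assert len(merged) == 1 and merged["n_pentamers"].iloc[0] == 2
        split = h.detect_ares({"g": "ATTTAGGGATTTA"})  # gap 3
        assert len(split) == 2

    def test_class_saturates_at_five(self):
        seq = "ATTTA" + "TTTA" * 7
        spans = h.detect_ares({"g": seq})
        assert spans["are_class"].iloc[0] == 5
        assert spans["n_pentamers"].iloc[0] == 8

    def test_bed_loader_round_trip_and_precedence_schema(self, tmp_path):
        spans = h.detect_ares({"g1": "GGATTTAGG", "g2": "ATTTATTTA"})
        bed = tmp_path / "ares.bed"
        with open(bed, "w") as fh:
            for r in spans.itertuples(index=False):
                fh.write(f"{r.gene_id}\t{r.start}\t{r.end}\tARE\t{r.n_pentamers}\t+\n")
        loaded = h.load_ares(bed)
        pd.testing.assert_frame_equal(loaded, spans)

    def test_bed_loader_reports_malformed_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("g1\t0\t5\tARE\t1\t+\ng2\tx\t9\tARE\t1\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            h.load_ares(bed)


class TestAnnotateGenes:
    def test_bins_and_defaults(self):
        spans = h.detect_ares({"g1": "GGATTTAGG"})
        annotated = h.annotate_genes_with_features(
            ["g1", "g2", "g3"], spans, {"g1": 1, "g2": 5}
        )
        assert annotated.loc["g1", "has_are"]
        assert not annotated.loc["g2", "has_are"]
        assert annotated.loc["g3", "hur_sites"] == 0
        assert annotated.loc["g2", "hur_bin"] == "3+"
        assert annotated.loc["g3", "hur_bin"] == "0"

    def test_bin_populations_sum_to_gene_count(self):
        genes = [f"g{i}" for i in range(25)]
        hur = {g: i % 5 for i, g in enumerate(genes)}
        annotated = h.annotate_genes_with_features(genes, None, hur)
        assert annotated["hur_bin"].value_counts().sum() == len(genes)

    def test_disjoint_universe_rejected(self):
        spans = h.detect_ares({"x1": "GGATTTAGG"})
        with pytest.raises(ValueError, match="id-scheme"):
            h.annotate_genes_with_features(["g1"], spans, None)
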