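"""Canonical k-mer enumeration, weight tables, region scoring and PWMs."""

import numpy as np
import pandas as pd
import pytest

from gkmprior import dna
from gkmprior.scoring import (
    KmerWeightTable,
    Pwm,
    build_kmer_weight_table,
    build_pwm_from_top_kmers,
    enumerate_canonical_kmers,
    pwm_information_content,
    score_regions,
    score_sequence,
)


class TestCanonicalEnumeration:
    def test_small_counts_against_bruteforce(self):
        # l=1: A~T and C~G pair up; l=2: 16 words, 4 self-complementary
        assert len(enumerate_canonical_kmers(1)) == 2
        assert len(enumerate_canonical_kmers(2)) == 10
        for l in (1, 3, 5, 7):
            brute = set()
            for code in range(4**l):
                kmer = dna.code_to_kmer(code, l)
                brute.add(min(kmer, dna.revcomp(kmer)))
            got = {k.decode() for k in enumerate_canonical_kmers(l, as_strings=True)}
            assert got == brute
            assert len(got) == 4**l // 2

    def test_each_pair_represented_once(self):
        canon = set(enumerate_canonical_kmers(5).tolist())
        for code in canon:
            rc = int(dna.revcomp_codes(np.array([code]), 5)[0])
            assert (rc == code) or (rc not in canon)

    def test_invalid_and_guarded_lengths(self):
        with pytest.raises(ValueError):
            enumerate_canonical_kmers(0)
        with pytest.raises(MemoryError):
            enumerate_canonical_kmers(14)


class TestWeightTable:
    def test_table_matches_direct_model_scoring(self, small_model):
        table = build_kmer_weight_table(small_model)
        rng = np.random.default_rng(1)
        l = small_model.config.l
        for code in rng.integers(0, 4**l, size=12):
            kmer = dna.code_to_kmer(int(code), l)
            assert table.weight_of(kmer) == pytest.approx(
                score_sequence(small_model, kmer), abs=1e-9
            )

    def test_canonical_pair_shares_weight(self, small_model):
        table = build_kmer_weight_table(small_model)
        rng = np.random.default_rng(2)
        for code in rng.integers(0, 4**table.l, size=20):
            kmer = dna.code_to_kmer(int(code), table.l)
            assert table.weight_of(kmer) == table.weight_of(dna.revcomp(kmer))

    def test_top_ties_broken_lexicographically(self):
        l = 3
        weights = np.zeros(4**l)
        table = KmerWeightTable(l=l, weights=weights)
        codes, w = table.top(5)
        assert list(codes) == sorted(codes)  # all-tie case: lexicographic order

    def test_sliding_sum_lookup_equals_per_window_model_scores(self, small_model):
        # dual-route check: table lookup vs direct kernel-model scoring
        table = build_kmer_weight_table(small_model)
        rng = np.random.default_rng(3)
        l = small_model.config.l
        for _ in range(5):
            seq = dna.decode(rng.integers(0, 4, size=30).astype(np.uint8))
            direct = sum(score_sequence(small_model, seq[i:i + l])
                         for i in range(len(seq) - l + 1))
            lookup = float(table.weights[dna.window_codes(seq, l)].sum())
            assert lookup == pytest.approx(direct, abs=1e-9)

    def test_serialization_roundtrip(self, small_model, tmp_path):
        table = build_kmer_weight_table(small_model)
        table.save(tmp_path / "w.tsv")
        loaded = KmerWeightTable.load(tmp_path / "w.tsv")
        np.testing.assert_allclose(loaded.weights, table.weights, atol=1e-12)

    def test_partial_table_top_ignores_missing_entries(self, small_model, tmp_path):
        # a table saved with top_n stores negative weights too; reloading must
        # not let absent k-mers (NaN) outrank them
        table = build_kmer_weight_table(small_model)
        table.save(tmp_path / "top.tsv", top_n=300)
        loaded = KmerWeightTable.load(tmp_path / "top.tsv")
        full_codes, full_w = table.top(300)
        part_codes, part_w = loaded.top(300)
        np.testing.assert_array_equal(part_codes, full_codes)
        np.testing.assert_allclose(part_w, full_w, atol=1e-12)


class TestScoreSequence:
    def test_strand_invariance_exact(self, small_model):
        rng = np.random.default_rng(4)
        for _ in range(5):
            seq = dna.decode(rng.integers(0, 4, size=25).astype(np.uint8))
            assert score_sequence(small_model, seq) == score_sequence(
                small_model, dna.revcomp(seq)
            )

    def test_motif_bearing_sequence_scores_high(self, small_model, motif):
        rng = np.random.default_rng(5)
        flank = lambda n: dna.decode(rng.integers(0, 4, size=n).astype(np.uint8))
        carrier = flank(4) + motif.consensus + flank(5)
        null = np.array([
            score_sequence(small_model, flank(len(carrier))) for _ in range(300)
        ])
        assert score_sequence(small_model, carrier) > np.quantile(null, 0.95)

    def test_too_short_raises(self, small_model):
        with pytest.raises(ValueError):
            score_sequence(small_model, "ACG")


class TestScoreRegions:
    def test_single_window_region_equals_kmer_weight(self, small_model):
        table = build_kmer_weight_table(small_model)
        l = table.l
        genome = {"chrT": "ACGTACGTACGTACGTACGT"}
        regions = pd.DataFrame([("chrT", 2, 2 + l, "r", 0.0, "+")],
                               columns=["chrom", "start", "end", "name", "score", "strand"])
        results, skipped = score_regions(table, genome, regions)
        assert results[0].score == pytest.approx(table.weight_of(genome["chrT"][2:2 + l]))
        assert results[0].best_window == 0

    def test_short_region_skipped_with_reason(self, small_model):
        table = build_kmer_weight_table(small_model)
        genome = {"chrT": "ACGTACGTACGTACGT"}
        regions = pd.DataFrame([("chrT", 0, 4, "tiny", 0.0, "+")],
                               columns=["chrom", "start", "end", "name", "score", "strand"])
        results, skipped = score_regions(table, genome, regions)
        assert results == [] and skipped[0][0] == "tiny"

    def test_planted_motif_region_beats_empirical_null(self, small_model, motif):
        table = build_kmer_weight_table(small_model)
        rng = np.random.default_rng(6)
        L = 30
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        inst = motif.consensus
        carrier = dna.decode(rng.integers(0, 4, size=10).astype(np.uint8)) + inst \
            + dna.decode(rng.integers(0, 4, size=L - 10 - len(inst)).astype(np.uint8))
        null_scores = []
        for i in range(200):
            seq = dna.decode(rng.integers(0, 4, size=L).astype(np.uint8))
            r, _ = score_regions(table, {"c": seq},
                                 pd.DataFrame([("c", 0, L, f"n{i}", 0.0, "+")], columns=cols))
            null_scores.append(r[0].score)
        r, _ = score_regions(table, {"c": carrier},
                             pd.DataFrame([("c", 0, L, "m", 0.0, "+")], columns=cols))
        assert r[0].score > np.quantile(null_scores, 0.99)

    def test_center_window_mode_scores_central_bases(self, small_model):
        table = build_kmer_weight_table(small_model)
        genome = {"chrT": "ACGTACGTACGTACGTACGTACGTACGT"}
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        regions = pd.DataFrame([("chrT", 0, 28, "r", 0.0, "+")], columns=cols)
        full, _ = score_regions(table, genome, regions, mode="sliding_sum")
        center, _ = score_regions(table, genome, regions, mode="center_window", window=12)
        sub = genome["chrT"][8:20]
        expected = float(table.weights[dna.window_codes(sub, table.l)].sum())
        assert center[0].score == pytest.approx(expected)
        assert center[0].score != pytest.approx(full[0].score)


class TestPwm:
    def test_identical_top_kmers_give_point_masses(self):
        l = 5
        weights = np.zeros(4**l)
        seq = "ACGTC"
        code = dna.kmer_to_code(seq)
        weights[code] = 5.0
        weights[int(dna.revcomp_codes(np.array([code]), l)[0])] = 5.0
        table = KmerWeightTable(l=l, weights=weights)
        pwm = build_pwm_from_top_kmers(table, top_n=1)
        arr = dna.encode(seq)
        delta = 0.25 / (1 + 4 * 0.25)
        for i, b in enumerate(arr):
            assert pwm.matrix[i, b] == pytest.approx((1 + 0.25) / 2.0)
            others = [pwm.matrix[i, j] for j in range(4) if j != b]
            assert all(o == pytest.approx(delta) for o in others)

    def test_reverse_complemented_table_gives_reverse_complement_pwm(self, small_model):
        table = build_kmer_weight_table(small_model)
        pwm = build_pwm_from_top_kmers(table, top_n=50)
        # canonical keying makes the table strand-symmetric already; the rc
        # of the PWM must describe the same motif on the other strand
        rc = pwm.reverse_complement()
        np.testing.assert_allclose(rc.matrix, pwm.matrix[::-1, ::-1])
        np.testing.assert_allclose(rc.reverse_complement().matrix, pwm.matrix)

    def test_recovers_planted_motif_core(self, small_model, motif):
        table = build_kmer_weight_table(small_model)
        pwm = build_pwm_from_top_kmers(table, top_n=200)
        best = -2.0
        planted = motif.pwm
        Lp, Lm = len(pwm), planted.shape[0]
        for mat in (pwm.matrix, pwm.matrix[::-1, ::-1]):
            for off in range(-Lm + 1, Lp):
                cors = [np.corrcoef(planted[i], mat[off + i])[0, 1]
                        for i in range(Lm) if 0 <= off + i < Lp]
                if len(cors) >= 5:
                    best = max(best, float(np.mean(cors)))
        assert best >= 0.8

    def test_top_n_clamped_with_warning(self, small_model):
        table = build_kmer_weight_table(small_model)
        with pytest.warns(UserWarning):
            pwm = build_pwm_from_top_kmers(table, top_n=4**table.l)
        assert pwm.n_contributing_kmers == 4**table.l // 2

    def test_meme_output_format(self, small_model, tmp_path):
        table = build_kmer_weight_table(small_model)
        pwm = build_pwm_from_top_kmers(table, top_n=10)
        pwm.to_meme(tmp_path / "m.meme")
        text = (tmp_path / "m.meme").read_text()
        assert "MEME version 4" in text
        assert f"w= {len(pwm)}" in text


class TestInformationContent:
    def test_uniform_and_point_mass_rows(self):
        pwm = Pwm(np.array([[0.25, 0.25, 0.25, 0.25], [1.0, 0.0, 0.0, 0.0]]))
        ic = pwm_information_content(pwm)
        assert ic[0] == pytest.approx(0.0, abs=1e-12)
        assert ic[1] == pytest.approx(2.0, abs=1e-12)

    def test_recovered_core_positions_carry_information(self, small_model):
        table = build_kmer_weight_table(small_model)
        pwm = build_pwm_from_top_kmers(table, top_n=200)
        assert pwm_information_content(pwm).max() > 1.0
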