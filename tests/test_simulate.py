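"""Properties of the synthetic-data generators and their ground-truth sidecars."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gkmprior import dna
from gkmprior.catalog import VariantRecord
from gkmprior.simulate import (
    PlantedMotifSpec,
    SyntheticStudyConfig,
    default_motif,
    generate_emsa_data,
    generate_eqtl_table,
    generate_genome,
    generate_gwas_catalog,
    generate_ld_table,
    generate_peaks,
    generate_regulatory_tracks,
    simulate_study,
)


class TestGenome:
    def test_gc_content_within_three_standard_errors(self):
        g = generate_genome(2, 50_000, 0.41, seed=7)
        n = 2 * 50_000
        obs = sum(s.count("G") + s.count("C") for s in g.chromosomes.values()) / n
        se = np.sqrt(0.41 * 0.59 / n)
        assert abs(obs - 0.41) < 3 * se

    def test_zero_gc_gives_at_only(self):
        g = generate_genome(1, 100, 0.0, seed=1)
        assert set(g.chromosomes["chr1"]) <= {"A", "T"}

    def test_deterministic_under_seed(self):
        a = generate_genome(2, 5000, 0.5, seed=7)
        b = generate_genome(2, 5000, 0.5, seed=7)
        assert a.chromosomes == b.chromosomes
        c = generate_genome(2, 5000, 0.5, seed=8)
        assert c.chromosomes != a.chromosomes

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_genome(0, 100, 0.5, seed=1)
        with pytest.raises(ValueError):
            generate_genome(1, 100, 1.5, seed=1)


class TestPeaks:
    def test_full_planting_probability_places_every_peak(self, small_genome, motif):
        peaks, truth, _ = generate_peaks(small_genome, motif, 60, 40, seed=3)
        assert truth["planted"].all()
        assert truth["offset"].notna().all()

    def test_zero_planting_probability_places_nothing(self, small_genome):
        m = default_motif(planting_probability=0.0)
        peaks, truth, genome = generate_peaks(small_genome, m, 60, 40, seed=3)
        assert not truth["planted"].any()
        # genome untouched
        assert genome.chromosomes == small_genome.chromosomes

    def test_signal_correlates_with_motif_strength_at_high_gain(self, small_genome):
        # use a degenerate-enough PWM that instance log-odds actually vary;
        # the near-consensus default would leave nothing to rank
        majors = [0.55, 0.65, 0.75, 0.85, 0.6, 0.7, 0.8, 0.9]
        rows = []
        for i, (b, p) in enumerate(zip([0, 1, 2, 3, 0, 1, 2, 3], majors)):
            row = np.full(4, (1 - p) / 3)
            row[b] = p
            rows.append(row)
        variable_motif = PlantedMotifSpec(np.array(rows), name="soft")
        peaks, truth, _ = generate_peaks(
            small_genome, variable_motif, 120, 40, seed=3, gain=10.0, noise_sd=0.5
        )
        planted = truth[truth["planted"]]
        assert planted["log_odds"].nunique() > 20
        rho = spearmanr(planted["signal"], planted["log_odds"]).statistic
        assert rho > 0.9

    def test_instances_are_written_into_returned_genome(self, small_genome, motif):
        peaks, truth, genome = generate_peaks(small_genome, motif, 30, 40, seed=4)
        for row in truth[truth["planted"]].itertuples(index=False):
            seq = genome.chromosomes[row.chrom][row.start + row.offset :
                                                row.start + row.offset + len(motif)]
            expected = row.instance if row.strand == "+" else dna.revcomp(row.instance)
            assert seq == expected

    def test_peaks_sorted_descending_and_nonoverlapping(self, small_genome, motif):
        peaks, _, _ = generate_peaks(small_genome, motif, 80, 40, seed=5)
        assert (peaks["score"].diff().dropna() <= 0).all()
        for chrom, sub in peaks.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_peak_shorter_than_motif_raises(self, small_genome, motif):
        with pytest.raises(ValueError):
            generate_peaks(small_genome, motif, 10, len(motif) - 1, seed=1)


class TestGwasCatalog:
    def test_exact_planted_class_counts(self, small_genome):
        table, truth = generate_gwas_catalog(
            small_genome, 100, fraction_cvd=0.5, fraction_indel=0.1,
            fraction_malformed=0.1, seed=2,
        )
        assert len(table) == 100
        assert truth["is_cvd"].sum() == 50
        assert truth["is_indel"].sum() == 10
        assert truth["is_malformed"].sum() == 10
        assert not (truth["is_indel"] & truth["is_malformed"]).any()

    def test_all_cvd_traits_match_published_pattern(self, small_genome):
        import re

        from gkmprior.catalog import CVD_TRAIT_PATTERN

        table, truth = generate_gwas_catalog(small_genome, 50, fraction_cvd=1.0, seed=3)
        rx = re.compile(CVD_TRAIT_PATTERN, re.IGNORECASE)
        assert all(rx.search(t) for t in table["DISEASE/TRAIT"])

    def test_rerun_same_seed_identical(self, small_genome, tmp_path):
        a, _ = generate_gwas_catalog(small_genome, 80, seed=5)
        b, _ = generate_gwas_catalog(small_genome, 80, seed=5)
        a.to_csv(tmp_path / "a.tsv", sep="\t", index=False)
        b.to_csv(tmp_path / "b.tsv", sep="\t", index=False)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_exclusive_fractions_enforced(self, small_genome):
        with pytest.raises(ValueError):
            generate_gwas_catalog(small_genome, 10, fraction_indel=0.6, fraction_malformed=0.6)

    def test_ref_allele_matches_genome(self, small_genome):
        _, truth = generate_gwas_catalog(small_genome, 60, fraction_indel=0.0,
                                         fraction_malformed=0.0, seed=6)
        for r in truth.itertuples(index=False):
            assert small_genome.chromosomes[r.chrom][r.pos - 1] == r.ref[0]


class TestRegulatoryTracks:
    def test_zero_orphans_all_footprints_nested(self, small_genome):
        enh, fp = generate_regulatory_tracks(small_genome, 10, 300, 2, 20, 0.0, seed=1)
        for f in fp.itertuples(index=False):
            assert any(e.chrom == f.chrom and e.start <= f.start and f.end <= e.end
                       for e in enh.itertuples(index=False))

    def test_orphan_arithmetic(self, small_genome):
        enh, fp = generate_regulatory_tracks(small_genome, 10, 300, 3, 20, 0.25, seed=1)
        assert len(fp) == 40  # 30 nested / (1 - 0.25)
        orphan = fp[fp["name"].str.endswith("orphan")]
        assert len(orphan) == 10
        for f in orphan.itertuples(index=False):
            assert not any(e.chrom == f.chrom and e.start < f.end and f.start < e.end
                           for e in enh.itertuples(index=False))

    def test_dgf_longer_than_enhancer_raises(self, small_genome):
        with pytest.raises(ValueError):
            generate_regulatory_tracks(small_genome, 5, 50, 1, 60, 0.0, seed=1)


def _leads(small_genome, n=4):
    out = []
    for i in range(n):
        pos = 5000 + 2000 * i
        ref = small_genome.chromosomes["chr1"][pos - 1]
        alt = "A" if ref != "A" else "C"
        out.append(VariantRecord(f"rs{i}", "chr1", pos, ref, alt))
    return out


class TestLdTable:
    def test_every_lead_links_to_itself_at_r2_one(self, small_genome):
        table, _ = generate_ld_table(_leads(small_genome), seed=1, genome=small_genome)
        for lead in _leads(small_genome):
            self_rows = table[(table["lead_rsid"] == lead.rsid)
                              & (table["linked_rsid"] == lead.rsid)]
            assert len(self_rows) == len(set(table["population"]))
            assert (self_rows["r2"] == 1.0).all()

    def test_extreme_decay_kills_all_proxies(self, small_genome):
        table, truth = generate_ld_table(_leads(small_genome), r2_decay=1e6, seed=1,
                                         genome=small_genome)
        non_self = table[table["lead_rsid"] != table["linked_rsid"]]
        assert (non_self["r2"] <= 0.8).all()
        assert not truth["qualifies"].any()

    def test_per_population_rows_emitted(self, small_genome):
        pops = ("EUR", "AFR", "SAS", "EAS", "AMR")
        table, _ = generate_ld_table(_leads(small_genome, 1), populations=pops, seed=2,
                                     genome=small_genome)
        non_self = table[table["lead_rsid"] != table["linked_rsid"]]
        counts = non_self.groupby("linked_rsid")["population"].nunique()
        assert (counts == 5).all()

    def test_planned_high_ld_counts(self, small_genome):
        leads = _leads(small_genome)
        table, truth = generate_ld_table(leads, seed=3, genome=small_genome,
                                         n_high_ld_per_lead=1)
        assert truth["qualifies"].sum() == len(leads)

    def test_empty_population_list_raises(self, small_genome):
        with pytest.raises(ValueError):
            generate_ld_table(_leads(small_genome), populations=(), seed=1)


class TestEqtlTable:
    def test_zero_significant_fraction_yields_no_joinable_pairs(self, small_genome):
        variants = _leads(small_genome, 6)
        table, truth = generate_eqtl_table(variants, fraction_significant=0.0, seed=1)
        assert len(truth) == 0
        from gkmprior.catalog import join_eqtl

        pairs, summary = join_eqtl(variants, table)
        assert summary["n_pairs"] == 0

    def test_planted_pairs_recovered_exactly_by_join(self, small_genome):
        variants = _leads(small_genome, 8)
        sig = [v.rsid for v in variants[:3]]
        table, truth = generate_eqtl_table(variants, significant_rsids=sig, seed=2)
        from gkmprior.catalog import join_eqtl

        pairs, summary = join_eqtl(variants, table)
        assert summary["n_pairs"] == len(truth) == 3
        assert {p.variant_rsid for p in pairs} == set(sig)

    def test_shuffled_variant_ids_break_joins(self, small_genome):
        variants = _leads(small_genome, 8)
        sig = [v.rsid for v in variants[:4]]
        table, _ = generate_eqtl_table(variants, significant_rsids=sig, seed=3)
        shuffled = table.copy()
        shuffled["variant_id"] = ["rsZ" + str(i) for i in range(len(table))]
        from gkmprior.catalog import join_eqtl

        _, summary = join_eqtl(variants, shuffled)
        assert summary["n_pairs"] == 0

    def test_unknown_tissue_against_vocabulary_raises(self, small_genome):
        with pytest.raises(ValueError):
            generate_eqtl_table(_leads(small_genome), tissues=("heart atrial appendage", "Brain?"),
                                vocabulary=("heart atrial appendage",), seed=1)


class TestEmsaData:
    def test_noiseless_half_saturation_identity(self):
        df = generate_emsa_data(kd=200, bmax=0.8, concentrations=(200.0,), noise_sd=0.0,
                                n_replicates=1, seed=1)
        frac = (df["bound"] - df["background"]) / (
            df["bound"] - df["background"] + df["unbound"] - df["background"]
        )
        assert frac.iloc[0] == pytest.approx(0.4, abs=1e-12)

    def test_noiseless_closed_form_fractions(self):
        xs = (50.0, 100.0, 500.0, 1000.0, 2000.0)
        df = generate_emsa_data(kd=200, bmax=1.0, concentrations=xs, noise_sd=0.0,
                                n_replicates=1, seed=1)
        frac = ((df["bound"] - df["background"])
                / (df["bound"] + df["unbound"] - 2 * df["background"]))
        expected = [x / (200 + x) for x in xs]
        np.testing.assert_allclose(frac, expected, atol=1e-12)

    def test_low_concentration_limit(self):
        df = generate_emsa_data(kd=200, bmax=1.0, concentrations=(1e-6,), noise_sd=0.0,
                                n_replicates=1, seed=1)
        frac = (df["bound"] - df["background"]).iloc[0] / 10000.0
        assert frac == pytest.approx(0.0, abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_emsa_data(kd=-5, bmax=1.0)
        with pytest.raises(ValueError):
            generate_emsa_data(kd=100, bmax=1.0, concentrations=(0.0, 50.0))


class TestStudy:
    def test_study_is_deterministic_and_roundtrips(self, tmp_path):
        a = simulate_study(seed=3)
        b = simulate_study(seed=3)
        pd.testing.assert_frame_equal(a.gwas, b.gwas)
        pd.testing.assert_frame_equal(a.ld_table, b.ld_table)
        assert a.ground_truth == b.ground_truth
        a.write(tmp_path / "study")
        from gkmprior import io

        genome = io.read_fasta(tmp_path / "study" / "genome.fa")
        assert genome == a.genome.chromosomes
        peaks = io.read_bed(tmp_path / "study" / "peaks.bed")
        assert len(peaks) == len(a.peaks)
        assert peaks["start"].tolist() == a.peaks["start"].tolist()

    def test_prioritized_sites_carry_planted_consensus(self):
        study = simulate_study(seed=4)
        motif = study.motif
        for site in study.ground_truth["prioritized_sites"]:
            seq = study.genome.chromosomes[site["chrom"]][
                site["motif_start"] : site["motif_start"] + len(motif)
            ]
            assert seq == motif.consensus
            assert study.genome.chromosomes[site["chrom"]][site["pos"] - 1] == site["ref"]
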