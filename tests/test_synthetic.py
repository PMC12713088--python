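"""The synthetic-study generator: determinism, constraints, calibration."""

import numpy as np
import pytest

from chromtargets.genome_io import write_gene_table
from chromtargets.synthetic import (
    COMPLEX_FACTORS,
    TRHT_TRHD_FACTORS,
    SimConfig,
    default_pwms,
    joint_presence_probs,
    plant_motifs,
    simulate_binding,
    simulate_genome,
    simulate_marks_and_expression,
    simulate_study,
)


def small_cfg(**kw):
    base = dict(n_genes=300, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_byte_identical_under_same_seed(self, tmp_path):
        cfg = small_cfg()
        g1, s1 = simulate_genome(cfg)
        g2, s2 = simulate_genome(cfg)
        assert s1 == s2
        write_gene_table(g1, tmp_path / "a.tsv")
        write_gene_table(g2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_gene_count_bounds_and_no_overlap(self):
        genes, seqs = simulate_genome(small_cfg(n_genes=100, n_chromosomes=2))
        assert len(genes) == 100
        by_chrom: dict[str, list] = {}
        for g in genes:
            assert 0 <= g.start < g.end <= len(seqs[g.chrom])
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                assert a.end <= b.start

    def test_degenerate_length_range(self):
        genes, _ = simulate_genome(small_cfg(gene_length_range=(1000, 1000)))
        assert all(g.length == 1000 for g in genes)

    def test_chromosome_cap_error_names_chromosome(self):
        with pytest.raises(ValueError, match="chr1"):
            simulate_genome(small_cfg(chromosome_cap=10_000))

    def test_sequences_are_acgt_with_2kb_flanks(self):
        genes, seqs = simulate_genome(small_cfg(n_genes=20))
        assert all(set(s) <= set("ACGT") for s in seqs.values())
        for g in genes:
            assert g.start >= 2000
            assert g.end + 2000 <= len(seqs[g.chrom])


class TestSimulateBinding:
    def test_full_detection_peaks_for_every_occupied_gene(self):
        cfg = small_cfg(factor_detection_prob=1.0)
        genes, _ = simulate_genome(cfg)
        peaks, counts, truth = simulate_binding(cfg, genes)
        occupied = truth.target_genes()
        for f in TRHT_TRHD_FACTORS:
            with_peak = {p.peak_id.split("_", 1)[1] for p in peaks[f]}
            assert with_peak == occupied

    def test_zero_occupancy_means_no_peaks(self):
        cfg = small_cfg(
            complex_occupancy_probs={"TRHT_TRHD": 0.0, "PEAT": 0.0, "PRC2": 0.0}
        )
        genes, _ = simulate_genome(cfg)
        peaks, counts, truth = simulate_binding(cfg, genes)
        assert all(len(v) == 0 for v in peaks.values())
        assert not truth.occupancy[list(COMPLEX_FACTORS)].any().any()

    def test_marginal_occupancy_calibration(self):
        cfg = SimConfig(n_genes=6000, seed=11)
        genes, _ = simulate_genome(cfg)
        _, _, truth = simulate_binding(cfg, genes)
        occ = truth.occupancy
        for name, p in cfg.complex_occupancy_probs.items():
            se = np.sqrt(p * (1 - p) / len(genes))
            assert abs(occ[name].mean() - p) < 3 * se

    def test_within_complex_correlation_exceeds_cross_complex(self):
        from chromtargets.stats_core import pearson_corr_matrix

        wins = 0
        for seed in range(5):
            cfg = SimConfig(n_genes=2000, seed=seed)
            genes, _ = simulate_genome(cfg)
            _, counts, _ = simulate_binding(cfg, genes)
            corr = pearson_corr_matrix(counts.values, transform="log2p1")
            if corr.loc["TRB1", "ICU11"] > corr.loc["TRB1", "LHP1"]:
                wins += 1
        assert wins == 5

    def test_prc2_avoids_peat(self):
        cfg = SimConfig(n_genes=6000, seed=13)
        genes, _ = simulate_genome(cfg)
        _, _, truth = simulate_binding(cfg, genes)
        occ = truth.occupancy
        p_prc2_given_peat = occ.loc[occ["PEAT"], "PRC2"].mean()
        p_prc2_given_not = occ.loc[~occ["PEAT"], "PRC2"].mean()
        assert p_prc2_given_peat < 0.5 * p_prc2_given_not


class TestMarksAndExpression:
    def _with_truth(self, cfg):
        genes, _ = simulate_genome(cfg)
        _, _, truth = simulate_binding(cfg, genes)
        return genes, truth

    def test_single_replicate_rejected(self):
        cfg = small_cfg(n_replicates=1)
        genes, truth = self._with_truth(cfg)
        with pytest.raises(ValueError, match="replicates"):
            simulate_marks_and_expression(cfg, genes, truth)

    def test_zero_planted_fractions_mean_empty_truth(self):
        cfg = small_cfg(
            planted_fraction_per_subclass={"peat_shared": 0.0, "specific": 0.0, "prc2_shared": 0.0},
            background_expression_change_prob=0.0,
            expression_coupling=0.0,
        )
        genes, truth = self._with_truth(cfg)
        _, _, truth = simulate_marks_and_expression(cfg, genes, truth)
        assert not truth.planted_marks.any().any()
        assert (truth.planted_expression == 0).all().all()

    def test_planted_changes_reference_existing_genes(self):
        cfg = small_cfg()
        genes, truth = self._with_truth(cfg)
        marks, rna, truth = simulate_marks_and_expression(cfg, genes, truth)
        ids = {g.gene_id for g in genes}
        assert set(truth.planted_marks.index) <= ids
        for geno in cfg.genotypes:
            assert set(marks[geno].gene_ids) == ids
            assert set(rna[geno].gene_ids) == ids

    def test_planted_counts_match_bernoulli_rates(self):
        cfg = SimConfig(n_genes=6000, seed=5)
        genes, _ = simulate_genome(cfg)
        _, _, truth = simulate_binding(cfg, genes)
        _, _, truth = simulate_marks_and_expression(cfg, genes, truth)
        pm = truth.planted_marks["jmj14"]
        for sub, p in cfg.planted_fraction_per_subclass.items():
            members = list(truth.subclass_members(sub))
            frac = pm[members].mean()
            se = np.sqrt(p * (1 - p) / len(members))
            assert abs(frac - p) < 4 * se

    def test_wild_type_mark_baselines_ordered(self):
        cfg = SimConfig(n_genes=6000, seed=19)
        genes, _ = simulate_genome(cfg)
        _, _, truth = simulate_binding(cfg, genes)
        marks, _, truth = simulate_marks_and_expression(cfg, genes, truth)
        from chromtargets.genome_io import rpkm

        wt = rpkm(marks["WT"], genes).values.mean(axis=1)
        means = {s: wt[list(truth.subclass_members(s))].mean()
                 for s in ("peat_shared", "specific", "prc2_shared")}
        assert means["peat_shared"] > means["specific"] > means["prc2_shared"]


class TestPlantMotifs:
    def test_joint_probability_arithmetic(self):
        p_both, a_only, b_only, neither = joint_presence_probs(0.5, 0.4, 1.5)
        assert p_both == pytest.approx(0.30)
        assert a_only == pytest.approx(0.20)
        assert neither == pytest.approx(0.40)

    def test_infeasible_joint_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            joint_presence_probs(0.2, 0.9, 5.0)

    def test_full_marginals_plant_both_everywhere(self):
        cfg = small_cfg(n_genes=100, motif_marginals=(1.0, 1.0), motif_cooccurrence_excess=1.0)
        genes, seqs = simulate_genome(cfg)
        peaks, _, _ = simulate_binding(cfg, genes)
        pwm_a, pwm_b = default_pwms()
        edited, truth = plant_motifs(cfg, peaks["TRB1"], seqs, pwm_a, pwm_b)
        assert set(truth.motif_classes.values()) == {"both"}
        for _, row in truth.motif_placements.iterrows():
            peak = next(p for p in peaks["TRB1"] if p.peak_id == row.peak_id)
            pwm = pwm_a if row.motif_id == "telobox" else pwm_b
            assert 0 <= row.offset <= (peak.end - peak.start) - pwm.length
            word = edited[peak.chrom][peak.start + row.offset: peak.start + row.offset + pwm.length]
            from chromtargets.motifs import revcomp

            assert word == (pwm.consensus if row.strand == "+" else revcomp(pwm.consensus))

    def test_independence_excess_near_one_over_many_peaks(self):
        cfg = SimConfig(n_genes=6000, seed=23, motif_cooccurrence_excess=1.0,
                        factor_detection_prob=1.0, peat_given_trht_boost=1.0,
                        complex_occupancy_probs={"TRHT_TRHD": 0.9, "PEAT": 0.05, "PRC2": 0.05})
        genes, seqs = simulate_genome(cfg)
        peaks, _, _ = simulate_binding(cfg, genes)
        trb1 = peaks["TRB1"]
        assert len(trb1) >= 5000
        pwm_a, pwm_b = default_pwms()
        _, truth = plant_motifs(cfg, trb1, seqs, pwm_a, pwm_b)
        vals = list(truth.motif_classes.values())
        n = len(vals)
        p_both = vals.count("both") / n
        p_a = p_both + vals.count("a_only") / n
        p_b = p_both + vals.count("b_only") / n
        assert 0.9 < p_both / (p_a * p_b) < 1.1


class TestStudyDeterminism:
    def test_identical_study_under_same_config(self):
        cfg = small_cfg(n_genes=120)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.sequences == s2.sequences
        assert s1.truth.occupancy.equals(s2.truth.occupancy)
        for geno in s1.mark_counts:
            assert s1.mark_counts[geno].values.equals(s2.mark_counts[geno].values)
        assert s1.truth.motif_placements.equals(s2.truth.motif_placements)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimConfig(factor_detection_prob=1.5)
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=-1)
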