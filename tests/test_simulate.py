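"""Synthetic study generator: annotation, gene sets, cohort, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pathgxe import simulate as sim
from pathgxe.simulate import (
    HALLMARKS,
    BinaryExposure,
    SimulationConfig,
    SimulationError,
)


class TestAnnotation:
    def test_counts_and_window_membership(self):
        cfg = SimulationConfig(
            n_genes=2, snps_per_gene=(3, 3), intergenic_fraction=0.0, seed=1
        )
        genes, snps = sim.make_annotation(cfg)
        assert len(genes) == 2
        assert len(snps) == 6
        merged = snps.merge(genes, on="gene_id")
        assert (
            (merged["pos"] >= merged["window_start"])
            & (merged["pos"] <= merged["window_end"])
        ).all()

    def test_gene_bodies_and_windows_disjoint(self, small_study):
        genes = small_study["genes"].sort_values(["chrom", "start"])
        for _, sub in genes.groupby("chrom"):
            w_end = sub["window_end"].to_numpy()
            w_start = sub["window_start"].to_numpy()
            assert (w_start[1:] > w_end[:-1]).all()

    def test_intergenic_snp_count_exact(self):
        cfg = SimulationConfig(
            n_genes=2, snps_per_gene=(3, 3), intergenic_fraction=0.5, seed=1
        )
        _, snps = sim.make_annotation(cfg)
        assert len(snps) == 9
        assert int(snps["gene_id"].isna().sum()) == 3

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_genes=10, seed=99)
        g1, s1 = sim.make_annotation(cfg)
        g2, s2 = sim.make_annotation(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(s1, s2)
        assert g1.to_csv() == g2.to_csv()  # byte-identical after serialization

    def test_infeasible_packing_reported(self):
        cfg = SimulationConfig(n_genes=5, chrom_length=100_000)
        with pytest.raises(SimulationError, match="chrom_length"):
            sim.make_annotation(cfg)

    def test_invalid_config_lists_violations(self):
        cfg = SimulationConfig(n_cases=0, causal_fraction=2.0)
        with pytest.raises(SimulationError, match="n_cases.*causal_fraction|causal_fraction.*n_cases"):
            cfg.validate()


class TestGeneSets:
    def test_manifest_counts_per_library(self, small_study):
        libs = small_study["libraries"]
        assert set(libs) == {"LIB"}
        assert libs["LIB"].manifest_count == 4
        for members in libs["LIB"].sets.values():
            assert len(members) > 0

    def test_single_pathway_covering_all_genes(self):
        cfg = SimulationConfig(
            n_genes=6,
            n_pathways_per_library={"ONE": 1},
            genes_per_pathway=(6, 6),
            seed=2,
        )
        genes, _ = sim.make_annotation(cfg)
        libs = sim.make_gene_sets(cfg, genes["gene_id"])
        assert set(libs["ONE"].sets["ONE_0001"]) == set(genes["gene_id"])

    def test_oversized_pathway_request_rejected(self):
        cfg = SimulationConfig(n_genes=3, genes_per_pathway=(10, 12))
        with pytest.raises(SimulationError, match="exceeds gene universe"):
            sim.make_gene_sets(cfg, ["G1", "G2", "G3"])

    def test_membership_reproducible(self, small_config):
        genes, _ = sim.make_annotation(small_config)
        a = sim.make_gene_sets(small_config, genes["gene_id"])
        b = sim.make_gene_sets(small_config, genes["gene_id"])
        assert a["LIB"].sets == b["LIB"].sets

    def test_unknown_causal_pathway_rejected(self):
        cfg = SimulationConfig(
            n_genes=10, n_pathways_per_library={"L": 2}, genes_per_pathway=(2, 4),
            causal_pathways=("L_9999",),
        )
        genes, _ = sim.make_annotation(cfg)
        with pytest.raises(SimulationError, match="L_9999"):
            sim.make_gene_sets(cfg, genes["gene_id"])


class TestCohort:
    def test_allele_frequencies_within_binomial_bound(self, small_study):
        cohort = small_study["cohort"]
        n = cohort.genotypes.shape[0]
        maf = cohort.snp_map["maf"].to_numpy()
        obs = cohort.genotypes.mean(axis=0) / 2
        # retrospective sampling perturbs frequencies slightly at causal
        # SNPs; a 5-sd binomial band holds for this effect size
        sd = np.sqrt(maf * (1 - maf) / (2 * n))
        assert (np.abs(obs - maf) < 5 * sd + 0.02).all()

    def test_hwe_genotype_pool(self):
        # chi-square HWE check at alpha=1e-4 passes for >=99% of SNPs
        cfg = SimulationConfig(n_genes=60, snps_per_gene=(4, 8), seed=3)
        _, snps = sim.make_annotation(cfg)
        pool = sim.draw_genotype_pool(cfg, snps)
        n = pool.shape[0]
        failures = 0
        for j in range(pool.shape[1]):
            counts = np.bincount(pool[:, j], minlength=3)
            p_hat = (counts[1] + 2 * counts[2]) / (2 * n)
            expected = n * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
            )
            chi2 = ((counts - expected) ** 2 / expected).sum()
            if sps.chi2.sf(chi2, df=1) < 1e-4:
                failures += 1
        assert failures / pool.shape[1] <= 0.01

    def test_outcome_prevalence_and_quotas(self, small_study):
        cohort = small_study["cohort"]
        cfg = small_study["config"]
        assert cohort.outcome.sum() == cfg.n_cases
        assert (cohort.outcome == 0).sum() == cfg.n_controls
        assert 0 < cohort.outcome.mean() < 1

    def test_truth_marks_exactly_the_causal_fraction(self, small_study):
        cfg = small_study["config"]
        truth = small_study["cohort"].truth
        snps = small_study["snps"]
        causal_genes = set(small_study["libraries"]["LIB"].sets["LIB_0001"])
        eligible = snps.loc[snps["gene_id"].isin(causal_genes), "snp_id"]
        n_expected = int(np.ceil(cfg.causal_fraction * len(eligible)))
        assert truth["causal"].sum() == n_expected
        assert set(truth.index[truth["causal"]]) <= set(eligible)
        assert (truth.loc[truth["causal"], "beta_gxe"] == cfg.beta_gxe).all()
        assert (truth.loc[~truth["causal"], "beta_gxe"] == 0).all()

    def test_quota_unreachable_suggests_recalibration(self):
        cfg = SimulationConfig(
            n_genes=5,
            n_pathways_per_library={"L": 1},
            genes_per_pathway=(2, 3),
            n_cases=500,
            n_controls=500,
            baseline_prevalence=0.001,
            pool_factor=2,
            seed=4,
        )
        genes, snps = sim.make_annotation(cfg)
        libs = sim.make_gene_sets(cfg, genes["gene_id"])
        with pytest.raises(SimulationError, match="recalibrate"):
            sim.simulate_cohort(cfg, snps, libs)


class TestSummaryStatShortcut:
    def _null_setup(self, n_snps, seed=0):
        cfg = SimulationConfig(
            n_genes=max(2, n_snps // 4),
            n_pathways_per_library={"L": 1},
            genes_per_pathway=(2, 2),
            snps_per_gene=(4, 4),
            intergenic_fraction=0.0,
            beta_gxe=0.0,
            seed=seed,
        )
        genes, snps = sim.make_annotation(cfg)
        libs = sim.make_gene_sets(cfg, genes["gene_id"])
        truth = sim.build_truth_table(cfg, snps, libs)
        return snps, truth

    def test_null_rejection_rate_nominal(self):
        # 10,000 null SNPs at V=0.01: rejection rate 0.05 +- 3 sd
        snps, truth = self._null_setup(10_000)
        stats = sim.simulate_summary_stats(truth, snps, 0.01, seed=21)
        frac = (stats["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.007

    def test_wald_pvalue_identities(self):
        snps, truth = self._null_setup(8, seed=5)
        stats = sim.simulate_summary_stats(truth, snps, 0.01, seed=6)
        z = np.abs(stats["beta"] / stats["se"])
        np.testing.assert_allclose(stats["p"], 2 * sps.norm.sf(z), rtol=1e-12)
        # the quantile anchor: |z| = 1.959964 corresponds to p ~ 0.05
        assert 2 * sps.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)
        # and a zero estimate corresponds to p = 1 under the same formula
        assert 2 * sps.norm.sf(0.0) == 1.0

    def test_nonpositive_variance_rejected(self):
        snps, truth = self._null_setup(8, seed=7)
        with pytest.raises(SimulationError):
            sim.simulate_summary_stats(truth, snps, 0.0, seed=0)


class TestAnnotationFixtures:
    def test_exact_scored_count_and_range(self):
        genes = [f"G{i}" for i in range(100)]
        scores, _, _ = sim.make_annotation_fixtures(genes, seed=1, absence_rate=0.3)
        assert len(scores) == 70
        assert scores["otp_score"].between(0, 1).all()

    def test_zero_scores_never_clear_cutoff(self):
        genes = [f"G{i}" for i in range(20)]
        scores, _, _ = sim.make_annotation_fixtures(genes, seed=2, absence_rate=0.0)
        scores["otp_score"] = 0.0
        assert (scores["otp_score"] > 0.05).sum() == 0

    def test_restricted_hallmark_vocabulary(self):
        genes = [f"G{i}" for i in range(50)]
        only = ("Sustaining Proliferative Signalling",)
        _, hm, _ = sim.make_annotation_fixtures(genes, seed=3, hallmarks=only)
        assert set(hm["hallmark"]) <= set(only)

    def test_default_vocabulary_is_the_ten_hallmarks(self):
        genes = [f"G{i}" for i in range(300)]
        _, hm, flags = sim.make_annotation_fixtures(genes, seed=4)
        assert set(hm["hallmark"]) <= set(HALLMARKS)
        assert flags["known_locus"].dtype == bool
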