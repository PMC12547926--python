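"""FDR, category collapsing, overlaps, and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from pathgxe import reporting
from pathgxe.reporting import (
    ReportingError,
    annotate_genes,
    apply_fdr,
    bh_fdr,
    collapse_categories,
    enriched_genes,
    overlap_summary,
    single_exposure_percentage,
)


class TestBhFdr:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.005, 0.1, 0.9])), [0.015, 0.15, 0.9])

    def test_step_up_collapses_to_common_value(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_p_is_its_own_q(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.37])), [0.37])

    def test_agrees_with_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(1e-8, 1, size=rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_q_at_least_p_and_order_invariant(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.001, 1, 50)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ReportingError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ReportingError):
            bh_fdr(np.array([0.5, 1.5]))

    def test_apply_fdr_stratified_by_exposure_and_method(self):
        df = pd.DataFrame(
            {
                "feature_id": ["f1", "f2", "f1", "f2"],
                "library": ["L"] * 4,
                "exposure": ["a", "a", "b", "b"],
                "method": ["ADABF"] * 4,
                "p": [0.01, 0.04, 0.5, 0.9],
            }
        )
        out = apply_fdr(df)
        np.testing.assert_allclose(
            out.loc[out["exposure"] == "a", "q"], bh_fdr(np.array([0.01, 0.04]))
        )
        np.testing.assert_allclose(
            out.loc[out["exposure"] == "b", "q"], bh_fdr(np.array([0.5, 0.9]))
        )


class TestCollapse:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "exposure", "p"])

    def test_minimum_p_per_category_retained(self):
        df = self._table(
            [("pw", "smoking_ever", 0.03), ("pw", "pack_years", 0.01)]
        )
        out = collapse_categories(
            df, {"smoking_ever": "smoking", "pack_years": "smoking"}
        )
        assert len(out) == 1
        assert out.iloc[0]["p"] == 0.01
        assert out.iloc[0]["exposure"] == "pack_years"

    def test_single_member_category_identity(self):
        df = self._table([("pw", "bmi", 0.2)])
        out = collapse_categories(df, {"bmi": "adiposity"})
        assert out.iloc[0]["p"] == 0.2

    def test_tie_broken_lexicographically(self):
        df = self._table([("pw", "zzz", 0.05), ("pw", "aaa", 0.05)])
        out = collapse_categories(df, {"zzz": "c", "aaa": "c"})
        assert out.iloc[0]["exposure"] == "aaa"

    def test_unmapped_exposure_rejected(self):
        df = self._table([("pw", "bmi", 0.2)])
        with pytest.raises(ReportingError, match="bmi"):
            collapse_categories(df, {"height": "anthropometry"})

    def test_one_row_per_feature_category(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "feature_id": rng.choice(["f1", "f2", "f3"], 60),
                "exposure": rng.choice(["a1", "a2", "b1"], 60),
                "p": rng.uniform(0.001, 1, 60),
            }
        ).drop_duplicates(["feature_id", "exposure"])
        cmap = {"a1": "A", "a2": "A", "b1": "B"}
        out = collapse_categories(df, cmap)
        assert not out.duplicated(["feature_id", "category"]).any()
        # never increases any retained p
        for row in out.itertuples():
            sub = df[(df["feature_id"] == row.feature_id)]
            sub = sub[sub["exposure"].map(cmap) == row.category]
            assert row.p == sub["p"].min()


class TestEnrichedGenes:
    def test_threshold_and_dedup_with_host_pathways(self):
        res = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "exposure": ["bmi", "bmi", "bmi"],
                "p": [0.049, 0.3, 0.2],
            }
        )
        members = {"P1": ("g1",), "P2": ("g1", "g2"), "P3": ("g1",)}
        out = enriched_genes(res, members, alpha=0.05)
        assert list(out["gene_id"]) == ["g1"]
        assert out.iloc[0]["host_pathways"] == "P1,P2,P3"

    def test_no_enriched_pathways_warns_empty(self):
        res = pd.DataFrame({"gene_id": ["g"], "exposure": ["e"], "p": [0.001]})
        with pytest.warns(UserWarning):
            out = enriched_genes(res, {}, alpha=0.05)
        assert out.empty


class TestOverlap:
    def test_printed_pair_percentage(self):
        assert single_exposure_percentage(136, 181) == 75.1
        assert single_exposure_percentage(65, 152) == 42.8

    def _results(self, n_single, n_double, method="ADABF", library="BIOCARTA"):
        rows = []
        for i in range(n_single):
            rows.append((f"s{i}", library, "bmi", method, 0.01))
        for i in range(n_double):
            rows.append((f"d{i}", library, "bmi", method, 0.01))
            rows.append((f"d{i}", library, "smoking", method, 0.01))
        return pd.DataFrame(
            rows, columns=["feature_id", "library", "exposure", "method", "p"]
        )

    def test_counts_and_percentages(self):
        out = overlap_summary(self._results(136, 45), alpha=0.05)
        stratum = out["strata"][("ADABF", "BIOCARTA")]
        assert stratum["n_enriched"] == 181
        assert stratum["counts_by_n_exposures"] == {1: 136, 2: 45}
        assert stratum["pct_by_n_exposures"][1] == 75.1
        assert sum(stratum["pct_by_n_exposures"].values()) == pytest.approx(100, abs=0.1)

    def test_single_exposure_only_gives_100_percent(self):
        out = overlap_summary(self._results(10, 0), alpha=0.05)
        assert out["strata"][("ADABF", "BIOCARTA")]["pct_by_n_exposures"] == {1: 100.0}

    def test_cross_method_intersection_requires_both(self):
        df = pd.concat(
            [
                self._results(3, 0, method="ADABF"),
                self._results(1, 0, method="ORA"),
            ]
        )
        out = overlap_summary(df, alpha=0.05)
        assert out["adabf_and_ora"]["bmi"] == {"s0"}  # only the shared feature

    def test_features_at_alpha_boundary_excluded(self):
        df = self._results(2, 0)
        df.loc[df["feature_id"] == "s0", "p"] = 0.05  # not < alpha
        out = overlap_summary(df, alpha=0.05)
        assert out["strata"][("ADABF", "BIOCARTA")]["n_enriched"] == 1


class TestAnnotate:
    def _inputs(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "exposure": ["e"] * 3, "p": [0.01] * 3}
        )
        scores = pd.DataFrame({"gene_id": ["g1", "g2"], "otp_score": [0.05, 0.6]})
        hm = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "hallmark": ["Resisting Cell Death", "Evading Growth Suppressors"],
            }
        )
        loci = pd.DataFrame({"gene_id": ["g2"], "known_locus": [True]})
        return genes, scores, hm, loci

    def test_strict_cutoff_and_unscored_retention(self):
        genes, scores, hm, loci = self._inputs()
        out = annotate_genes(genes, scores, hm, loci, score_cutoff=0.05).set_index("gene_id")
        assert not out.loc["g1", "high_evidence"]  # exactly 0.05 is not > 0.05
        assert out.loc["g2", "high_evidence"]
        assert not out.loc["g3", "scored"]  # absent from scores, kept
        assert len(out) == 3

    def test_multiple_hallmarks_both_reported(self):
        genes, scores, hm, loci = self._inputs()
        out = annotate_genes(genes, scores, hm, loci).set_index("gene_id")
        assert out.loc["g1", "hallmarks"] == (
            "Evading Growth Suppressors;Resisting Cell Death"
        )
        assert out.loc["g1", "any_hallmark"]
        assert not out.loc["g3", "any_hallmark"]
        assert out.loc["g2", "known_locus"]
        assert not out.loc["g1", "known_locus"]
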