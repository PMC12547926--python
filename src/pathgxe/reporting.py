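"""Multiplicity control, exposure-category collapsing, and annotation.

The reporting layer turns per-feature p-values (from ADABF and ORA, per
exposure) into the deliverable tables: Benjamini-Hochberg q-values
within each (exposure, method) stratum, one row per feature and exposure
category (minimum p across sub-measurements), the enriched-gene table,
single/multi-exposure overlap summaries, and prior-evidence annotation
(evidence score, hallmarks of cancer, known risk loci).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd


class ReportingError(ValueError):
    pass


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped
    at 1; output order matches input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ReportingError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_fdr(
    results: pd.DataFrame,
    stratum: str = "pooled",
) -> pd.DataFrame:
    """Attach BH q-values within each (exposure, method) stratum.

    ``stratum="pooled"`` pools libraries within a method (the default);
    ``stratum="library"`` adjusts per library instead.
    """
    if stratum not in ("pooled", "library"):
        raise ReportingError("stratum must be 'pooled' or 'library'")
    keys = ["exposure", "method"] + (["library"] if stratum == "library" else [])
    out = results.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(keys, observed=True).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out


def collapse_categories(
    results: pd.DataFrame,
    category_map: Mapping[str, str],
    feature_cols: tuple[str, ...] = ("feature_id",),
) -> pd.DataFrame:
    """Keep, per (feature, category), the sub-measurement with minimal p.

    Ties between sub-measurements are broken by exposure name
    (lexicographically first wins) for determinism.  Every exposure in
    the table must be mapped to a category.
    """
    unmapped = sorted(set(results["exposure"]) - set(category_map))
    if unmapped:
        raise ReportingError(f"exposures without a category: {unmapped}")
    out = results.copy()
    out["category"] = out["exposure"].map(category_map)
    out = out.sort_values(["p", "exposure"], kind="stable")
    keys = list(feature_cols) + ["category"]
    out = out.drop_duplicates(subset=keys, keep="first")
    return out.sort_values(keys, kind="stable").reset_index(drop=True)


def enriched_genes(
    gene_results: pd.DataFrame,
    enriched_pathway_members: Mapping[str, tuple[str, ...]] | Mapping[tuple, tuple[str, ...]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes with p < alpha inside enriched pathways, deduplicated.

    ``gene_results`` needs gene_id, exposure, p.  Each retained gene row
    lists its host enriched pathways (comma-joined, sorted).
    """
    if not enriched_pathway_members:
        warnings.warn("no enriched pathways; enriched-gene table is empty")
        return pd.DataFrame(columns=["gene_id", "exposure", "p", "host_pathways"])
    gene_to_pathways: dict[str, set[str]] = {}
    for pid, members in enriched_pathway_members.items():
        pid_str = pid if isinstance(pid, str) else ":".join(pid)
        for g in members:
            gene_to_pathways.setdefault(g, set()).add(pid_str)
    hit = gene_results[
        (gene_results["p"] < alpha) & gene_results["gene_id"].isin(gene_to_pathways)
    ].copy()
    hit = hit.sort_values(["p", "exposure"], kind="stable").drop_duplicates(
        subset=["gene_id", "exposure"], keep="first"
    )
    hit["host_pathways"] = hit["gene_id"].map(
        lambda g: ",".join(sorted(gene_to_pathways[g]))
    )
    return hit.sort_values(["gene_id", "exposure"]).reset_index(drop=True)


def single_exposure_percentage(n_single: int, n_total: int) -> float:
    """Percent of enriched features hit by exactly one exposure, 1 decimal."""
    if n_total <= 0:
        raise ReportingError("total enriched count must be positive")
    return round(100.0 * n_single / n_total, 1)


def overlap_summary(
    results: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "p",
) -> dict:
    """Per (method, library) multi-exposure overlap counts and percentages.

    A feature is enriched for an exposure when its ``value_col`` (p by
    default, q for FDR-level summaries) is < alpha.  Returns a dict with
    per-(method, library) strata — total enriched features, counts and
    percentages by number of enriching exposures — plus the per-exposure
    sets of pathways enriched under both methods.
    """
    enriched = results[results[value_col] < alpha]
    strata = {}
    for (method, library), sub in enriched.groupby(["method", "library"], observed=True):
        n_exposures = sub.groupby("feature_id", observed=True)["exposure"].nunique()
        total = int(n_exposures.size)
        counts = n_exposures.value_counts().sort_index()
        strata[(method, library)] = {
            "n_enriched": total,
            "counts_by_n_exposures": {int(k): int(v) for k, v in counts.items()},
            "pct_by_n_exposures": {
                int(k): single_exposure_percentage(int(v), total)
                for k, v in counts.items()
            },
        }
    both: dict[str, set[str]] = {}
    for exposure, sub in enriched.groupby("exposure", observed=True):
        by_method = {
            m: set(s["feature_id"]) for m, s in sub.groupby("method", observed=True)
        }
        if {"ADABF", "ORA"} <= set(by_method):
            both[exposure] = by_method["ADABF"] & by_method["ORA"]
        else:
            both[exposure] = set()
    return {"strata": strata, "adabf_and_ora": both, "alpha": alpha}


def annotate_genes(
    gene_table: pd.DataFrame,
    scores: pd.DataFrame,
    hallmark_map: pd.DataFrame,
    known_loci: pd.DataFrame,
    score_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Join prior-evidence annotations onto the enriched-gene table.

    Adds: otp_score (NaN when the gene is absent from the score table),
    scored flag, high_evidence (score strictly > cutoff), hallmarks
    (semicolon-joined labels, empty when none), any_hallmark, and
    known_locus.  Unscored genes are kept.
    """
    out = gene_table.merge(scores, on="gene_id", how="left")
    out["scored"] = out["otp_score"].notna()
    out["high_evidence"] = out["otp_score"].fillna(-1.0) > score_cutoff
    hm = (
        hallmark_map.groupby("gene_id", observed=True)["hallmark"]
        .apply(lambda s: ";".join(sorted(s)))
        .rename("hallmarks")
        if len(hallmark_map)
        else pd.Series(name="hallmarks", dtype=object)
    )
    out = out.merge(hm, left_on="gene_id", right_index=True, how="left")
    out["hallmarks"] = out["hallmarks"].fillna("")
    out["any_hallmark"] = out["hallmarks"] != ""
    kl = known_loci.set_index("gene_id")["known_locus"]
    out["known_locus"] = out["gene_id"].map(kl).astype("boolean").fillna(False).astype(bool)
    return out
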