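"""End-to-end orchestration: simulate -> scan -> map -> adabf -> ora -> report.

A single YAML/JSON run configuration drives all stages; every artifact
is a TSV stamped with the config hash and master seed, and downstream
stages refuse artifacts produced under a different configuration.
Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import adabf as adabf_mod
from . import io as pio
from . import mapping, ora, reporting, scan, simulate

log = logging.getLogger("pathgxe")

STAGES = ("simulate", "scan", "map", "adabf", "ora", "report")

_SIM_KEYS = {f.name for f in dataclasses.fields(simulate.SimulationConfig)} - {"seed"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated effective run configuration with field defaults.

    Thresholds default to the analysis conventions: prior variance
    W = 0.04, B = 1000 resamples, ±20 kb gene windows, gene-list SNP
    threshold 5e-3, enrichment alpha 0.05, FDR 0.05, evidence-score
    cutoff 0.05.
    """

    outdir: str = "pathgxe_run"
    seed: int = 0
    W: float = adabf_mod.DEFAULT_PRIOR_VARIANCE
    B: int = adabf_mod.DEFAULT_RESAMPLES
    window_kb: float = 20.0
    gene_list_threshold: float = ora.DEFAULT_SNP_P_THRESHOLD
    alpha: float = 0.05
    fdr: float = 0.05
    otp_cutoff: float = 0.05
    fdr_stratum: str = "pooled"
    gene_level: str = "enriched"  # or "genomewide"
    stages: tuple[str, ...] = STAGES
    exposures: list = field(
        default_factory=lambda: [
            {"name": "smoking_ever", "category": "smoking", "dietary": False},
            {"name": "pack_years", "category": "smoking", "dietary": False},
        ]
    )
    covariate_names: tuple[str, ...] = ("age", "sex")
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        errs = []
        for name in ("gene_list_threshold", "alpha", "fdr", "otp_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                errs.append(f"{name}={v} must be in (0, 1)")
        if self.B < 1:
            errs.append(f"B={self.B} must be >= 1")
        if self.W <= 0:
            errs.append(f"W={self.W} must be positive")
        if self.window_kb < 0:
            errs.append(f"window_kb={self.window_kb} must be >= 0")
        if self.fdr_stratum not in ("pooled", "library"):
            errs.append("fdr_stratum must be 'pooled' or 'library'")
        if self.gene_level not in ("enriched", "genomewide"):
            errs.append("gene_level must be 'enriched' or 'genomewide'")
        bad_stages = [s for s in self.stages if s not in STAGES]
        if bad_stages:
            errs.append(f"unknown stages: {bad_stages}")
        if not self.exposures:
            errs.append("at least one exposure is required")
        names = [e.get("name") for e in self.exposures]
        if len(set(names)) != len(names):
            errs.append("exposure names must be unique")
        bad_sim = sorted(set(self.simulation) - _SIM_KEYS)
        if bad_sim:
            errs.append(f"unknown simulation keys: {bad_sim}")
        if errs:
            raise ConfigError("invalid configuration: " + "; ".join(errs))

    def effective(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # analysis parameters only: where artifacts live (and which stages
        # ran) must not change what they contain
        eff = {
            k: v for k, v in self.effective().items() if k not in ("outdir", "stages")
        }
        return pio.config_hash(eff)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Omitted fields take the defaults above; unknown keys and range
    violations are reported together in a single error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    if "stages" in raw:
        cfg.stages = tuple(raw["stages"])
    errs = []
    if unknown:
        errs.append(f"unknown keys: {unknown}")
    try:
        cfg.validate()
    except ConfigError as exc:
        errs.append(str(exc))
    if errs:
        raise ConfigError(f"{path}: " + "; ".join(errs))
    log.info("effective config: %s", json.dumps(cfg.effective(), default=str))
    return cfg


def _sim_config(cfg: RunConfig) -> simulate.SimulationConfig:
    kwargs = dict(cfg.simulation)
    if "exposure_model" in kwargs and isinstance(kwargs["exposure_model"], dict):
        em = kwargs["exposure_model"]
        if em.get("kind") == "continuous":
            kwargs["exposure_model"] = simulate.ContinuousExposure(
                em.get("mean", 0.0), em.get("sd", 1.0)
            )
        else:
            kwargs["exposure_model"] = simulate.BinaryExposure(em.get("prevalence", 0.5))
    for key in ("genes_per_pathway", "snps_per_gene", "maf_range", "causal_pathways"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return simulate.SimulationConfig(seed=cfg.seed, **kwargs)


def _meta(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash, "seed": cfg.seed}


def _path(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


def stage_simulate(cfg: RunConfig) -> None:
    sim = _sim_config(cfg)
    genes, snps = simulate.make_annotation(sim)
    libraries = simulate.make_gene_sets(sim, genes["gene_id"])
    meta = _meta(cfg)
    mapping.write_gene_intervals(
        genes, _path(cfg, "genes.bed"),
        header_comments=[f"pathgxe config_hash={meta['config_hash']} seed={meta['seed']}"],
    )
    for lib in libraries.values():
        mapping.write_gmt(lib, _path(cfg, f"{lib.name}.gmt"))
    pio.write_table(snps, _path(cfg, "snps.tsv"), meta)
    truth = simulate.build_truth_table(sim, snps, libraries)
    pio.write_table(truth.reset_index(), _path(cfg, "truth.tsv"), meta)

    pool = simulate.draw_genotype_pool(sim, snps)
    for i, exp in enumerate(cfg.exposures):
        cohort = simulate.simulate_cohort(
            sim, snps, libraries, exposure_name=exp["name"],
            genotype_pool=pool, truth=truth, seed_offset=i,
        )
        df = pd.DataFrame(cohort.genotypes, columns=cohort.snp_ids)
        df.insert(0, "outcome", cohort.outcome.astype(int))
        df.insert(1, "exposure_value", cohort.exposure)
        for c in cohort.covariates.columns:
            df[c] = cohort.covariates[c].to_numpy()
        pio.write_table(df, _path(cfg, f"cohort_{exp['name']}.tsv"), meta)

    scores, hallmarks, loci = simulate.make_annotation_fixtures(
        genes["gene_id"], seed=cfg.seed
    )
    pio.write_table(scores, _path(cfg, "otp_scores.tsv"), meta)
    pio.write_table(hallmarks, _path(cfg, "hallmarks.tsv"), meta)
    pio.write_table(loci, _path(cfg, "known_loci.tsv"), meta)


def _load_cohort(cfg: RunConfig, exposure_name: str) -> simulate.SimulatedCohort:
    h = cfg.config_hash
    snps = pio.read_table(_path(cfg, "snps.tsv"), expect_hash=h)
    truth = pio.read_table(_path(cfg, "truth.tsv"), expect_hash=h).set_index("snp_id")
    df = pio.read_table(_path(cfg, f"cohort_{exposure_name}.tsv"), expect_hash=h)
    snp_ids = list(snps["snp_id"])
    cov_names = [c for c in df.columns if c not in ("outcome", "exposure_value", *snp_ids)]
    return simulate.SimulatedCohort(
        genotypes=df[snp_ids].to_numpy(),
        snp_ids=snp_ids,
        snp_map=snps.set_index("snp_id")[["chrom", "pos", "gene_id", "maf"]],
        exposure=df["exposure_value"].to_numpy(),
        exposure_name=exposure_name,
        covariates=df[cov_names],
        outcome=df["outcome"].to_numpy(dtype=float),
        truth=truth,
    )


def stage_scan(cfg: RunConfig) -> None:
    logs = {}
    for exp in cfg.exposures:
        cohort = _load_cohort(cfg, exp["name"])
        stats, slog = scan.run_scan(
            cohort,
            exposure=exp["name"],
            covariates=list(cfg.covariate_names),
            dietary=bool(exp.get("dietary", False)),
        )
        pio.write_table(stats, _path(cfg, f"stats_{exp['name']}.tsv"), _meta(cfg))
        logs[exp["name"]] = slog
    with open(_path(cfg, "scan_log.json"), "w") as fh:
        json.dump(logs, fh, indent=2, sort_keys=True)


def _load_libraries(cfg: RunConfig) -> list[mapping.GeneSetLibrary]:
    libs = []
    for name in sorted(os.listdir(cfg.outdir)):
        if name.endswith(".gmt"):
            libs.append(mapping.read_gmt(_path(cfg, name)))
    if not libs:
        raise ConfigError(f"no .gmt libraries found in {cfg.outdir}")
    return libs


def stage_map(cfg: RunConfig) -> None:
    genes = mapping.read_gene_intervals(
        _path(cfg, "genes.bed"), window_bp=int(cfg.window_kb * 1000)
    )
    snps = pio.read_table(_path(cfg, "snps.tsv"), expect_hash=cfg.config_hash)
    assignments = mapping.assign_snps_to_genes(snps, genes)
    pio.write_table(assignments, _path(cfg, "assignments.tsv"), _meta(cfg))


def _feature_sets(cfg: RunConfig):
    assignments = pio.read_table(
        _path(cfg, "assignments.tsv"), expect_hash=cfg.config_hash,
        dtype={"gene_id": "string"},
    )
    libraries = _load_libraries(cfg)
    gene_sets, pathway_sets, dropped = mapping.build_feature_snp_sets(
        assignments, libraries
    )
    return assignments, libraries, gene_sets, pathway_sets, dropped


def stage_adabf(cfg: RunConfig) -> None:
    _, libraries, gene_sets, pathway_sets, dropped = _feature_sets(cfg)
    log.info("feature sets: %s", dropped)
    for exp in cfg.exposures:
        stats = pio.read_table(
            _path(cfg, f"stats_{exp['name']}.tsv"), expect_hash=cfg.config_hash
        )
        present = set(stats["snp_id"])
        psets = {k: frozenset(v & present) for k, v in pathway_sets.items()}
        psets = {k: v for k, v in psets.items() if v}
        res = adabf_mod.run_adabf_for_features(
            stats, psets, kind="pathway",
            prior_variance=cfg.W, B=cfg.B, seed=cfg.seed,
        )
        res.insert(1, "library", [f.split(":", 1)[0] for f in res["feature_id"]])
        res.insert(0, "exposure", exp["name"])
        pio.write_table(res, _path(cfg, f"adabf_pathways_{exp['name']}.tsv"), _meta(cfg))

        if cfg.gene_level == "enriched":
            enriched = set(res.loc[res["p"] < cfg.alpha, "feature_id"])
            keep_genes: set[str] = set()
            for lib in libraries:
                for pid, members in lib.sets.items():
                    if f"{lib.name}:{pid}" in enriched:
                        keep_genes.update(members)
            gsets = {g: s for g, s in gene_sets.items() if g in keep_genes}
        else:
            gsets = dict(gene_sets)
        gsets = {g: frozenset(s & present) for g, s in gsets.items()}
        gsets = {g: s for g, s in gsets.items() if s}
        gres = adabf_mod.run_adabf_for_features(
            stats, gsets, kind="gene",
            prior_variance=cfg.W, B=cfg.B, seed=cfg.seed,
        )
        gres.insert(0, "exposure", exp["name"])
        pio.write_table(gres, _path(cfg, f"adabf_genes_{exp['name']}.tsv"), _meta(cfg))


def stage_ora(cfg: RunConfig) -> None:
    assignments, libraries, gene_sets, _, _ = _feature_sets(cfg)
    background = set(gene_sets)  # genes with >=1 mapped SNP
    for exp in cfg.exposures:
        stats = pio.read_table(
            _path(cfg, f"stats_{exp['name']}.tsv"), expect_hash=cfg.config_hash
        )
        gene_list = ora.build_gene_list(stats, assignments, cfg.gene_list_threshold)
        res = ora.run_ora(gene_list & background, background, libraries)
        res.insert(0, "exposure", exp["name"])
        pio.write_table(res, _path(cfg, f"ora_{exp['name']}.tsv"), _meta(cfg))


def stage_report(cfg: RunConfig) -> dict:
    _, libraries, gene_sets, _, _ = _feature_sets(cfg)
    category_map = {e["name"]: e.get("category", e["name"]) for e in cfg.exposures}
    rows = []
    gene_rows = []
    for exp in cfg.exposures:
        ad = pio.read_table(
            _path(cfg, f"adabf_pathways_{exp['name']}.tsv"), expect_hash=cfg.config_hash
        )
        rows.append(
            ad.assign(method="ADABF")[
                ["feature_id", "library", "exposure", "method", "p"]
            ]
        )
        orr = pio.read_table(
            _path(cfg, f"ora_{exp['name']}.tsv"), expect_hash=cfg.config_hash
        )
        orr = orr.assign(
            method="ORA", feature_id=orr["library"] + ":" + orr["pathway_id"]
        )
        rows.append(orr[["feature_id", "library", "exposure", "method", "p"]])
        gr = pio.read_table(
            _path(cfg, f"adabf_genes_{exp['name']}.tsv"), expect_hash=cfg.config_hash
        )
        gene_rows.append(
            gr.rename(columns={"feature_id": "gene_id"})[["gene_id", "exposure", "p"]]
        )
    pathway_results = pd.concat(rows, ignore_index=True)
    pathway_results = reporting.apply_fdr(pathway_results, stratum=cfg.fdr_stratum)
    pio.write_table(pathway_results, _path(cfg, "report_pathways.tsv"), _meta(cfg))

    collapsed = reporting.collapse_categories(
        pathway_results, category_map, feature_cols=("feature_id", "library", "method")
    )
    pio.write_table(collapsed, _path(cfg, "report_pathways_collapsed.tsv"), _meta(cfg))

    overlaps = reporting.overlap_summary(pathway_results, alpha=cfg.alpha)
    overlaps_fdr = reporting.overlap_summary(
        pathway_results, alpha=cfg.fdr, value_col="q"
    )

    gene_results = pd.concat(gene_rows, ignore_index=True)
    enriched_pids = {
        row.feature_id: ()
        for row in pathway_results.itertuples()
        if row.method == "ADABF" and row.p < cfg.alpha
    }
    members = {}
    for lib in libraries:
        for pid, genes in lib.sets.items():
            key = f"{lib.name}:{pid}"
            if key in enriched_pids:
                members[key] = genes
    genes_table = reporting.enriched_genes(gene_results, members, alpha=cfg.alpha)
    scores = pio.read_table(_path(cfg, "otp_scores.tsv"), expect_hash=cfg.config_hash)
    hallmarks = pio.read_table(_path(cfg, "hallmarks.tsv"), expect_hash=cfg.config_hash)
    loci = pio.read_table(_path(cfg, "known_loci.tsv"), expect_hash=cfg.config_hash)
    annotated = reporting.annotate_genes(
        genes_table, scores, hallmarks, loci, score_cutoff=cfg.otp_cutoff
    )
    pio.write_table(annotated, _path(cfg, "report_genes.tsv"), _meta(cfg))

    def _strata_json(d):
        return {f"{m}/{l}": v for (m, l), v in d["strata"].items()}

    summary = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "n_pathway_results": int(len(pathway_results)),
        "n_enriched_genes": int(annotated["gene_id"].nunique()) if len(annotated) else 0,
        "n_high_evidence_genes": int(
            annotated.loc[annotated["high_evidence"], "gene_id"].nunique()
        )
        if len(annotated)
        else 0,
        "overlap_p": _strata_json(overlaps),
        "overlap_fdr": _strata_json(overlaps_fdr),
        "adabf_and_ora_counts": {
            k: len(v) for k, v in overlaps["adabf_and_ora"].items()
        },
    }
    with open(_path(cfg, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "scan": stage_scan,
    "map": stage_map,
    "adabf": stage_adabf,
    "ora": stage_ora,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None):
    """Run the enabled stages in dependency order.

    A stage failure halts the run; a FAILED marker naming the stage is
    left in the output directory alongside any partial artifacts.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    todo = [s for s in STAGES if s in (stages or cfg.stages)]
    result = None
    for stage_name in todo:
        log.info("stage %s: start", stage_name)
        try:
            result = _STAGE_FUNCS[stage_name](cfg)
        except Exception as exc:
            with open(_path(cfg, "FAILED"), "w") as fh:
                fh.write(f"stage={stage_name}\nerror={exc}\n")
            raise RuntimeError(f"stage '{stage_name}' failed: {exc}") from exc
        log.info("stage %s: done", stage_name)
    marker = _path(cfg, "FAILED")
    if os.path.exists(marker):
        os.remove(marker)
    return result
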