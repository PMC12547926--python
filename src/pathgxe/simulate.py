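"""Self-contained miniature gene-environment interaction study generator.

Produces everything the downstream pipeline consumes — a synthetic gene
annotation with flanking windows, gene-set libraries, a case-control
cohort under a logistic disease model with multiplicative G×E effects
concentrated in designated causal pathways, and (optionally, bypassing
the cohort) summary statistics drawn from the asymptotic sampling
distribution beta_hat ~ Normal(beta_true, V).

Genotypes follow Hardy-Weinberg proportions at each SNP's minor allele
frequency; case/control quotas are filled retrospectively by rejection
sampling from a shared genotype pool, so several exposures can be
scanned against the same genetic background.  Every operation is
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy import stats as sps

from .mapping import GeneSetLibrary, make_gene_intervals

# the ten hallmarks of cancer used to label genes
HALLMARKS = (
    "Activating Invasion and Metastasis",
    "Avoiding Immune Destruction",
    "Deregulating Cellular Metabolism",
    "Enabling Replicative Immortality",
    "Evading Growth Suppressors",
    "Genome Instability and Mutation",
    "Resisting Cell Death",
    "Sustaining Proliferative Signalling",
    "Tumor-promoting Inflammation",
    "Inducing or Accessing Vasculature",
)

# the five gene-set library names with full-scale pathway counts 292/186/
# 196/1614/662; the demo default is a tenth-scale version of the same mix
DEFAULT_LIBRARY_SIZES = {
    "BIOCARTA": 29,
    "KEGG": 19,
    "PID": 20,
    "REACTOME": 161,
    "WIKIPATHWAYS": 66,
}

FULL_SCALE_LIBRARY_SIZES = {
    "BIOCARTA": 292,
    "KEGG": 186,
    "PID": 196,
    "REACTOME": 1614,
    "WIKIPATHWAYS": 662,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class BinaryExposure:
    prevalence: float = 0.5


@dataclass(frozen=True)
class ContinuousExposure:
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class SimulationConfig:
    """Knobs of the miniature study.

    Covariate spec entries are (name, (dist, *params), effect) where dist
    is "normal" or "bernoulli" and effect is the covariate's log-odds
    coefficient in the disease model.
    """

    n_genes: int = 100
    genes_per_pathway: tuple[int, int] = (5, 20)
    n_pathways_per_library: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_SIZES)
    )
    snps_per_gene: tuple[int, int] = (2, 6)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cases: int = 500
    n_controls: int = 500
    exposure_model: BinaryExposure | ContinuousExposure = field(
        default_factory=BinaryExposure
    )
    covariate_spec: Sequence[tuple] = (
        ("age", ("normal", 60.0, 10.0), 0.01),
        ("sex", ("bernoulli", 0.5), 0.2),
    )
    beta_g: float = 0.05
    beta_e: float = 0.2
    beta_gxe: float = 0.3
    causal_pathways: tuple[str, ...] = ()
    causal_fraction: float = 0.5
    intergenic_fraction: float = 0.1
    chrom_length: int = 30_000_000
    baseline_prevalence: float = 0.10
    pool_factor: int = 25
    seed: int = 0

    def validate(self) -> None:
        errs = []
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi < 0.5) and not (0.01 < lo <= hi == 0.5):
            errs.append(f"maf_range {self.maf_range} must lie within (0.01, 0.5]")
        if self.n_cases <= 0 or self.n_controls <= 0:
            errs.append("n_cases and n_controls must be positive")
        if not 0 <= self.causal_fraction <= 1:
            errs.append("causal_fraction must be in [0, 1]")
        if self.n_genes < 1:
            errs.append("n_genes must be >= 1")
        if self.genes_per_pathway[0] < 1 or self.genes_per_pathway[0] > self.genes_per_pathway[1]:
            errs.append("genes_per_pathway must be an increasing positive pair")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            errs.append("snps_per_gene must be an increasing positive pair")
        if not 0 < self.baseline_prevalence < 1:
            errs.append("baseline_prevalence must be in (0, 1)")
        if not 0 <= self.intergenic_fraction < 1:
            errs.append("intergenic_fraction must be in [0, 1)")
        if errs:
            raise SimulationError("; ".join(errs))


@dataclass
class SimulatedCohort:
    """Individual-level data plus the generating truth."""

    genotypes: np.ndarray  # (n_individuals, n_snps) dosages {0,1,2}
    snp_ids: list[str]
    snp_map: pd.DataFrame  # indexed by snp_id: chrom, pos, gene_id, maf
    exposure: np.ndarray
    exposure_name: str
    covariates: pd.DataFrame
    outcome: np.ndarray
    truth: pd.DataFrame  # per snp_id: beta_g, beta_e, beta_gxe, causal


def make_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out non-overlapping genes and their SNPs on synthetic chromosomes.

    Genes are placed with inter-gene gaps wide enough that the ±20 kb
    windows never overlap; each gene receives its configured number of
    SNP positions uniformly within its window, and an additional
    ``intergenic_fraction × n_mappable`` SNPs land in the gaps between
    windows (mapping to no gene).

    Returns ``(gene table, snp table)``; the snp table has columns
    snp_id, chrom, pos, gene_id (NA for intergenic), maf.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA]))
    win = 20_000
    min_len, max_len = 5_000, 50_000
    if config.chrom_length < 2 * win + max_len + 100_000:
        raise SimulationError(
            f"chrom_length {config.chrom_length} too short to place one gene with "
            f"disjoint ±{win} bp windows (needs >= {2 * win + max_len + 100_000})"
        )
    ids, chroms, starts, ends = [], [], [], []
    chrom_idx, cursor = 1, win + 1
    for i in range(config.n_genes):
        length = int(rng.integers(min_len, max_len + 1))
        if cursor + length + win > config.chrom_length:
            chrom_idx += 1
            cursor = win + 1
        ids.append(f"G{i + 1:04d}")
        chroms.append(f"chrS{chrom_idx}")
        starts.append(cursor)
        ends.append(cursor + length - 1)
        # gap > 2*win keeps adjacent windows disjoint
        cursor = ends[-1] + int(rng.integers(2 * win + 1, 2 * win + 40_001))
    genes = make_gene_intervals(ids, chroms, starts, ends, window_bp=win)

    snp_rows = []
    for row in genes.itertuples(index=False):
        k = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
        span = row.window_end - row.window_start + 1
        offs = rng.choice(span, size=k, replace=False)
        for pos in np.sort(offs) + row.window_start:
            snp_rows.append((row.chrom, int(pos), row.gene_id))
    n_mappable = len(snp_rows)
    n_intergenic = int(round(config.intergenic_fraction * n_mappable))
    # gaps between consecutive windows on each chromosome
    gaps = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("window_start")
        prev_end = 0
        for r in sub.itertuples(index=False):
            if r.window_start - 1 > prev_end + 1:
                gaps.append((chrom, prev_end + 1, r.window_start - 1))
            prev_end = r.window_end
    for _ in range(n_intergenic):
        gi = int(rng.integers(len(gaps)))
        chrom, lo, hi = gaps[gi]
        snp_rows.append((chrom, int(rng.integers(lo, hi + 1)), None))

    snp_rows.sort(key=lambda t: (t[0], t[1]))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "gene_id"])
    snps.insert(0, "snp_id", [f"snp{i + 1:06d}" for i in range(len(snps))])
    snps["gene_id"] = snps["gene_id"].astype("string")
    snps["maf"] = rng.uniform(config.maf_range[0], config.maf_range[1], size=len(snps))
    return genes, snps


def make_gene_sets(
    config: SimulationConfig, gene_ids: Sequence[str]
) -> dict[str, GeneSetLibrary]:
    """One gene-set library per configured name, with random memberships."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise SimulationError("need at least one gene id")
    lo, hi = config.genes_per_pathway
    if lo > len(gene_ids):
        raise SimulationError(
            f"smallest requested pathway size {lo} exceeds gene universe of {len(gene_ids)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB]))
    libraries: dict[str, GeneSetLibrary] = {}
    for lib_name, n_pathways in config.n_pathways_per_library.items():
        sets: dict[str, tuple[str, ...]] = {}
        for i in range(n_pathways):
            size = int(rng.integers(lo, min(hi, len(gene_ids)) + 1))
            members = rng.choice(gene_ids, size=size, replace=False)
            sets[f"{lib_name}_{i + 1:04d}"] = tuple(sorted(members))
        libraries[lib_name] = GeneSetLibrary(name=lib_name, sets=sets)
    all_pids = {pid for lib in libraries.values() for pid in lib.sets}
    missing = [p for p in config.causal_pathways if p not in all_pids]
    if missing:
        raise SimulationError(f"causal pathways not present in generated libraries: {missing}")
    return libraries


def _draw_covariates(spec: Sequence[tuple], n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, dist, _effect in spec:
        kind = dist[0]
        if kind == "normal":
            cols[name] = rng.normal(dist[1], dist[2], size=n)
        elif kind == "bernoulli":
            cols[name] = rng.binomial(1, dist[1], size=n).astype(float)
        else:
            raise SimulationError(f"unknown covariate distribution '{kind}'")
    return pd.DataFrame(cols)


def _draw_exposure(model, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, BinaryExposure):
        return rng.binomial(1, model.prevalence, size=n).astype(float)
    if isinstance(model, ContinuousExposure):
        return rng.normal(model.mean, model.sd, size=n)
    raise SimulationError(f"unknown exposure model {model!r}")


def build_truth_table(
    config: SimulationConfig,
    snps: pd.DataFrame,
    libraries: Mapping[str, GeneSetLibrary],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign true per-SNP effects; beta_gxe only within causal pathways.

    Within the union of the causal pathways' genes, a ``causal_fraction``
    of SNPs (rounded up, at least one if any exist) carry the interaction
    effect; those SNPs also carry the main genotype effect beta_g.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC]))
    causal_genes: set[str] = set()
    for pid in config.causal_pathways:
        for lib in libraries.values():
            if pid in lib.sets:
                causal_genes.update(lib.sets[pid])
    eligible = snps.index[snps["gene_id"].isin(sorted(causal_genes))].to_numpy()
    n_causal = int(np.ceil(config.causal_fraction * eligible.size)) if eligible.size else 0
    causal_idx = (
        rng.choice(eligible, size=n_causal, replace=False) if n_causal else np.array([], int)
    )
    truth = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "beta_g": 0.0,
            "beta_e": config.beta_e,
            "beta_gxe": 0.0,
            "causal": False,
        }
    )
    truth.loc[causal_idx, "beta_g"] = config.beta_g
    truth.loc[causal_idx, "beta_gxe"] = config.beta_gxe
    truth.loc[causal_idx, "causal"] = True
    return truth.set_index("snp_id")


def simulate_cohort(
    config: SimulationConfig,
    snps: pd.DataFrame,
    libraries: Mapping[str, GeneSetLibrary],
    exposure_name: str = "exposure",
    genotype_pool: np.ndarray | None = None,
    truth: pd.DataFrame | None = None,
    seed_offset: int = 0,
) -> SimulatedCohort:
    """Retrospective case-control cohort under the logistic G×E model.

    The disease model is logit P(Y=1) = b0 + beta_g·G + beta_e·E +
    beta_gxe·G·E + covariate effects, with interaction effects only on
    the causal SNPs of the designated pathways.  A genotype pool of
    ``pool_factor × (n_cases + n_controls)`` individuals is drawn once
    (or supplied, to share genotypes across exposures); outcomes are
    drawn over the pool and quotas filled by rejection.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xD, seed_offset])
    )
    if genotype_pool is None:
        genotype_pool = draw_genotype_pool(config, snps)
    if genotype_pool.shape[1] != len(snps):
        raise SimulationError("genotype pool width does not match SNP table")
    n_pool = genotype_pool.shape[0]
    if truth is None:
        truth = build_truth_table(config, snps, libraries)
    exposure = _draw_exposure(config.exposure_model, n_pool, rng)
    covariates = _draw_covariates(config.covariate_spec, n_pool, rng)

    bg = truth["beta_g"].to_numpy()
    bgxe = truth["beta_gxe"].to_numpy()
    causal = truth["causal"].to_numpy()
    G = genotype_pool.astype(float)
    lp = np.full(n_pool, float(logit(config.baseline_prevalence)))
    lp += config.beta_e * exposure
    if causal.any():
        Gc = G[:, causal]
        lp += Gc @ bg[causal]
        lp += (Gc * exposure[:, None]) @ bgxe[causal]
    for name, _dist, effect in config.covariate_spec:
        x = covariates[name].to_numpy()
        lp += effect * (x - x.mean())
    prob = expit(lp)
    y = rng.binomial(1, prob).astype(float)

    case_idx = np.nonzero(y == 1)[0]
    ctrl_idx = np.nonzero(y == 0)[0]
    if case_idx.size < config.n_cases or ctrl_idx.size < config.n_controls:
        prev = y.mean()
        raise SimulationError(
            f"case/control quota unreachable from pool of {n_pool} "
            f"(observed prevalence {prev:.4f}); recalibrate baseline_prevalence "
            "or increase pool_factor"
        )
    keep = np.concatenate([case_idx[: config.n_cases], ctrl_idx[: config.n_controls]])
    keep = rng.permutation(keep)
    snp_map = snps.set_index("snp_id")[["chrom", "pos", "gene_id", "maf"]]
    return SimulatedCohort(
        genotypes=genotype_pool[keep],
        snp_ids=list(snps["snp_id"]),
        snp_map=snp_map,
        exposure=exposure[keep],
        exposure_name=exposure_name,
        covariates=covariates.iloc[keep].reset_index(drop=True),
        outcome=y[keep],
        truth=truth,
    )


def draw_genotype_pool(config: SimulationConfig, snps: pd.DataFrame) -> np.ndarray:
    """HWE genotype dosages {0,1,2}: Binomial(2, MAF) per SNP."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE]))
    n_pool = config.pool_factor * (config.n_cases + config.n_controls)
    mafs = snps["maf"].to_numpy()
    return rng.binomial(2, mafs, size=(n_pool, mafs.size)).astype(np.int8)


def interaction_variance(
    n: int, maf: float | np.ndarray, exposure_var: float, case_fraction: float = 0.5,
    exposure_mean: float = 0.0,
) -> float | np.ndarray:
    """Rough asymptotic sampling variance of the logistic G×E estimate.

    Uses V ≈ 1 / (n · ȳ(1-ȳ) · Var(G·E)) with Var(G·E) computed under
    HWE and G ⟂ E.  A coarse default for the summary-statistic shortcut
    generator; unit tests that need an exact V should pass their own.
    """
    maf = np.asarray(maf, dtype=float)
    eg, vg = 2 * maf, 2 * maf * (1 - maf)
    e2g = vg + eg**2
    e2e = exposure_var + exposure_mean**2
    var_ge = e2g * e2e - (eg * exposure_mean) ** 2
    out = 1.0 / (n * case_fraction * (1 - case_fraction) * var_ge)
    return out if out.ndim else float(out)


def simulate_summary_stats(
    truth: pd.DataFrame,
    snps: pd.DataFrame,
    variances: np.ndarray | float,
    seed: int = 0,
    exposure: str = "exposure",
) -> pd.DataFrame:
    """Shortcut generator: beta_hat ~ Normal(beta_true, V), two-sided Wald p.

    Bypasses the cohort entirely; one summary record per SNP in ``truth``
    (indexed by snp_id), with chrom/pos looked up from the SNP table.
    """
    v = np.broadcast_to(np.asarray(variances, dtype=float), (len(truth),)).copy()
    if np.any(v <= 0):
        raise SimulationError("variances must be strictly positive")
    rng = np.random.default_rng(seed)
    beta_true = truth["beta_gxe"].to_numpy()
    beta_hat = rng.normal(beta_true, np.sqrt(v))
    se = np.sqrt(v)
    p = 2.0 * sps.norm.sf(np.abs(beta_hat) / se)
    pos = snps.set_index("snp_id")
    return pd.DataFrame(
        {
            "chrom": pos.loc[truth.index, "chrom"].to_numpy(),
            "pos": pos.loc[truth.index, "pos"].to_numpy(),
            "snp_id": truth.index.to_numpy(),
            "exposure": exposure,
            "beta": beta_hat,
            "se": se,
            "p": p,
        }
    )


def make_annotation_fixtures(
    gene_ids: Sequence[str],
    seed: int = 0,
    absence_rate: float = 0.3,
    hallmark_rate: float = 0.5,
    known_locus_rate: float = 0.01,
    hallmarks: Sequence[str] = HALLMARKS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic prior-evidence fixtures for the annotation stage.

    Stand-ins for the external gene-level resources a real analysis would
    join against: a 0-1 prior-evidence (target-platform-style) score
    table from which ``absence_rate`` of genes is deliberately missing, a
    hallmark-of-cancer label table (weighted towards Sustaining
    Proliferative Signalling), and a known-risk-locus flag table.  Scores
    are drawn as u^10 with u uniform, so roughly the top quarter clears
    the conventional 0.05 highlight cutoff.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise SimulationError("need at least one gene id")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF]))
    n_scored = int(round((1 - absence_rate) * len(gene_ids)))
    scored = sorted(rng.choice(gene_ids, size=n_scored, replace=False))
    scores = pd.DataFrame(
        {"gene_id": scored, "otp_score": rng.uniform(size=n_scored) ** 10}
    )
    weights = np.array([3.0 if h == "Sustaining Proliferative Signalling" else 1.0 for h in hallmarks])
    weights = weights / weights.sum()
    hm_rows = []
    for g in gene_ids:
        if rng.uniform() < hallmark_rate:
            k = min(int(rng.integers(1, 3)), len(hallmarks))
            for h in rng.choice(hallmarks, size=k, replace=False, p=weights):
                hm_rows.append((g, h))
    hallmark_table = pd.DataFrame(hm_rows, columns=["gene_id", "hallmark"])
    flags = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "known_locus": rng.binomial(1, known_locus_rate, size=len(gene_ids)).astype(bool),
        }
    )
    return scores, hallmark_table, flags
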