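# Methods

## The model being tested

For a binary disease outcome Y, genotype dosage G ∈ [0, 2], exposure E,
and covariates X, the per-SNP model is the multiplicative-scale logistic
interaction model

logit P(Y=1) = β₀ + β_G·G + β_E·E + β_GE·G·E + γᵀX,

and the scan tests H₀: β_GE = 0 with a 1-df Wald test. Fitting is
maximum likelihood via iteratively reweighted least squares
(statsmodels GLM, binomial family), with the variance of β̂_GE taken
from the inverse observed information. Convergence is declared at a
deviance change below 1e-10 or stopped at 50 iterations. Fits that do
not converge, or whose estimates diverge (|β̂| > 50 or se > 100,
the signature of quasi-separation), are flagged with a status code and
excluded from downstream aggregation; the run log reports the counts.
The design matrix is rank-checked up front and rank deficiency is an
error naming the offending columns (a monomorphic genotype is the
common case), never a silent NA.

## SNP-to-gene and gene-to-pathway mapping

A SNP belongs to a gene when its position lies inside the gene body
extended by 20 kb on each side, inclusive at both ends, with the 5′
window floored at position 1. Strand is ignored. A SNP inside several
overlapping windows counts for every covering gene — at the
summary-statistic level there is no principled tie-break, and dropping
such SNPs would bias against gene-dense regions. SNPs covered by no
window are retained in the assignment table with an empty gene so they
can be counted, and are excluded from aggregation. Internally all
coordinates are 1-based inclusive; BED input/output uses 0-based
half-open coordinates and is converted at the boundary. Pathway SNP
sets are unions of member-gene SNP sets; features left with zero SNPs
are dropped and counted. No gene-set size filter is applied by default.

## Adaptive combination of Bayes factors (ADABF)

Each SNP's interaction estimate gets a closed-form approximate Bayes
factor under a N(0, W) effect prior:

log BF = ½·log( V̂/(V̂+W) ) + β̂²W / (2V̂(V̂+W)),

computed in log space so extreme z-scores cannot overflow. W defaults
to 0.2² = 0.04 (a plausible scale for log-odds interaction effects) and
is configurable. Natural logarithms are used throughout.

With BFs ordered ascending, the truncation scores are
S_k = Σᵢ I(BF₍ᵢ₎ ≥ BF₍ₖ₎)·log BF₍ᵢ₎; the indicator keeps ties on the ≥
side, so tied positions share a score, and for distinct BFs the scores
telescope: S_k − S_{k+1} = log BF₍ₖ₎.

Significance is Monte Carlo with a fixed number of draws B (default
1000). Null summary statistics are β* = z√V̂ with z standard normal —
independent across SNPs by default, or multivariate normal under a
user-supplied per-feature LD correlation matrix (positive
semi-definiteness is checked; the square root is taken by eigen
decomposition so singular LD matrices work). Each draw is scored
exactly like the observed data. Per truncation point,
p_k = (1 + #{b: S*_{bk} ≥ S_k})/(B+1), and the adaptive statistic is
min_k p_k. Its reference distribution reuses the same B draws in the
adaptive rank-truncated product manner: the observed data and the B
draws are treated as B+1 exchangeable datasets, each draw's own min-p
is its plus-one rank among the other B datasets (remaining draws plus
the observed), and the overall p-value is the plus-one rank of the
observed min-p among the null min-p values. All p-values therefore
live on the grid {1/(B+1), …, 1}, and 1/(B+1) is the attainable floor.
A sequential early-stopping variant was considered and rejected:
fixed-B is reproducible and the per-feature cost is already small.

Per-feature RNG seeds are derived from the master seed and the feature
id by SHA-256 (truncated below 2³¹), so results are invariant to
feature ordering and safe to parallelize. Within a feature, SNPs are
processed in sorted snp_id order, which fixes all remaining ties
deterministically.

Gene-level ADABF is computed, by default, only for genes inside
pathways already enriched at the unadjusted α (the gene table exists to
explain pathway hits); a `gene_level: genomewide` config switch computes
it for every mapped gene instead.

## Over-representation analysis

The per-exposure gene list contains every gene with at least one SNP
interaction p-value strictly below 5×10⁻³. Each pathway's p-value is
the exact hypergeometric upper tail

p = Σ_{j=n}^{min(K,M)} C(L−M, K−j)·C(M, j) / C(L, K)

with K the gene-list size, L the background size, M the pathway size
inside the background, n the observed overlap. It is evaluated by
log-binomial (log-gamma) summation, so large universes are exact to
floating-point precision. The background defaults to all genes with at
least one mapped SNP, and pathways are intersected with the background
before sizing M, so genes outside the analysis universe cannot inflate
a pathway. An empty gene list yields p = 1 everywhere with a warning
rather than an error.

## Multiplicity, collapsing, reporting

Benjamini–Hochberg q-values are computed within each (exposure, method)
stratum, pooling gene-set libraries by default (`fdr_stratum: library`
adjusts per library instead — both conventions are defensible and the
choice is exposed). Exposure sub-measurements (e.g. ever-smoking and
pack-years) are collapsed per feature and category by keeping the
minimum p, ties broken by lexicographically first exposure name.
Overlap summaries count features enriched for exactly 1, 2, 3, …
exposures per method and library at unadjusted p < 0.05, with
percentages rounded to one decimal; FDR-level summaries are produced
alongside from the q-values. Annotation joins three fixture tables onto
the enriched-gene table: a 0–1 prior-evidence score (highlight flag is
strictly score > 0.05; genes absent from the table are kept and flagged
unscored), hallmark-of-cancer labels (all labels reported), and a
known-risk-locus flag.

## The synthetic study generator

The generator emulates the structure of a pooled case–control G×E
consortium study at desk scale. Genes (5–50 kb) are placed on synthetic
chromosomes with gaps wide enough that the ±20 kb windows never
overlap; each gene hosts 2–6 SNP positions inside its window, plus a
configurable fraction of intergenic SNPs that map to nothing. MAFs are
uniform on (0.05, 0.5) — above the 1% floor that a QC'd, imputed panel
would have. Genotypes are Binomial(2, MAF) per SNP (Hardy–Weinberg,
linkage equilibrium). Five libraries named after the standard gene-set
collections are generated at a tenth of their published pathway counts
(29/19/20/161/66) by default; the published sizes themselves
(292/186/196/1614/662, totalling 2950) are available as
`FULL_SCALE_LIBRARY_SIZES`.

Disease status follows the logistic model above with β_GE nonzero only
for a configurable causal fraction of the SNPs inside designated causal
pathways (those SNPs also carry β_G); the intercept is the logit of a
baseline prevalence (default 0.10). Case–control sampling is
retrospective: a genotype pool of `pool_factor` × cohort size
individuals is drawn once, outcomes are drawn over the pool, and the
first n_cases cases and n_controls controls are kept (order then
shuffled). An unreachable quota — the symptom of a mis-calibrated
intercept — is an explicit error. Several exposures can share one
genotype pool, mirroring per-exposure scans over one genotyped
consortium; each exposure redraws outcomes, so its analysis cohort is
its own case–control subset of the pool.

A shortcut generator bypasses the cohort entirely and draws
β̂ ~ N(β_true, V) with two-sided Wald p-values — the asymptotic sampling
distribution of the scan — for fast, exactly-controlled tests of the
aggregation stages. Its default V is the rough asymptotic
1/(n·ȳ(1−ȳ)·Var(G·E)) under independence of G and E; tests that need V
pinned pass it explicitly.

What the generator does *not* emulate: linkage disequilibrium (null
draws are LD-free unless a correlation matrix is supplied), population
stratification and relatedness, genotyping or imputation error,
exposure measurement error, and study-level heterogeneity. Passing
tests therefore demonstrate correctness of the statistics under the
stated model, not robustness to confounding or LD — LD-aware nulls are
available but are only as good as the supplied correlation matrix.

## Numerical and design notes

- Default demo scale (100 genes, ~400 SNPs, 500+500 individuals,
  two exposures) runs the full pipeline in a few seconds; the validation
  suite uses cohorts up to n = 5000 and 100 replicates per effect size
  for power curves, sizes chosen to make the statistical checks sharp at
  interactive runtimes.
- Monte Carlo p-values use plus-one estimators everywhere; nothing can
  return p = 0.
- The hypergeometric tail short-circuits n = 0 to p = 1 and clips the
  log-sum-exp result at 1 to absorb last-bit float excess.
- BH q-values are computed by reverse cumulative minimum over the
  sorted p·m/rank sequence; input order is restored exactly.
- Artifacts carry `# pathgxe config_hash=… seed=…` headers; the hash
  covers analysis parameters only (not output paths), and stages refuse
  to read artifacts whose hash differs from the active config.
- Known limitations: the scan loops SNPs through a general GLM fitter
  (~3 ms/SNP — fine for panels up to ~10⁵ SNPs, not for 7 million);
  pathway ADABF treats shared SNPs in overlapping features
  independently; and the generator's exchangeable, LD-free panel makes
  the independent-null resampling exactly correct by construction,
  which real panels only approximate.
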