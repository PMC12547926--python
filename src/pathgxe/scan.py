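"""Per-SNP 1-df multiplicative gene-environment interaction scan.

For each SNP a logistic regression of case status on
[1, G, E, G*E, covariates] is fit by iteratively reweighted least
squares; the Wald test of the product term's coefficient is the
interaction test.  Genotypes are accepted as any real dosage in [0, 2],
so imputed-dosage data work unchanged.

Non-converged or separated fits are flagged (status != "ok") rather than
silently dropped; ``run_scan`` excludes flagged records from its output
table and reports counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

MAX_ITER = 50
TOL = 1e-10

STAT_COLUMNS = ["chrom", "pos", "snp_id", "exposure", "beta", "se", "p"]


class ScanError(ValueError):
    pass


class RankDeficiencyError(ScanError):
    """Design matrix is not full column rank; names the offending columns."""


@dataclass
class GxeFit:
    beta: float
    variance: float
    se: float
    p: float
    status: str  # "ok" | "non_converged" | "unstable"
    n_iter: int

    @property
    def converged(self) -> bool:
        return self.status == "ok"


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # constant (zero-variance) columns other than the intercept first:
    # the common failure mode is a monomorphic genotype
    sd = X.std(axis=0)
    constant = [names[i] for i in range(1, X.shape[1]) if sd[i] == 0.0]
    if constant:
        raise RankDeficiencyError(
            f"constant columns in design matrix: {constant} "
            "(monomorphic genotype or degenerate exposure/covariate)"
        )
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[i] for i in np.nonzero(diag < tol)[0]]
    if bad:
        raise RankDeficiencyError(f"collinear columns in design matrix: {bad}")


def fit_logistic_gxe(
    genotype: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None,
    outcome: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> GxeFit:
    """ML logistic fit of outcome on [1, G, E, G*E, covariates].

    Returns the interaction coefficient, its variance from the inverse
    observed information, and the two-sided Wald p-value.  The caller
    must supply complete cases; the outcome must contain both classes.
    """
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ScanError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ScanError("outcome has a single class; logistic model is undefined")
    if np.any(g < 0) or np.any(g > 2):
        raise ScanError("genotype dosages must lie in [0, 2]")
    cols = [np.ones_like(g), g, e, g * e]
    names = ["intercept", "G", "E", "GxE"]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != g.size:
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j}")
    X = np.column_stack(cols)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ScanError("missing values in design or outcome; complete-case filter first")
    _check_rank(X, names)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=max_iter, tol=tol)
    beta = float(res.params[3])
    variance = float(res.cov_params()[3, 3])
    se = float(np.sqrt(variance))
    z = beta / se if se > 0 else np.inf
    p = float(2.0 * sps.norm.sf(abs(z)))
    if not res.converged:
        status = "non_converged"
    elif not np.isfinite(se) or se > 100 or abs(beta) > 50:
        status = "unstable"  # quasi-separation: estimates diverging
    else:
        status = "ok"
    return GxeFit(
        beta=beta,
        variance=variance,
        se=se,
        p=max(p, np.finfo(float).tiny),
        status=status,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", max_iter)),
    )


def run_scan(
    cohort,
    exposure: str,
    covariates: list[str] | None = None,
    dietary: bool = False,
    energy_covariate: str = "energy",
) -> tuple[pd.DataFrame, dict]:
    """Scan every SNP in a cohort; returns (summary-stat table, run log).

    ``cohort`` is a :class:`pathgxe.simulate.SimulatedCohort` (or any
    object with the same attributes).  For dietary exposures the total
    energy covariate is mandatory and appended to the adjustment set.
    Flagged (non-converged/unstable) SNPs are excluded from the returned
    table and counted in the log.
    """
    covariates = list(covariates) if covariates else []
    if dietary:
        if energy_covariate not in cohort.covariates.columns:
            raise ScanError(
                f"dietary exposure requires the '{energy_covariate}' covariate, "
                f"which is absent (have: {list(cohort.covariates.columns)})"
            )
        if energy_covariate not in covariates:
            covariates.append(energy_covariate)
    missing = [c for c in covariates if c not in cohort.covariates.columns]
    if missing:
        raise ScanError(f"covariates not in cohort: {missing}")
    cov = cohort.covariates[covariates].to_numpy() if covariates else None
    e = np.asarray(cohort.exposure, dtype=float)
    y = np.asarray(cohort.outcome, dtype=float)

    rows = []
    flagged: dict[str, int] = {}
    for j, snp_id in enumerate(cohort.snp_ids):
        fit = fit_logistic_gxe(cohort.genotypes[:, j], e, cov, y)
        if fit.status != "ok":
            flagged[fit.status] = flagged.get(fit.status, 0) + 1
            continue
        rows.append(
            {
                "chrom": cohort.snp_map.loc[snp_id, "chrom"],
                "pos": int(cohort.snp_map.loc[snp_id, "pos"]),
                "snp_id": snp_id,
                "exposure": exposure,
                "beta": fit.beta,
                "se": fit.se,
                "p": fit.p,
            }
        )
    if not rows:
        raise ScanError("no SNPs survived the scan (all flagged or none supplied)")
    log = {
        "exposure": exposure,
        "n_snps_in": len(cohort.snp_ids),
        "n_snps_out": len(rows),
        "n_flagged": sum(flagged.values()),
        "flagged_by_status": flagged,
        "covariates": covariates,
        "dietary": dietary,
    }
    return pd.DataFrame(rows, columns=STAT_COLUMNS), log
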