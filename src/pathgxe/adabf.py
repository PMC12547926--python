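"""Adaptive combination of Bayes factors (ADABF) for SNP-set association.

Given per-SNP interaction summary statistics (beta_hat, V_hat), each SNP
gets a closed-form approximate Bayes factor under a normal effect prior
with variance W:

    BF = sqrt(V / (V + W)) * exp(beta^2 * W / (2 * V * (V + W)))

Ordering the BFs ascending as BF_(1) <= ... <= BF_(L), the truncation
scores are

    S_k = sum_i I(BF_(i) >= BF_(k)) * log BF_(i),   k = 1..L

so S_k accumulates the log Bayes factors of the k-th smallest BF and
everything above it (ties included by the >=).  The adaptive statistic is
the best (smallest) Monte Carlo p-value over truncation points; its own
significance is assessed against the same B null draws by rank reuse, in
the style of adaptive rank-truncated product tests.  Null summary
statistics are drawn as beta* = z * sqrt(V) with z standard normal,
independent across SNPs by default or multivariate normal under a
user-supplied correlation (LD) matrix.

All Monte Carlo p-values use the plus-one estimator, so 1/(B+1) is the
attainable floor.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_PRIOR_VARIANCE = 0.04  # W = 0.2^2
DEFAULT_RESAMPLES = 1000


class AdabfError(ValueError):
    pass


def wakefield_log_bf(
    beta: np.ndarray | float,
    variance: np.ndarray | float,
    prior_variance: float = DEFAULT_PRIOR_VARIANCE,
) -> np.ndarray | float:
    """Natural-log approximate Bayes factor for a normal effect estimate.

    log BF = 0.5*log(V/(V+W)) + beta^2 * W / (2*V*(V+W)).

    Computed in log space so extreme z-scores cannot overflow.  Symmetric
    in the sign of ``beta``.
    """
    beta = np.asarray(beta, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise AdabfError("variance must be strictly positive")
    if prior_variance <= 0:
        raise AdabfError("prior_variance must be strictly positive")
    w = prior_variance
    out = 0.5 * np.log(variance / (variance + w)) + beta**2 * w / (
        2.0 * variance * (variance + w)
    )
    return out if out.ndim else float(out)


def adabf_scores(log_bf: np.ndarray) -> np.ndarray:
    """Truncation scores S_1..S_L from a vector of log Bayes factors.

    With the BFs sorted ascending, S_k sums log BF over every SNP whose
    BF is >= the k-th smallest; tied values are all included, so tied
    positions share the same score.
    """
    a = np.sort(np.asarray(log_bf, dtype=float))
    if a.size == 0:
        raise AdabfError("need at least one SNP")
    # suffix sums: c[i] = sum(a[i:])
    c = np.cumsum(a[::-1])[::-1]
    # first index of each tie run, so S_k includes ties to the left of k
    first = np.searchsorted(a, a, side="left")
    return c[first]


def _scores_matrix(log_bf: np.ndarray) -> np.ndarray:
    """Row-wise ``adabf_scores`` for a (B, L) matrix, vectorized.

    Exact under ties as well (first-of-run lookup via a running maximum).
    """
    a = np.sort(log_bf, axis=1)
    c = np.cumsum(a[:, ::-1], axis=1)[:, ::-1]
    L = a.shape[1]
    idx = np.arange(L)
    newrun = np.ones(a.shape, dtype=bool)
    newrun[:, 1:] = a[:, 1:] != a[:, :-1]
    first = np.maximum.accumulate(np.where(newrun, idx, 0), axis=1)
    return np.take_along_axis(c, first, axis=1)


def _check_correlation(correlation: np.ndarray, L: int) -> np.ndarray:
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (L, L):
        raise AdabfError(f"correlation matrix must be {L}x{L}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise AdabfError("correlation matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-8:
        raise AdabfError(
            f"correlation matrix not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )
    return corr


def resample_null_scores(
    variances: np.ndarray,
    prior_variance: float = DEFAULT_PRIOR_VARIANCE,
    B: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator = 0,
    correlation: np.ndarray | None = None,
) -> np.ndarray:
    """Draw B null score vectors; returns a (B, L) matrix of S vectors.

    Under the null each SNP's estimate is beta* = z*sqrt(V) with its own
    sampling variance V; z are i.i.d. standard normal, or multivariate
    normal when an LD ``correlation`` matrix is supplied.
    """
    v = np.asarray(variances, dtype=float)
    if np.any(v <= 0):
        raise AdabfError("variances must be strictly positive")
    if B < 1:
        raise AdabfError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = v.size
    if correlation is None:
        z = rng.standard_normal((B, L))
    else:
        corr = _check_correlation(correlation, L)
        # eigen square root handles PSD (singular) LD matrices
        eigvals, eigvecs = np.linalg.eigh(corr)
        root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
        z = rng.standard_normal((B, L)) @ root.T
    beta_null = z * np.sqrt(v)
    log_bf = wakefield_log_bf(beta_null, v, prior_variance)
    return _scores_matrix(np.asarray(log_bf))


@dataclass
class AdabfResult:
    """ADABF outcome for one feature (gene or pathway)."""

    feature_id: str
    L: int
    s: np.ndarray  # observed S_1..S_L
    per_k_p: np.ndarray  # Monte Carlo p-value of each S_k
    p: float  # overall adaptive p-value
    B: int
    seed: int

    @property
    def s_max(self) -> float:
        return float(self.s.max())


def adabf_pvalue(
    beta: np.ndarray,
    variance: np.ndarray,
    prior_variance: float = DEFAULT_PRIOR_VARIANCE,
    B: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator = 0,
    correlation: np.ndarray | None = None,
    feature_id: str = "",
) -> AdabfResult:
    """Adaptive p-value for one SNP set from its summary statistics.

    Per truncation point, p_k = (1 + #{b : S*_bk >= S_k}) / (B+1).  The
    adaptive statistic is min_k p_k.  Following the adaptive rank-
    truncated product convention, the observed data and the B null draws
    are treated as B+1 exchangeable datasets: each null draw's own
    per-k p-values are its plus-one ranks among the other B datasets
    (the remaining draws plus the observed), and the overall p-value is
    the plus-one rank of the observed min-p among the null min-p values.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    variance = np.atleast_1d(np.asarray(variance, dtype=float))
    if beta.shape != variance.shape:
        raise AdabfError("beta and variance must have matching shapes")
    obs_s = adabf_scores(wakefield_log_bf(beta, variance, prior_variance))
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    null_s = resample_null_scores(
        variance, prior_variance, B=B, seed=seed, correlation=correlation
    )
    L = obs_s.size
    per_k_p = np.empty(L)
    null_min_p = np.full(B, np.inf)
    for k in range(L):
        col = np.sort(null_s[:, k])
        lt_obs = np.searchsorted(col, obs_s[k], side="left")
        per_k_p[k] = (1 + B - lt_obs) / (B + 1)
        # null draw b vs the other B datasets (remaining draws + observed):
        # #{b' != b : S_b'k >= S_bk} = (B - lt_b - 1) + I(S_k >= S*_bk)
        lt = np.searchsorted(col, null_s[:, k], side="left")
        ge_obs = (obs_s[k] >= null_s[:, k]).astype(int)
        null_min_p = np.minimum(null_min_p, (B - lt + ge_obs) / (B + 1))
    min_p_obs = per_k_p.min()
    p = (1 + int(np.sum(null_min_p <= min_p_obs))) / (B + 1)
    return AdabfResult(
        feature_id=feature_id,
        L=int(L),
        s=obs_s,
        per_k_p=per_k_p,
        p=float(p),
        B=int(B),
        seed=int(seed_int),
    )


def derive_feature_seed(master_seed: int, feature_id: str) -> int:
    """Stable per-feature seed < 2^31, independent of iteration order."""
    digest = hashlib.sha256(f"{master_seed}:{feature_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_adabf_for_features(
    stats: pd.DataFrame,
    feature_sets: Mapping[str, Iterable[str]] | Mapping[tuple[str, str], Iterable[str]],
    kind: str,
    prior_variance: float = DEFAULT_PRIOR_VARIANCE,
    B: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    correlations: Mapping | None = None,
) -> pd.DataFrame:
    """ADABF over a map of features (gene or pathway SNP sets).

    ``stats`` needs columns ``snp_id``, ``beta``, ``se`` (or ``variance``).
    Each feature gets its own RNG seed derived from the master seed and
    the feature id, so results do not depend on feature order.  SNPs are
    processed in sorted snp_id order for tie-break determinism.
    """
    if stats["snp_id"].duplicated().any():
        raise AdabfError("stats table has duplicate snp_id rows; one record per SNP required")
    if "variance" in stats.columns:
        var = stats.set_index("snp_id")["variance"].astype(float)
    elif "se" in stats.columns:
        var = (stats.set_index("snp_id")["se"].astype(float)) ** 2
    else:
        raise AdabfError("stats table needs a 'variance' or 'se' column")
    beta = stats.set_index("snp_id")["beta"].astype(float)

    rows = []
    for key in feature_sets:
        snp_ids = sorted(feature_sets[key])
        fid = key if isinstance(key, str) else ":".join(key)
        missing = [s for s in snp_ids if s not in beta.index]
        if missing:
            raise AdabfError(
                f"feature '{fid}' references SNPs absent from stats: {missing[:10]}"
            )
        corr = correlations.get(key) if correlations else None
        fseed = derive_feature_seed(seed, fid)
        res = adabf_pvalue(
            beta.loc[snp_ids].to_numpy(),
            var.loc[snp_ids].to_numpy(),
            prior_variance=prior_variance,
            B=B,
            seed=fseed,
            correlation=corr,
            feature_id=fid,
        )
        rows.append(
            {
                "feature_id": fid,
                "kind": kind,
                "L": res.L,
                "S_max": res.s_max,
                "p": res.p,
                "B": res.B,
                "seed": fseed,
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "kind", "L", "S_max", "p", "B", "seed"])
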