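"""Over-representation analysis of per-exposure gene lists.

The gene list for an exposure collects every gene with at least one SNP
whose interaction p-value falls strictly below a threshold (default
5e-3).  For each pathway the upper hypergeometric tail

    p = sum_{j=n}^{min(K, M)} C(L-M, K-j) * C(M, j) / C(L, K)

is the probability of drawing at least the observed number n of pathway
genes into a list of K genes from a background universe of L genes of
which M belong to the pathway.  Evaluated with log-binomials for
numerical stability; pathways are intersected with the background before
sizing M so genes outside the analysis universe cannot inflate it.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .mapping import GeneSetLibrary

DEFAULT_SNP_P_THRESHOLD = 5e-3


class OraError(ValueError):
    pass


def build_gene_list(
    stats: pd.DataFrame,
    assignments: pd.DataFrame,
    threshold: float = DEFAULT_SNP_P_THRESHOLD,
) -> set[str]:
    """Genes with at least one SNP p-value strictly below ``threshold``.

    ``stats`` needs ``snp_id`` and ``p``; ``assignments`` is the long
    SNP-to-gene table (rows with NA gene_id are ignored).
    """
    if not 0 < threshold < 1:
        raise OraError("threshold must be in (0, 1)")
    merged = assignments.dropna(subset=["gene_id"]).merge(
        stats[["snp_id", "p"]], on="snp_id", how="inner"
    )
    if merged.empty:
        return set()
    min_p = merged.groupby("gene_id", observed=True)["p"].min()
    return set(min_p.index[min_p < threshold].astype(str))


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(K: int, L_bg: int, M: int, n: int) -> float:
    """Upper tail P(X >= n) for X ~ Hypergeom(L_bg, M, K).

    K: gene-list size, L_bg: background size, M: pathway size within the
    background, n: observed overlap.  Exact via log-binomial summation.
    """
    for name, val in (("K", K), ("L_bg", L_bg), ("M", M), ("n", n)):
        if val < 0:
            raise OraError(f"{name} must be non-negative, got {val}")
    if M > L_bg or K > L_bg:
        raise OraError(f"M ({M}) and K ({K}) must not exceed L_bg ({L_bg})")
    if n > min(K, M):
        raise OraError(f"overlap n ({n}) exceeds min(K, M) = {min(K, M)}")
    if n == 0:
        return 1.0
    j = np.arange(n, min(K, M) + 1)
    # terms with K-j > L_bg-M are impossible; C(L-M, K-j) handles via -inf
    valid = (K - j) <= (L_bg - M)
    j = j[valid]
    if j.size == 0:
        return 0.0
    log_terms = (
        _log_binom(L_bg - M, K - j) + _log_binom(M, j) - _log_binom(L_bg, K)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def run_ora(
    gene_list: set[str] | Iterable[str],
    background: set[str] | Iterable[str],
    libraries: Iterable[GeneSetLibrary],
) -> pd.DataFrame:
    """Hypergeometric test of every pathway in every library.

    The gene list must be a subset of the background.  Pathways are
    intersected with the background before sizing M.  Columns:
    pathway_id, library, K, L_bg, M, n, p.
    """
    background = set(background)
    gene_list = set(gene_list)
    if not background:
        raise OraError("background gene universe is empty")
    if not gene_list <= background:
        extra = sorted(gene_list - background)[:10]
        raise OraError(f"gene list contains genes outside the background: {extra}")
    if not gene_list:
        warnings.warn("empty gene list: all ORA p-values are 1")
    K = len(gene_list)
    L_bg = len(background)
    rows = []
    for lib in libraries:
        for pid, members in lib.sets.items():
            in_bg = set(members) & background
            M = len(in_bg)
            n = len(gene_list & in_bg)
            p = 1.0 if M == 0 else hypergeometric_tail(K, L_bg, M, n)
            rows.append(
                {
                    "pathway_id": pid,
                    "library": lib.name,
                    "K": K,
                    "L_bg": L_bg,
                    "M": M,
                    "n": n,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["pathway_id", "library", "K", "L_bg", "M", "n", "p"])
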