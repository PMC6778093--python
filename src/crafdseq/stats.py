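"""Downstream statistics: functional-category enrichment of target genes
and rank comparison between enriched and non-enriched peaks.

Category enrichment uses the exact one-sided hypergeometric upper tail:
with ``N`` background genes of which ``K`` carry a category, and ``n``
target genes of which ``k`` carry it,

    p = P[X >= k],  X ~ Hypergeom(N, K, n).

Benjamini–Hochberg adjusted p-values are reported alongside; rows are
flagged significant at raw p < alpha (the conventional reporting filter)
and at adjusted p < alpha.

The rank comparison is a Kruskal–Wallis test on mid-ranks with the usual
tie correction,

    H = [ 12 / (N(N+1)) * sum_g R_g^2 / n_g  -  3(N+1) ]
        / ( 1 - sum_t (t^3 - t) / (N^3 - N) ),

with the p-value from the chi-square distribution with k-1 degrees of
freedom, or — for pooled sample sizes N <= 10, where the chi-square
approximation is poor — from exact enumeration of all assignments of the
pooled observations to the groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from statistics import median
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CrafdValidationError

#: pooled-sample-size cutoff below which the permutation null is enumerated
EXACT_PERMUTATION_MAX_N = 10


@dataclass
class CategoryEnrichmentResult:
    category: str
    n_background: int
    k_background_in_cat: int
    n_targets: int
    k_targets_in_cat: int
    p_value: float
    adjusted_p: float
    significant_raw: bool
    significant_adjusted: bool


def category_enrichment(
    target_genes: Iterable[str],
    background_genes_with_categories: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[CategoryEnrichmentResult]:
    """Hypergeometric over-representation test per functional category.

    ``background_genes_with_categories`` maps every background gene to
    its (possibly multiple) category labels; a gene counts once in every
    category it carries.  Targets must be a subset of the background.
    Results are sorted by raw p-value (ties by category name).
    """
    background = {g: set(cats) for g, cats in background_genes_with_categories.items()}
    targets = set(target_genes)
    missing = targets - background.keys()
    if missing:
        raise CrafdValidationError(
            f"{len(missing)} target genes absent from background, "
            f"e.g. {sorted(missing)[:3]}"
        )
    categories = sorted({c for cats in background.values() for c in cats})
    N, n = len(background), len(targets)
    rows = []
    for cat in categories:
        K = sum(cat in cats for cats in background.values())
        k = sum(cat in background[g] for g in targets)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, K, k, min(p, 1.0)))
    if rows:
        _, adj, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    else:
        adj = []
    results = [
        CategoryEnrichmentResult(
            category=cat,
            n_background=N,
            k_background_in_cat=K,
            n_targets=n,
            k_targets_in_cat=k,
            p_value=p,
            adjusted_p=float(a),
            significant_raw=p < alpha,
            significant_adjusted=float(a) < alpha,
        )
        for (cat, K, k, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

@dataclass
class KruskalResult:
    H: float
    p_value: float
    method: Literal["chi_square", "exact_permutation"]
    group_sizes: list[int]
    rank_sums: list[float]


def _kw_H(pooled_ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    """Tie-corrected H for a given assignment of pooled mid-ranks to groups
    (ranks are listed group by group)."""
    N = pooled_ranks.size
    offset = 0
    acc = 0.0
    for n_g in sizes:
        R = pooled_ranks[offset : offset + n_g].sum()
        acc += R * R / n_g
        offset += n_g
    H = 12.0 / (N * (N + 1)) * acc - 3.0 * (N + 1)
    if tie_term >= 1.0:  # all observations identical
        return 0.0
    return H / (1.0 - tie_term)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: Literal["auto", "chi_square", "exact_permutation"] = "auto",
) -> KruskalResult:
    """Kruskal–Wallis test over two or more groups.

    ``method="auto"`` enumerates the exact permutation null when the
    pooled sample size is at most 10 and falls back to the chi-square
    approximation otherwise; both can be forced.
    """
    if len(groups) < 2:
        raise CrafdValidationError("kruskal_wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise CrafdValidationError("kruskal_wallis groups must be non-empty")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (N**3 - N)) if N > 1 else 1.0
    H = _kw_H(ranks, sizes, tie_term)

    offset = 0
    rank_sums = []
    for n_g in sizes:
        rank_sums.append(float(ranks[offset : offset + n_g].sum()))
        offset += n_g

    if method == "auto":
        method = "exact_permutation" if N <= EXACT_PERMUTATION_MAX_N else "chi_square"

    if H == 0.0:
        p = 1.0
    elif method == "chi_square":
        p = float(sps.chi2.sf(H, df=len(groups) - 1))
    else:
        p = _exact_permutation_p(ranks, sizes, tie_term, H)
    return KruskalResult(
        H=float(H), p_value=p, method=method, group_sizes=sizes, rank_sums=rank_sums
    )


def _exact_permutation_p(
    ranks: np.ndarray, sizes: Sequence[int], tie_term: float, H_obs: float
) -> float:
    """P[H >= H_obs] over all distinct assignments of the pooled ranks to
    groups of the given sizes (enumerated exhaustively)."""
    idx = tuple(range(ranks.size))
    count = total = 0
    tol = 1e-12

    def recurse(remaining: tuple[int, ...], chosen: list[int], g: int) -> None:
        nonlocal count, total
        if g == len(sizes) - 1:
            perm = ranks[np.array(chosen + list(remaining))]
            total += 1
            if _kw_H(perm, sizes, tie_term) >= H_obs - tol:
                count += 1
            return
        for combo in combinations(remaining, sizes[g]):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, chosen + list(combo), g + 1)

    recurse(idx, [], 0)
    return count / total


# ---------------------------------------------------------------------------
# enriched-vs-non-enriched rank comparison
# ---------------------------------------------------------------------------

@dataclass
class RankComparison:
    """Kruskal–Wallis comparison of predicted-interaction ranks between
    enriched and non-enriched peaks (lower rank = stronger prediction)."""

    ranks_enriched: list[float]
    ranks_non_enriched: list[float]
    H: float
    p_value: float
    method: str
    median_enriched: float
    median_non_enriched: float
    direction: Literal["enriched_better", "non_enriched_better", "tie"]


def compare_enriched_ranks(
    peak_table: Iterable[tuple],
    include_partial: bool = False,
    method: Literal["auto", "chi_square", "exact_permutation"] = "auto",
) -> RankComparison:
    """Compare interaction-prediction ranks of enriched vs non-enriched peaks.

    ``peak_table`` rows are ``(peak_id, status, rank)`` where status is an
    enrichment status string or a boolean (True = enriched).  Partially
    enriched peaks are excluded unless ``include_partial``, in which case
    they join the enriched group.
    """
    enr: list[float] = []
    non: list[float] = []
    for peak_id, status, rank in peak_table:
        if isinstance(status, bool):
            status = "enriched" if status else "not_enriched"
        if status == "enriched":
            enr.append(float(rank))
        elif status == "not_enriched":
            non.append(float(rank))
        elif status == "partially_enriched":
            if include_partial:
                enr.append(float(rank))
        else:
            raise CrafdValidationError(f"unknown enrichment status {status!r}")
    if not enr or not non:
        raise CrafdValidationError(
            "both enriched and non-enriched groups must be non-empty"
        )
    kw = kruskal_wallis([enr, non], method=method)
    m_e, m_n = median(enr), median(non)
    if m_e < m_n:
        direction = "enriched_better"
    elif m_e > m_n:
        direction = "non_enriched_better"
    else:
        direction = "tie"
    return RankComparison(
        ranks_enriched=enr,
        ranks_non_enriched=non,
        H=kw.H,
        p_value=kw.p_value,
        method=kw.method,
        median_enriched=m_e,
        median_non_enriched=m_n,
        direction=direction,
    )
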