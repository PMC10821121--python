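"""Nonparametric cohort statistics.

Spearman rank correlation (exact permutation p for small n, t
approximation otherwise) and the Wilcoxon rank-sum / Mann-Whitney test.
Both the R-style W (rank sum of the first group minus its minimum,
identical to the Mann-Whitney U of that group) and the raw rank sum are
reported, because the two conventions are easy to conflate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from fmt_engraft.engraftment import EngraftmentResult, ProvenancePartition


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    rho: float | None
    p_value: float | None
    n: int
    method: str  # "exact-permutation" | "t-approximation"


@dataclass(frozen=True)
class RankSumResult:
    group_a: str
    group_b: str
    W: float  # R convention: rank sum of group a minus n1(n1+1)/2 == U of a
    U: float  # Mann-Whitney U of group a (equal to W)
    U_other: float
    rank_sum: float  # raw rank sum of group a
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal-approximation"


def spearman(
    x, y, x_label: str = "x", y_label: str = "y", exact_max_n: int = 9
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks. For n <= ``exact_max_n``
    the p-value comes from exhaustive permutation of one ranking;
    otherwise from the t approximation. A constant input leaves rho
    undefined (None, with a warning).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return CorrelationResult(x_label, y_label, None, None, n, "undefined")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        p = float(sps.spearmanr(xv, yv).pvalue)
        method = "t-approximation"
    return CorrelationResult(x_label, y_label, rho, p, n, method)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating all pairings of one rank vector."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = num / denom
    tol = 1e-12
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - tol))


def wilcoxon_rank_sum(
    a, b, group_a: str = "a", group_b: str = "b", exact_max_product: int = 400
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Mid-ranks handle ties. The exact null distribution is used when
    n1 * n2 <= ``exact_max_product`` and there are no ties; otherwise the
    normal approximation with continuity and tie correction.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(av), len(bv)
    pooled = np.concatenate([av, bv])
    ranks = sps.rankdata(pooled)
    rank_sum = float(ranks[:n1].sum())
    u1 = rank_sum - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 * n2 <= exact_max_product and not has_ties:
        method = "exact"
        p = float(sps.mannwhitneyu(av, bv, alternative="two-sided", method="exact").pvalue)
    else:
        method = "normal-approximation"
        p = float(
            sps.mannwhitneyu(
                av, bv, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return RankSumResult(
        group_a=group_a,
        group_b=group_b,
        W=u1,
        U=u1,
        U_other=u2,
        rank_sum=rank_sum,
        p_value=p,
        n1=n1,
        n2=n2,
        method=method,
    )


def summarize_cohort(
    results: list[EngraftmentResult], partitions: list[ProvenancePartition]
) -> dict:
    """Cohort-level summary of engraftment rates and provenance fractions.

    Rates: mean/median/min/max over triads with a defined rate
    (undefined rates are counted but excluded from aggregates).
    Fractions: per-class means at each stage, plus unpaired rank-sum
    tests of the pre vs post recipient-derived and always-shared
    fractions (both group orderings of W are recoverable from the
    reported U and U_other).
    """
    rates = [r.rate_percent for r in results if r.defined]
    if not rates:
        raise ValueError("no triad has a defined engraftment rate")
    rates_arr = np.asarray(rates)
    summary: dict = {
        "n_triads": len(results),
        "n_rates_defined": len(rates),
        "n_rates_undefined": len(results) - len(rates),
        "rate_mean_percent": float(rates_arr.mean()),
        "rate_median_percent": float(np.median(rates_arr)),
        "rate_min_percent": float(rates_arr.min()),
        "rate_max_percent": float(rates_arr.max()),
    }
    pre = [p for p in partitions if p.stage == "preFMT"]
    post = [p for p in partitions if p.stage == "postFMT"]
    for stage, parts in (("preFMT", pre), ("postFMT", post)):
        for cls in ("always_shared", "donor_derived", "recipient_derived", "environmental"):
            vals = [p.as_dict()[cls] for p in parts]
            summary[f"{stage}_mean_fraction_{cls}"] = (
                float(np.mean(vals)) if vals else float("nan")
            )
    if pre and post:
        for cls in ("recipient_derived", "always_shared"):
            test = wilcoxon_rank_sum(
                [p.as_dict()[cls] for p in pre],
                [p.as_dict()[cls] for p in post],
                group_a=f"preFMT_{cls}",
                group_b=f"postFMT_{cls}",
            )
            summary[f"wilcoxon_{cls}_W"] = test.W
            summary[f"wilcoxon_{cls}_p"] = test.p_value
    return summary


def summary_table(summary: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"statistic": list(summary.keys()), "value": list(summary.values())}
    ).set_index("statistic")
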