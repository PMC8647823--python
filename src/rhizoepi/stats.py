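"""Shared rank-based and multiple-testing statistics.

Kruskal-Wallis H (tie-corrected) and Fisher's exact test are delegated to
scipy; Dunn's post hoc z-tests on pooled ranks and Benjamini-Hochberg step-up
adjustment are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """One statistical comparison: a statistic, its p-value, and group sizes."""

    comparison: str
    statistic: float
    p: float
    p_adj: float | None = None
    n_per_group: tuple[int, ...] = field(default_factory=tuple)
    skipped: bool = False
    note: str = ""


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sort ascending, set q_i = p_i * m / i, enforce monotone non-decreasing
    from the largest rank down, cap at 1, and restore the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the right enforces monotonicity
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def kruskal_h(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Identical samples in every group yield H = 0, p = 1 rather than scipy's
    all-ties error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 1:
            raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _tie_term(pooled_ranks: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled_ranks, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def dunn_vs_reference(groups: dict[str, np.ndarray], reference: str) -> list[TestResult]:
    """Dunn's multiple-comparison z-tests of every group against a reference.

    Pooled mid-ranks with tie correction; two-sided normal p-values; BH
    adjustment across the family of reference comparisons only.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} missing")
    names = [k for k in groups if k != reference]
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 observations")
    pooled = np.concatenate([arrays[k] for k in arrays])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # slice mean ranks back per group
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for k in arrays:
        n_k = arrays[k].size
        mean_rank[k] = float(np.mean(ranks[pos : pos + n_k]))
        sizes[k] = n_k
        pos += n_k
    tie_corr = _tie_term(ranks) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    results: list[TestResult] = []
    for k in names:
        se2 = var_base * (1.0 / sizes[k] + 1.0 / sizes[reference])
        if se2 <= 0:  # every observation identical
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[k] - mean_rank[reference]) / np.sqrt(se2)
            p = float(2.0 * sps.norm.sf(abs(z)))
        results.append(
            TestResult(
                comparison=f"{k}_vs_{reference}",
                statistic=float(z),
                p=p,
                n_per_group=(sizes[k], sizes[reference]),
            )
        )
    adj = bh_adjust([r.p for r in results]) if results else np.array([])
    for r, q in zip(results, adj):
        r.p_adj = float(q)
    return results


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds ratio, p). The p-value sums hypergeometric probabilities of
    tables at least as extreme as observed (scipy's two-sided convention).
    The odds ratio uses a Haldane +0.5 correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    if np.any(t == 0):
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)
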