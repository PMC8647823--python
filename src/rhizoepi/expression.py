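"""Count normalization, expressed-feature filters and a simplified two-group
differential test.

Normalization is median-of-ratios: each sample's size factor is the median,
over features positive in every sample, of that sample's count divided by the
feature's geometric mean. Expression filters implement the published rules:
TE subfamilies need >= 100 normalized counts (per-sample by default); TE loci
need length > 100 bp and >= 1 RPKM in >= 6 samples; genes need >= 2
normalized counts in >= 2 samples. The differential test is a deliberately
simple stand-in for a full negative-binomial fit: a moderated t-statistic on
log2(normalized + pseudocount), with per-feature variances shrunk toward an
empirical-Bayes prior estimated from all features (the limma construction),
BH correction, and significance at |log2FC| > 0.5 and FDR < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

LFC_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Computed over features with strictly positive counts in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature is positive in every sample; supply a pseudo-reference "
            "or filter samples"
        )
    ref = mat[positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def rpkm(counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all feature lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def apply_expression_filters(
    counts: pd.DataFrame,
    normalized: pd.DataFrame,
    kind: str,
    lengths: pd.Series | None = None,
    totals: pd.Series | None = None,
    subfamily_sum: bool = False,
) -> pd.Index:
    """Expressed-feature set under the published per-kind rules.

    kind='te_subfamily': >= 100 normalized counts in at least one sample
    (``subfamily_sum=True`` switches to the summed-across-samples reading);
    kind='te_locus': length > 100 bp and RPKM >= 1 in >= 6 samples;
    kind='gene': normalized count >= 2 in >= 2 samples.
    """
    if kind == "te_subfamily":
        if subfamily_sum:
            mask = normalized.sum(axis=1) >= 100
        else:
            mask = (normalized >= 100).any(axis=1)
    elif kind == "te_locus":
        if lengths is None:
            raise ValueError("te_locus filter needs feature lengths")
        vals = rpkm(counts, lengths, totals)
        mask = (lengths.reindex(counts.index) > 100) & ((vals >= 1).sum(axis=1) >= 6)
    elif kind == "gene":
        mask = (normalized >= 2).sum(axis=1) >= 2
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return counts.index[mask]


def exclude_genic_tes(te_loci: pd.DataFrame, expressed_genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition TE loci into (nongenic, genic) by >= 1 bp overlap with an
    expressed gene; genic TEs are excluded downstream because their apparent
    expression can come from the host gene."""
    genic_mask = np.zeros(len(te_loci), dtype=bool)
    by_chrom = {c: g for c, g in expressed_genes.groupby("chrom")}
    for i, row in enumerate(te_loci.itertuples(index=False)):
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        genic_mask[i] = bool(((g["start"] < row.end) & (row.start < g["end"])).any())
    return te_loci[~genic_mask], te_loci[genic_mask]


def _moderate_variances(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for per-feature variances.

    Method-of-moments fit on log variances: under a scaled inverse-chi-square
    prior, var(log s^2) = trigamma(d/2) + trigamma(d0/2). Returns d0 = inf
    (complete shrinkage to the common variance) when the observed spread is
    no wider than sampling noise alone.
    """
    from scipy.optimize import brentq
    from scipy.special import digamma, polygamma

    s2_pos = s2[s2 > 0]
    if s2_pos.size < 2:
        return np.inf, float(s2_pos[0]) if s2_pos.size else 0.0
    z = np.log(s2_pos)
    e = z - digamma(d / 2) + np.log(d / 2)
    excess = np.var(z, ddof=1) - float(polygamma(1, d / 2))
    if excess <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = float(brentq(lambda x: float(polygamma(1, x / 2)) - excess, 1e-6, 1e7))
    s0 = float(np.exp(np.mean(e) + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0


def simple_de(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential expression on normalized counts.

    log2FC = log2((mean_B + c) / (mean_A + c)); p from a moderated t-test on
    log2(count + c) whose per-feature variance is shrunk toward an empirical-
    Bayes prior estimated across features; BH-adjusted FDR; significant iff
    |log2FC| > lfc_threshold and FDR < fdr_threshold. A deliberate
    simplification of a dispersion-shrinking negative-binomial fit.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a = normalized[group_a].to_numpy(dtype=float)
    b = normalized[group_b].to_numpy(dtype=float)
    c = pseudocount
    log2fc = np.log2((b.mean(axis=1) + c) / (a.mean(axis=1) + c))
    la, lb = np.log2(a + c), np.log2(b + c)
    na, nb = la.shape[1], lb.shape[1]
    d = na + nb - 2
    s2 = ((na - 1) * la.var(axis=1, ddof=1) + (nb - 1) * lb.var(axis=1, ddof=1)) / d
    d0, s0 = _moderate_variances(s2, d)
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0)
        df = np.inf
    else:
        s2_mod = (d0 * s0 + d * s2) / (d0 + d)
        df = d0 + d
    diff = lb.mean(axis=1) - la.mean(axis=1)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
        p = 2.0 * sps.t.sf(np.abs(t), df)
    # degenerate features (zero moderated variance): no evidence unless shifted
    p = np.where(np.isnan(p) | (se == 0), np.where(diff == 0, 1.0, 0.0), p)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": (np.abs(log2fc) > lfc_threshold) & (fdr < fdr_threshold),
        },
        index=normalized.index,
    )
    out.index.name = "feature"
    return out
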