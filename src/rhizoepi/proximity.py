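"""Nearest-TE assignment per gene and class-level proximity statistics.

Distance is edge-to-edge between half-open intervals, strand-agnostic, 0 on
any overlap. Per gene class the distance distribution to a given TE family is
compared to the core (Class A) genes with a tie-corrected Kruskal-Wallis H
test, and over/under-representation of a family as the closest TE is tested
with Fisher's exact test on the 2x2 class-vs-reference table. Transposon-like
genes are excluded upstream (they are themselves TE-derived).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, fisher_2x2, kruskal_h


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 on overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end)


def nearest_te(genes: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Closest TE per gene: (gene_id, te_id, family, superfamily, distance).

    Minimum edge-to-edge distance over all TEs on the gene's chromosome; ties
    broken by leftmost TE start, then smallest TE id. Genes on chromosomes
    with no TE get distance NaN and are excluded from downstream tests.
    """
    rows = []
    te_by_chrom = {
        c: g.sort_values(["start", "te_id"]).reset_index(drop=True)
        for c, g in tes.groupby("chrom")
    }
    for row in genes.itertuples(index=False):
        grp = te_by_chrom.get(row.chrom)
        if grp is None or grp.empty:
            rows.append((row.gene_id, None, None, None, float("nan")))
            continue
        ts = grp["start"].to_numpy()
        te = grp["end"].to_numpy()
        d = np.maximum(np.maximum(ts - row.end, row.start - te), 0)
        i = int(np.argmin(d))  # argmin takes the first minimum = leftmost start
        rows.append(
            (row.gene_id, grp.at[i, "te_id"], grp.at[i, "family"],
             grp.at[i, "superfamily"], float(d[i]))
        )
    return pd.DataFrame(rows, columns=["gene_id", "te_id", "family", "superfamily", "distance"])


def _merged(nearest: pd.DataFrame, classes: pd.DataFrame) -> pd.DataFrame:
    df = nearest.merge(classes, on="gene_id", how="inner")
    df = df[df["gene_class"] != "transposon_related"]
    return df[df["distance"].notna()]


def distance_class_test(
    nearest: pd.DataFrame,
    classes: pd.DataFrame,
    families: list[str] | None = None,
    reference: str = "A",
) -> list[TestResult]:
    """Kruskal-Wallis test of each class's distance-to-family vs the reference.

    Restricted per family to genes whose closest TE belongs to that family.
    Groups with fewer than two observations are skipped with a flag. BH
    adjustment is applied within the family-panel of comparisons.
    """
    df = _merged(nearest, classes)
    if families is None:
        families = sorted(df["family"].dropna().unique())
    results: list[TestResult] = []
    for fam in families:
        sub = df[df["family"] == fam]
        ref = sub.loc[sub["gene_class"] == reference, "distance"].to_numpy()
        for cls in sorted(sub["gene_class"].unique()):
            if cls == reference:
                continue
            grp = sub.loc[sub["gene_class"] == cls, "distance"].to_numpy()
            name = f"{fam}:{cls}_vs_{reference}"
            if ref.size < 2 or grp.size < 2:
                results.append(TestResult(name, float("nan"), float("nan"),
                                          n_per_group=(grp.size, ref.size),
                                          skipped=True, note="<2 observations"))
                continue
            h, p = kruskal_h(grp, ref)
            results.append(TestResult(name, h, p, n_per_group=(grp.size, ref.size)))
    tested = [r for r in results if not r.skipped]
    adj = bh_adjust([r.p for r in tested]) if tested else []
    for r, q in zip(tested, adj):
        r.p_adj = float(q)
    return results


def closest_family_enrichment(
    nearest: pd.DataFrame,
    classes: pd.DataFrame,
    family: str,
    gene_class: str,
    reference: str = "A",
) -> TestResult:
    """Fisher's exact test: is ``family`` over-represented as the closest TE
    of ``gene_class`` genes relative to the reference class?

    2x2 table: rows = (gene_class, reference), columns = (closest TE is
    family, closest TE is another family).
    """
    df = _merged(nearest, classes)
    rows = []
    for cls in (gene_class, reference):
        sub = df[df["gene_class"] == cls]
        hit = int((sub["family"] == family).sum())
        rows.append([hit, len(sub) - hit])
    name = f"{family}:{gene_class}_vs_{reference}"
    n = (int(sum(rows[0])), int(sum(rows[1])))
    if 0 in n:
        return TestResult(name, float("nan"), float("nan"), n_per_group=n,
                          skipped=True, note="empty class margin")
    odds, p = fisher_2x2(rows)
    return TestResult(name, odds, p, n_per_group=n)


def kw_dunn(groups: dict[str, np.ndarray], reference: str = "A") -> tuple[float, float, list[TestResult]]:
    """Overall Kruskal-Wallis H plus Dunn's pairwise z-tests vs the reference.

    Returns (H, p_overall, reference comparisons with BH-adjusted p).
    """
    from .stats import dunn_vs_reference

    arrays = [np.asarray(v, float) for v in groups.values()]
    h, p = kruskal_h(*arrays)
    pairwise = dunn_vs_reference({k: np.asarray(v, float) for k, v in groups.items()}, reference)
    if h == 0.0:  # all observations identical: pairwise p forced to 1
        for r in pairwise:
            r.p = 1.0
            r.p_adj = 1.0
    return h, p, pairwise
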