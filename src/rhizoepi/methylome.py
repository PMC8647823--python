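"""Strand-merged CpG methylation scoring, bimodality and metagene profiles.

Per-site 5mC calls arrive as (chrom, pos0, strand, meth_freq, coverage)
records, one per cytosine. Symmetric CG calls — the plus-strand C at pos and
the minus-strand C at pos+1 — are merged to a single site keyed on the
plus-strand C, with a coverage-weighted mean frequency. Per-locus mCG scores
are the median site frequency inside the interval (the `bedtools map -median`
convention); loci with no sites are flagged undefined, never scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand", "meth_freq", "coverage"]


@dataclass(frozen=True)
class LocusMethylation:
    locus_id: str
    mcg_score: float  # NaN when undefined
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.n_sites > 0


def merge_symmetric_cg(records: pd.DataFrame) -> pd.DataFrame:
    """Merge plus/minus strand calls of each CpG into one plus-strand site.

    A minus-strand record at pos p pairs with a plus-strand record at p-1.
    Merged frequency is the coverage-weighted mean; coverages add. Unpaired
    records pass through unchanged (minus singletons re-keyed to the plus-C
    position p-1 so every site has one canonical coordinate).
    """
    df = records[SITE_COLUMNS].copy()
    if df["strand"].isin(["+", "-"]).all() is False:
        raise ValueError("strand must be '+' or '-'")
    if ((df["meth_freq"] < 0) | (df["meth_freq"] > 1)).any():
        raise ValueError("meth_freq outside [0, 1]")
    if (df["coverage"] < 1).any():
        raise ValueError("coverage must be >= 1")
    # canonical site key: plus-strand C position of the CpG
    df["site"] = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"])
    dup = df.duplicated(subset=["chrom", "strand", "pos"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate {first['strand']}-strand record at {first['chrom']}:{first['pos']}"
        )
    df["mass"] = df["meth_freq"] * df["coverage"]
    g = df.groupby(["chrom", "site"], sort=True).agg(
        mass=("mass", "sum"), coverage=("coverage", "sum")
    )
    out = g.reset_index().rename(columns={"site": "pos"})
    out["meth_freq"] = out["mass"] / out["coverage"]
    return out[["chrom", "pos", "meth_freq", "coverage"]]


def score_locus(sites: pd.DataFrame, chrom: str, start: int, end: int, locus_id: str = "") -> LocusMethylation:
    """Median site methylation over a 0-based half-open interval."""
    if end <= start:
        raise ValueError(f"malformed interval [{start}, {end})")
    sel = sites[(sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] < end)]
    n = len(sel)
    score = float(np.median(sel["meth_freq"].to_numpy())) if n else float("nan")
    return LocusMethylation(locus_id=locus_id, mcg_score=score, n_sites=n)


def score_loci(sites: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-locus median mCG for a frame of (locus_id, chrom, start, end).

    Undefined loci (no covered CpG) carry mcg_score = NaN and n_sites = 0.
    """
    if (loci["end"] <= loci["start"]).any():
        raise ValueError("malformed interval (end <= start)")
    out = []
    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom")}
    for row in loci.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            out.append((row.locus_id, float("nan"), 0))
            continue
        pos = g["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [row.start, row.end])
        n = int(hi - lo)
        score = float(np.median(g["meth_freq"].to_numpy()[lo:hi])) if n else float("nan")
        out.append((row.locus_id, score, n))
    return pd.DataFrame(out, columns=["locus_id", "mcg_score", "n_sites"])


def classify_sites(sites: pd.DataFrame, hi: float = 0.8, lo: float = 0.2) -> tuple[float, float, float]:
    """Fractions of sites highly (> hi), weakly (< lo) and intermediately methylated.

    Thresholds are strict, matching the bimodality summary convention.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    freq = sites["meth_freq"].to_numpy()
    if freq.size == 0:
        raise ValueError("no sites to classify")
    f_hi = float(np.mean(freq > hi))
    f_lo = float(np.mean(freq < lo))
    return f_hi, f_lo, 1.0 - f_hi - f_lo


def classify_gene_methylation(scores: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Label defined per-gene scores 'high' (score > threshold) or 'low'."""
    if scores["mcg_score"].isna().any():
        raise ValueError("undefined scores passed; filter n_sites == 0 loci first")
    return pd.Series(
        np.where(scores["mcg_score"] > threshold, "high", "low"),
        index=scores.index,
        name="meth_class",
    )


def metagene_profile(
    loci: pd.DataFrame,
    sites: pd.DataFrame,
    flank: int = 2000,
    body_bins: int = 50,
    flank_bin: int = 100,
) -> pd.DataFrame:
    """Mean mCG across scaled gene/TE bodies and fixed-width flanks.

    Body positions map to ``floor(body_bins * relative_position)``; each flank
    is tiled in ``flank_bin``-bp bins. Minus-strand loci are mirrored so the
    profile always reads 5' upstream -> body -> 3' downstream. Returns a frame
    (region, bin, mean_mcg, n) where region is upstream/body/downstream; loci
    shorter than 1 bp are skipped and counted in ``attrs['skipped']``.
    """
    n_flank = flank // flank_bin
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    skipped = 0
    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom")}

    def add(region: str, b: int, freqs: np.ndarray) -> None:
        key = (region, b)
        sums[key] = sums.get(key, 0.0) + float(freqs.sum())
        counts[key] = counts.get(key, 0) + int(freqs.size)

    for row in loci.itertuples(index=False):
        length = row.end - row.start
        if length < 1:
            skipped += 1
            continue
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        freq = g["meth_freq"].to_numpy()
        strand = getattr(row, "strand", "+")
        lo, hi = np.searchsorted(pos, [row.start - flank, row.end + flank])
        p, f = pos[lo:hi], freq[lo:hi]
        in_body = (p >= row.start) & (p < row.end)
        left = p < row.start
        right = p >= row.end
        rel = (p[in_body] - row.start) / length
        body_idx = np.minimum((rel * body_bins).astype(int), body_bins - 1)
        left_idx = np.minimum((row.start - 1 - p[left]) // flank_bin, n_flank - 1).astype(int)
        right_idx = np.minimum((p[right] - row.end) // flank_bin, n_flank - 1).astype(int)
        if strand == "-":
            body_idx = body_bins - 1 - body_idx
            left_idx, right_idx = right_idx, left_idx
            up_f, down_f = f[right], f[left]
        else:
            up_f, down_f = f[left], f[right]
        # upstream bins count outward from the body: bin 0 is farthest 5'
        for b in np.unique(left_idx if strand == "+" else right_idx):
            sel = (left_idx if strand == "+" else right_idx) == b
            add("upstream", int(n_flank - 1 - b), up_f[sel])
        for b in np.unique(body_idx):
            add("body", int(b), f[in_body][body_idx == b])
        for b in np.unique(right_idx if strand == "+" else left_idx):
            sel = (right_idx if strand == "+" else left_idx) == b
            add("downstream", int(b), down_f[sel])

    order = {"upstream": 0, "body": 1, "downstream": 2}
    records = [
        {"region": r, "bin": b, "mean_mcg": sums[(r, b)] / counts[(r, b)], "n": counts[(r, b)]}
        for (r, b) in sorted(sums, key=lambda k: (order[k[0]], k[1]))
    ]
    df = pd.DataFrame(records, columns=["region", "bin", "mean_mcg", "n"])
    df.attrs["skipped"] = skipped
    return df
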