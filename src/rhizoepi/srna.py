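"""Small-RNA locus calling, read profiling, treatment-enrichment flags,
genomic-origin assignment and a shuffled-locus distance null.

Locus calling is a simplified island clusterer mirroring the published
parameters: reads within ``pad`` bp of each other merge into islands, islands
below ``mincov`` reads-per-million-mapped (over the pooled libraries) are
dropped, a locus is stranded when the majority strand carries >= the strand
cutoff of its reads, and its dicer call reflects whether the modal read
length falls in [dicermin, dicermax]. Secondary-structure (foldsize) analysis
is intentionally not implemented.

Origin assignment is hierarchical: any >= 1 bp overlap with a classified TE
wins (split by the TE's expression flag), then overlap with an expressed
gene, else unannotated; overlaps with non-expressed genes fall through to
unannotated and are tallied.

The permutation null re-places every locus uniformly at random (chromosome
weighted by length, start uniform so the locus fits, length preserved) and
compares observed vs shuffled nearest-TE distances with a Kruskal-Wallis
H test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, kruskal_h

LIBRARIES = ("untreated", "oxidized", "trapr")

READ_COLUMNS = ["chrom", "start", "end", "strand", "sequence", "library", "count"]


@dataclass
class LocusCallParams:
    pad: int = 200
    mincov_rpmm: float = 10.0
    dicermin: int = 20
    dicermax: int = 27
    strand_cutoff: float = 0.8


def call_loci(reads: pd.DataFrame, params: LocusCallParams | None = None) -> pd.DataFrame:
    """Cluster pooled reads into sRNA loci.

    Reads from all libraries are pooled before clustering. Returns a frame
    with locus id, interval, per-library counts, strand fraction/flag, modal
    read length and dicer call.
    """
    if params is None:
        params = LocusCallParams()
    total = int(reads["count"].sum())
    if total == 0:
        raise ValueError("no mapped reads")
    threshold = params.mincov_rpmm * total / 1e6
    loci_rows = []
    locus_idx = 0
    for chrom, grp in reads.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # island break where the gap to the running max end exceeds pad
        run_end = np.maximum.accumulate(ends)
        breaks = np.zeros(len(grp), dtype=bool)
        breaks[1:] = starts[1:] - run_end[:-1] > params.pad
        island = np.cumsum(breaks)
        grp = grp.assign(_island=island)
        for _, isl in grp.groupby("_island", sort=True):
            pooled = int(isl["count"].sum())
            if pooled < threshold:
                continue
            counts = {
                f"count_{lib}": int(isl.loc[isl["library"] == lib, "count"].sum())
                for lib in LIBRARIES
            }
            plus = int(isl.loc[isl["strand"] == "+", "count"].sum())
            frac = max(plus, pooled - plus) / pooled
            lengths = (isl["end"] - isl["start"]).to_numpy()
            modal = int(
                pd.Series(np.repeat(lengths, isl["count"].to_numpy())).mode().iloc[0]
            )
            loci_rows.append(
                {
                    "locus_id": f"locus_{locus_idx:05d}",
                    "chrom": chrom,
                    "start": int(isl["start"].min()),
                    "end": int(isl["end"].max()),
                    "total_count": pooled,
                    **counts,
                    "strand_fraction": float(frac),
                    "stranded": frac >= params.strand_cutoff,
                    "major_length": modal,
                    "dicer_call": params.dicermin <= modal <= params.dicermax,
                }
            )
            locus_idx += 1
    return pd.DataFrame(
        loci_rows,
        columns=[
            "locus_id", "chrom", "start", "end", "total_count",
            *(f"count_{lib}" for lib in LIBRARIES),
            "strand_fraction", "stranded", "major_length", "dicer_call",
        ],
    )


def profile_reads(reads: pd.DataFrame, library: str, lengths: range = range(18, 36)) -> pd.DataFrame:
    """Length x first-nucleotide count matrix for one library (T shown as U)."""
    sub = reads[reads["library"] == library]
    mat = pd.DataFrame(0, index=list(lengths), columns=["A", "C", "G", "U"])
    if sub.empty:
        return mat
    length = (sub["end"] - sub["start"]).to_numpy()
    first = sub["sequence"].str[0].str.upper().replace("T", "U").to_numpy()
    count = sub["count"].to_numpy()
    for L, nt, c in zip(length, first, count):
        if L in mat.index and nt in mat.columns:
            mat.at[L, nt] += int(c)
    return mat


def enrichment_classify(
    oxidized_de: pd.DataFrame,
    trapr_de: pd.DataFrame,
    lfc_threshold: float = 0.0,
    fdr_threshold: float = 0.05,
    drop_unenriched: bool = False,
) -> pd.DataFrame:
    """Per-locus enrichment flags from the two treatment-vs-untreated tests.

    A locus is enriched in a treatment when log2FC > lfc_threshold at
    FDR < fdr_threshold there, and depleted when log2FC < -lfc_threshold at
    FDR < fdr_threshold in either treatment. The retained set drops depleted
    loci; ``drop_unenriched`` additionally drops loci enriched by neither
    treatment.
    """
    if not oxidized_de.index.equals(trapr_de.index):
        missing = oxidized_de.index.symmetric_difference(trapr_de.index)
        raise ValueError(f"designs must cover the same loci; mismatched: {list(missing)[:5]}")
    ox_enr = (oxidized_de["log2fc"] > lfc_threshold) & (oxidized_de["fdr"] < fdr_threshold)
    tr_enr = (trapr_de["log2fc"] > lfc_threshold) & (trapr_de["fdr"] < fdr_threshold)
    depleted = (
        ((oxidized_de["log2fc"] < -lfc_threshold) & (oxidized_de["fdr"] < fdr_threshold))
        | ((trapr_de["log2fc"] < -lfc_threshold) & (trapr_de["fdr"] < fdr_threshold))
    )
    retained = ~depleted
    if drop_unenriched:
        retained &= ox_enr | tr_enr
    return pd.DataFrame(
        {
            "oxidized_enriched": ox_enr,
            "trapr_enriched": tr_enr,
            "dual_enriched": ox_enr & tr_enr,
            "depleted": depleted,
            "retained": retained,
        },
        index=oxidized_de.index,
    )


ORIGINS = ("TE_expressed", "TE_nonexpressed", "genic", "unannotated")


def assign_origin(
    loci: pd.DataFrame,
    tes: pd.DataFrame,
    expressed_te_ids: set[str],
    genes: pd.DataFrame,
    expressed_gene_ids: set[str],
) -> pd.DataFrame:
    """Hierarchical genomic-origin label per locus.

    TE overlap beats gene overlap; among conflicting TE overlaps the larger
    overlap wins and an exact tie goes to the expressed copy. Returns
    (locus_id, origin, matched_id) with a tally of non-expressed-gene
    fall-throughs in ``attrs['nonexpressed_gene_overlaps']``.
    """
    te_by_chrom = {c: g for c, g in tes.groupby("chrom")}
    gene_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    rows = []
    fallthrough = 0
    for row in loci.itertuples(index=False):
        origin, matched = "unannotated", None
        t = te_by_chrom.get(row.chrom)
        if t is not None:
            ov = np.minimum(t["end"].to_numpy(), row.end) - np.maximum(t["start"].to_numpy(), row.start)
            hit = ov > 0
            if hit.any():
                sub = t[hit].assign(_ov=ov[hit])
                sub = sub.assign(_expr=sub["te_id"].isin(expressed_te_ids))
                sub = sub.sort_values(["_ov", "_expr"], ascending=[False, False])
                best = sub.iloc[0]
                matched = best["te_id"]
                origin = "TE_expressed" if best["_expr"] else "TE_nonexpressed"
        if matched is None:
            g = gene_by_chrom.get(row.chrom)
            if g is not None:
                ov = np.minimum(g["end"].to_numpy(), row.end) - np.maximum(g["start"].to_numpy(), row.start)
                hit = ov > 0
                if hit.any():
                    sub = g[hit].assign(_ov=ov[hit])
                    expressed = sub[sub["gene_id"].isin(expressed_gene_ids)]
                    if not expressed.empty:
                        origin = "genic"
                        matched = expressed.loc[expressed["_ov"].idxmax(), "gene_id"]
                    else:
                        fallthrough += 1
        rows.append((row.locus_id, origin, matched))
    out = pd.DataFrame(rows, columns=["locus_id", "origin", "matched_id"])
    out.attrs["nonexpressed_gene_overlaps"] = fallthrough
    return out


def _nearest_te_distance(loci: pd.DataFrame, tes: pd.DataFrame) -> np.ndarray:
    """Edge-to-edge distance to the nearest TE per locus (NaN if no TE on chrom)."""
    out = np.full(len(loci), np.nan)
    te_by_chrom = {c: g for c, g in tes.groupby("chrom")}
    for i, row in enumerate(loci.itertuples(index=False)):
        t = te_by_chrom.get(row.chrom)
        if t is None or t.empty:
            continue
        d = np.maximum(np.maximum(t["start"].to_numpy() - row.end, row.start - t["end"].to_numpy()), 0)
        out[i] = d.min()
    return out


def shuffle_loci(loci: pd.DataFrame, genome_lengths: dict[str, int], rng: np.random.Generator) -> pd.DataFrame:
    """Re-place each locus uniformly at random, preserving its length.

    Chromosome drawn with probability proportional to length; start uniform
    so the locus fits entirely.
    """
    chroms = list(genome_lengths)
    lens = np.array([genome_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    rows = []
    for row in loci.itertuples(index=False):
        length = row.end - row.start
        fits = lens >= length
        if not fits.any():
            raise ValueError(f"locus {row.locus_id} longer than every chromosome")
        p = np.where(fits, probs, 0.0)
        p /= p.sum()
        ci = int(rng.choice(len(chroms), p=p))
        start = int(rng.integers(0, genome_lengths[chroms[ci]] - length + 1))
        rows.append((row.locus_id, chroms[ci], start, start + length))
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])


def shuffle_null_distance(
    loci: pd.DataFrame,
    tes: pd.DataFrame,
    genome_lengths: dict[str, int],
    n_sets: int = 1,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, TestResult]:
    """Observed vs shuffled nearest-TE distances and their Kruskal-Wallis test."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = _nearest_te_distance(loci, tes)
    observed = observed[~np.isnan(observed)]
    shuffled_all = []
    for _ in range(n_sets):
        sh = shuffle_loci(loci, genome_lengths, rng)
        d = _nearest_te_distance(sh, tes)
        shuffled_all.append(d[~np.isnan(d)])
    shuffled = np.concatenate(shuffled_all)
    if observed.size == 0 or shuffled.size == 0:
        raise ValueError("no distances to compare")
    h, p = kruskal_h(observed, shuffled)
    return observed, shuffled, TestResult(
        "observed_vs_shuffled", h, p, n_per_group=(observed.size, shuffled.size)
    )


def te_srna_production(
    loci: pd.DataFrame, tes: pd.DataFrame, kimura_percent: pd.Series | None = None
) -> pd.DataFrame:
    """Per-superfamily sRNA production summary.

    A TE copy produces sRNA when >= 1 retained locus overlaps it. Returns
    (superfamily, n_copies, n_producing, pct_producing, n_srna_loci) and, when
    per-copy Kimura percentages are given, a 'kimura_bins' dict column of
    locus counts per host-copy divergence bin (0-40).
    """
    loci_by_chrom = {c: g for c, g in loci.groupby("chrom")}
    produced = np.zeros(len(tes), dtype=bool)
    n_loci = np.zeros(len(tes), dtype=int)
    for i, row in enumerate(tes.itertuples(index=False)):
        g = loci_by_chrom.get(row.chrom)
        if g is None:
            continue
        ov = (g["start"].to_numpy() < row.end) & (row.start < g["end"].to_numpy())
        produced[i] = bool(ov.any())
        n_loci[i] = int(ov.sum())
    df = tes.assign(_produced=produced, _n_loci=n_loci)
    rows = []
    for sf, grp in df.groupby("superfamily"):
        rec = {
            "superfamily": sf,
            "n_copies": len(grp),
            "n_producing": int(grp["_produced"].sum()),
            "pct_producing": 100.0 * float(grp["_produced"].mean()),
            "n_srna_loci": int(grp["_n_loci"].sum()),
        }
        if kimura_percent is not None:
            bins: dict[int, int] = {}
            for te_id, n in zip(grp["te_id"], grp["_n_loci"]):
                if n == 0 or te_id not in kimura_percent.index:
                    continue
                b = int(min(max(kimura_percent[te_id], 0), 40))
                bins[b] = bins.get(b, 0) + int(n)
            rec["kimura_bins"] = bins
        rows.append(rec)
    return pd.DataFrame(rows)
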