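"""Gene classes for a repeat-rich fungal genome.

Genes carrying transposon-related protein domains are set aside first. The
remainder split into: Class C, the five highly expanded signaling families
(S/T/Y kinase, calmodulin-dependent kinase, BTB/POZ, Sel1-like, Kelch-like);
crinkler-domain candidate effectors; Class B orphans with no known domain,
high copy number (B_HCN) when they overlap a de novo repeat and low copy
number (B_LCN) otherwise; and Class A, the core low-copy domain-bearing
genes. Matching is case-insensitive substring over free-text domain tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Transposon-related domain tokens; any case-insensitive substring hit
#: flags the gene as transposon_related.
TRANSPOSON_BLOCKLIST: tuple[str, ...] = (
    "transposon",
    "zinc_finger_bed_domain",
    "ricesleeper",
    "helicase-primase",
    "helicase/primase",
    "gag-pol",
    "far1-related",
    "ribonuclease_hi",
    "ribonuclease_h",
    "jockey",
    "rve_super_family_integrase",
    "transposase",
    "transposable",
    "helitron",
    "pif1",
    "zinc_finger_mym-type_protein_2",
    "reverse_transcriptase",
)

#: The five expanded Class C families: class label -> matching tokens.
CLASS_C_TOKENS: dict[str, tuple[str, ...]] = {
    "C_STY_kinase": ("sty_kinase", "s/t/y_kinase", "tyrosine_kinase", "pkinase_tyr", "protein_kinase"),
    "C_CaM_kinase": ("calmodulin", "cam_kinase", "camk"),
    "C_BTB_POZ": ("btb", "poz"),
    "C_Sel1": ("sel1",),
    "C_Kelch": ("kelch",),
}

CRINKLER_TOKENS: tuple[str, ...] = ("crinkler", "pf20147")

GENE_CLASSES: tuple[str, ...] = (
    "A",
    "B_LCN",
    "B_HCN",
    *CLASS_C_TOKENS.keys(),
    "crinkler",
    "transposon_related",
)


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    domains: tuple[str, ...] = field(default_factory=tuple)
    repeat_overlap: bool = False
    gene_class: str | None = None


def _matches(domains: tuple[str, ...], tokens: tuple[str, ...]) -> bool:
    low = [d.lower() for d in domains]
    return any(tok in d for d in low for tok in tokens)


def remove_transposon_genes(
    genes: list[GeneRecord], blocklist: tuple[str, ...] = TRANSPOSON_BLOCKLIST
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split genes into (kept, removed) on the transposon-domain blocklist."""
    tokens = tuple(t.lower() for t in blocklist)
    kept, removed = [], []
    for g in genes:
        if _matches(g.domains, tokens):
            g.gene_class = "transposon_related"
            removed.append(g)
        else:
            kept.append(g)
    return kept, removed


def classify_genes(
    genes: list[GeneRecord],
    blocklist: tuple[str, ...] = TRANSPOSON_BLOCKLIST,
    crinkler_precedence: bool = True,
) -> pd.DataFrame:
    """Assign exactly one class per gene; returns (gene_id, gene_class).

    Precedence: transposon blocklist, then crinkler (on a crinkler/Class-C
    conflict, crinkler wins unless ``crinkler_precedence`` is False, in which
    case the conflict raises), then Class C families in fixed order, then
    Class B (no domain; HCN iff repeat overlap), remainder Class A.
    """
    kept, removed = remove_transposon_genes(genes, blocklist)
    conflicts = 0
    for g in kept:
        is_crinkler = _matches(g.domains, CRINKLER_TOKENS)
        c_hit = next(
            (label for label, toks in CLASS_C_TOKENS.items() if _matches(g.domains, toks)),
            None,
        )
        if is_crinkler and c_hit is not None:
            if not crinkler_precedence:
                raise ValueError(
                    f"{g.gene_id}: both crinkler and {c_hit} tokens; set a precedence"
                )
            conflicts += 1
        if is_crinkler:
            g.gene_class = "crinkler"
        elif c_hit is not None:
            g.gene_class = c_hit
        elif not g.domains:
            g.gene_class = "B_HCN" if g.repeat_overlap else "B_LCN"
        else:
            g.gene_class = "A"
    df = pd.DataFrame(
        [(g.gene_id, g.gene_class) for g in kept + removed],
        columns=["gene_id", "gene_class"],
    )
    df.attrs["crinkler_conflicts"] = conflicts
    return df


def intergenic_distances(genes: list[GeneRecord]) -> pd.DataFrame:
    """Per-gene gap to the 5' and 3' neighbor on the same chromosome.

    Gaps between adjacent gene bounds, 0 when intervals overlap; NaN at
    chromosome ends. Input is sorted internally; duplicate gene ids raise.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated gene ids")
    rows = []
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    for _, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n = len(grp)
        left = np.full(n, np.nan)
        right = np.full(n, np.nan)
        if n > 1:
            # gap to previous neighbor: start_i - max(end of all previous)
            prev_max_end = np.maximum.accumulate(ends)[:-1]
            left[1:] = np.maximum(starts[1:] - prev_max_end, 0)
            right[:-1] = np.maximum(starts[1:] - ends[:-1], 0)
        for i in range(n):
            strand = grp.at[i, "strand"]
            five, three = (left[i], right[i]) if strand != "-" else (right[i], left[i])
            rows.append((grp.at[i, "gene_id"], five, three))
    return pd.DataFrame(rows, columns=["gene_id", "dist_5p", "dist_3p"])


def gene_density(genes: list[GeneRecord], chrom_lengths: dict[str, int], window: int) -> pd.DataFrame:
    """Gene counts per fixed tiling window (a gene counts in the window of its start)."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    starts_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        starts_by_chrom.setdefault(g.chrom, []).append(g.start)
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window))
        counts = np.zeros(n_win, dtype=int)
        for s in starts_by_chrom.get(chrom, []):
            counts[min(s // window, n_win - 1)] += 1
        for i, c in enumerate(counts):
            rows.append((chrom, i * window, min((i + 1) * window, length), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_genes"])
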