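"""Readers and writers for the pipeline's on-disk formats.

All coordinates are 0-based half-open inside the package; conversion to the
1-based inclusive GFF3 convention happens only here. FASTA goes through
Biopython. The RepeatMasker ``.out`` table (whitespace-delimited, three
header lines) and the narrow GFF3/BED6 dialects used by the pipeline are
parsed directly.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .divergence import PairwiseAlignment
from .genes import GeneRecord


class ParseError(ValueError):
    pass


# --- FASTA -----------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- pairwise alignment archive -------------------------------------------
# One aligned-FASTA pair per copy: >id|consensus|family|superfamily|chrom|start|end
# followed by >id|copy.

def write_alignments(alignments: list[PairwiseAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f">{a.copy_id}|consensus|{a.family}|{a.superfamily}|{a.chrom}|{a.start}|{a.end}\n"
                f"{a.consensus}\n>{a.copy_id}|copy\n{a.copy}\n"
            )


def read_alignments(path: str | os.PathLike) -> list[PairwiseAlignment]:
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 4:
        raise ParseError(f"{path}: expected blocks of 4 lines per copy")
    for i in range(0, len(lines), 4):
        header = lines[i][1:].split("|")
        if len(header) != 7 or lines[i + 2][1:].split("|")[0] != header[0]:
            raise ParseError(f"{path}: malformed alignment block near line {2 * i + 1}")
        copy_id, _, family, superfamily, chrom, start, end = header
        out.append(
            PairwiseAlignment(
                copy_id=copy_id, family=family, superfamily=superfamily,
                consensus=lines[i + 1], copy=lines[i + 3],
                chrom=chrom, start=int(start), end=int(end),
            )
        )
    return out


# --- RepeatMasker .out -----------------------------------------------------

_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeatmasker_out(tes: pd.DataFrame, path: str | os.PathLike) -> None:
    """TE table -> RepeatMasker-style .out (1-based inclusive query coords)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, row in enumerate(tes.itertuples(index=False), start=1):
            div = getattr(row, "divergence_pct", 0.0)
            fh.write(
                f"{1000:>5} {div:5.1f}  0.0  0.0  {row.chrom:<10} "
                f"{row.start + 1:>8} {row.end:>8} (0) + "
                f"{row.family:<18} {row.superfamily:<20} 1 {row.end - row.start} (0) "
                f"{row.te_id}\n"
            )


def read_repeatmasker_out(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a .out table to (te_id, family, superfamily, chrom, start, end).

    Header lines are tolerated and skipped; coordinates convert to 0-based
    half-open. The trailing ID field is used as te_id when present, else a
    running index.
    """
    rows = []
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header / blank
            try:
                chrom = parts[4]
                start = int(parts[5]) - 1
                end = int(parts[6])
                family = parts[9]
                superfamily = parts[10]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{ln_no}: malformed .out record") from exc
            if end < start:
                raise ParseError(f"{path}:{ln_no}: end < start after conversion")
            te_id = parts[14] if len(parts) > 14 else f"te_{len(rows):05d}"
            rows.append((te_id, family, superfamily, chrom, start, end))
    return pd.DataFrame(rows, columns=["te_id", "family", "superfamily", "chrom", "start", "end"])


# --- BED6 ------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path: str | os.PathLike, name_col: str = "te_id") -> None:
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = df[name_col]
    out["score"] = 0
    out["strand"] = df["strand"] if "strand" in df else "+"
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["end"] < df["start"]).any():
        raise ParseError(f"{path}: BED record with end < start")
    return df


# --- GFF3 genes ------------------------------------------------------------

def write_genes_gff3(genes: list[GeneRecord], path: str | os.PathLike) -> None:
    """Genes to GFF3 (1-based inclusive) with domains= and repeat_overlap= attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.domains:
                attrs += ";domains=" + ",".join(g.domains)
            attrs += f";repeat_overlap={'1' if g.repeat_overlap else '0'}"
            fh.write(
                f"{g.chrom}\trhizoepi\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_genes_gff3(path: str | os.PathLike) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln_no}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            start0, end0 = int(start) - 1, int(end)
            if end0 <= start0:
                raise ParseError(f"{path}:{ln_no}: end <= start after conversion")
            fields = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if "ID" not in fields:
                raise ParseError(f"{path}:{ln_no}: gene without ID attribute")
            domains = tuple(d for d in fields.get("domains", "").split(",") if d)
            genes.append(
                GeneRecord(
                    gene_id=fields["ID"], chrom=chrom, start=start0, end=end0,
                    strand=strand, domains=domains,
                    repeat_overlap=fields.get("repeat_overlap", "0") == "1",
                )
            )
    return genes


# --- simple TSV helpers ----------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_methylation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "pos", "strand", "meth_freq", "coverage"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(expected - set(df.columns))}")
    return df
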