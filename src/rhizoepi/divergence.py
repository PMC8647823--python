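"""CpG-adjusted Kimura 2-parameter divergence of TE copies and repeat landscapes.

Each TE copy is aligned against its family consensus. Transition (P) and
transversion (Q) proportions over aligned, unambiguous columns give the
Kimura 2-parameter distance

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

a standard proxy for copy age. Because methylated CpG sites deaminate at
roughly an order of magnitude above the background transition rate, a
transition at a column whose consensus base sits in a CpG dinucleotide is
down-weighted to 1/10 (the RepeatMasker convention), so recent hypermutation
at CpG sites does not inflate apparent age.

The repeat landscape bins copies by K (percent, 1-point bins from 0 to 50)
and accumulates genome coverage per TE superfamily per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID = frozenset("ACGT")

#: K values above this (in percent) are clamped into the last landscape bin.
MAX_BIN = 50


class SaturationError(ValueError):
    """Raised when observed P, Q put the K2P log argument at or below zero."""


class EmptyAlignmentError(ValueError):
    """Raised when no aligned column has unambiguous bases on both rows."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """A TE copy aligned to its family consensus (gapped, equal-length rows)."""

    copy_id: str
    family: str
    superfamily: str
    consensus: str
    copy: str
    chrom: str = ""
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.copy):
            raise ValueError(
                f"{self.copy_id}: aligned rows differ in length "
                f"({len(self.consensus)} vs {len(self.copy)})"
            )


@dataclass(frozen=True)
class KimuraEstimate:
    """Transition/transversion proportions and the resulting K2P distance."""

    P: float
    Q: float
    K: float
    n_sites: int
    cpg_adjusted: bool

    @property
    def percent(self) -> float:
        return 100.0 * self.K


def kimura_k(P: float, Q: float) -> float:
    """Closed-form K2P distance; raises SaturationError when undefined."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(f"saturated alignment: P={P:.4f}, Q={Q:.4f}")
    return -0.5 * float(np.log(a * np.sqrt(b)))


def consensus_cpg_columns(consensus: str) -> np.ndarray:
    """Boolean mask of alignment columns in consensus CpG context.

    Context is read on the consensus with gaps removed: a column belongs to a
    CpG if its consensus base is the C of a CG (next consensus base G) or the
    G of a CG (previous consensus base C).
    """
    cols = np.frombuffer(consensus.upper().encode(), dtype="S1")
    keep = cols != b"-"
    bases = cols[keep]
    cpg = np.zeros(bases.size, dtype=bool)
    if bases.size >= 2:
        is_cg = (bases[:-1] == b"C") & (bases[1:] == b"G")
        cpg[:-1] |= is_cg
        cpg[1:] |= is_cg
    mask = np.zeros(cols.size, dtype=bool)
    mask[keep] = cpg
    return mask


def kimura_distance(aln: PairwiseAlignment, cpg_adjust: bool = True) -> KimuraEstimate:
    """Estimate the (optionally CpG-adjusted) K2P distance of one alignment.

    Only columns where both rows carry an unambiguous A/C/G/T are counted;
    gaps and ambiguity codes are skipped. With ``cpg_adjust``, transitions at
    consensus-CpG columns contribute weight 1/10 to the transition count.
    """
    cons = np.frombuffer(aln.consensus.upper().encode(), dtype="S1")
    copy = np.frombuffer(aln.copy.upper().encode(), dtype="S1")
    valid_set = np.frombuffer(b"ACGT", dtype="S1")
    ok = np.isin(cons, valid_set) & np.isin(copy, valid_set)
    n_sites = int(np.count_nonzero(ok))
    if n_sites == 0:
        raise EmptyAlignmentError(f"{aln.copy_id}: no comparable aligned columns")
    diff = ok & (cons != copy)
    purine = np.isin(cons, np.frombuffer(b"AG", dtype="S1"))
    copy_purine = np.isin(copy, np.frombuffer(b"AG", dtype="S1"))
    transition = diff & (purine == copy_purine)
    transversion = diff & (purine != copy_purine)
    if cpg_adjust:
        cpg = consensus_cpg_columns(aln.consensus)
        weights = np.where(cpg, 0.1, 1.0)
        p_count = float(np.sum(weights[transition]))
    else:
        p_count = float(np.count_nonzero(transition))
    q_count = float(np.count_nonzero(transversion))
    P = p_count / n_sites
    Q = q_count / n_sites
    return KimuraEstimate(P=P, Q=Q, K=kimura_k(P, Q), n_sites=n_sites, cpg_adjusted=cpg_adjust)


def build_landscape(
    estimates: list[tuple[KimuraEstimate, int, str]], genome_length: int
) -> pd.DataFrame:
    """Genome coverage (%) per (superfamily, Kimura-percent bin).

    Copies land in bin floor(100*K), clamped to [0, 50]. Returns a long-format
    frame with columns superfamily, bin, coverage_pct, n_copies and an
    ``attrs['clamped']`` counter of copies whose K exceeded the last bin.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rows: dict[tuple[str, int], list[float]] = {}
    clamped = 0
    for est, length, superfamily in estimates:
        if length <= 0:
            raise ValueError("copy length must be positive")
        b = int(np.floor(100.0 * est.K))
        if b > MAX_BIN:
            b = MAX_BIN
            clamped += 1
        b = max(b, 0)
        rows.setdefault((superfamily, b), []).append(float(length))
    records = [
        {
            "superfamily": sf,
            "bin": b,
            "coverage_pct": 100.0 * sum(lengths) / genome_length,
            "n_copies": len(lengths),
        }
        for (sf, b), lengths in sorted(rows.items())
    ]
    df = pd.DataFrame(records, columns=["superfamily", "bin", "coverage_pct", "n_copies"])
    df.attrs["genome_length"] = genome_length
    df.attrs["clamped"] = clamped
    return df
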