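"""Synthetic genome, methylome, small-RNA and count-matrix generator.

Plants known truth so every downstream estimator can be tested for parameter
recovery: per-copy Kimura divergences realized as transition/transversion
substitutions whose expected proportions solve the K2P formula for the
target K; genes laid out per class with a fraction of expanded-family (Class
C) genes placed within a fixed distance of MULE copies; bimodal per-site CpG
methylation conditioned on feature class; 24-nt 5'U/A-biased small RNAs from
young TE copies with treatment enrichment and mitochondrial depletion; and
negative-binomial count matrices over the 5-condition x 4-replicate design
with planted subfamily fold changes.

All randomness flows through one explicit numpy Generator; identical
configs and seeds reproduce identical output bytes. Stage generators derive
their default Generator from ``config.seed`` plus a fixed stage offset so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import ConfigurationError, SimulationConfig
from .divergence import PairwiseAlignment, SaturationError, kimura_k
from .genes import GeneRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_STAGE_OFFSET = {"genome": 0, "methylome": 1, "srna": 2, "expression": 3}

#: domain-token pools per gene class used when emitting annotations
CLASS_DOMAINS: dict[str, tuple[str, ...]] = {
    "A": (
        "ABC_transporter", "Cytochrome_P450", "MFS_transporter",
        "Ribosomal_L4", "GTPase_Ras", "WD40_repeat", "Zinc_knuckle",
    ),
    "B_LCN": (),
    "B_HCN": (),
    "C_STY_kinase": ("STY_kinase",),
    "C_CaM_kinase": ("Calmodulin_kinase_II",),
    "C_BTB_POZ": ("BTB_POZ",),
    "C_Sel1": ("Sel1_repeat",),
    "C_Kelch": ("Kelch_motif",),
    "crinkler": ("Crinkler_PF20147",),
    "transposon_related": (
        "Transposase_mutator", "Reverse_transcriptase_1",
        "gag-pol_polyprotein", "Helitron_helicase_like",
    ),
}


@dataclass
class SyntheticTruth:
    """Planted parameters keyed by the ids of the emitted annotations."""

    te: pd.DataFrame = field(default_factory=pd.DataFrame)  # te_id, family, superfamily, planted_k, expressed, ...
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)  # gene_id, gene_class, near_mule, expressed
    methylation: pd.DataFrame = field(default_factory=pd.DataFrame)  # locus_id, feature_class, component
    srna: pd.DataFrame = field(default_factory=pd.DataFrame)  # locus_id, origin, enrichment flags
    subfamilies: pd.DataFrame = field(default_factory=pd.DataFrame)  # subfamily, planted_log2fc


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    mito_chrom: str
    te_table: pd.DataFrame
    alignments: list[PairwiseAlignment]
    gene_records: list[GeneRecord]
    truth: SyntheticTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def nuclear_lengths(self) -> dict[str, int]:
        return {n: l for n, l in self.chrom_lengths.items() if n != self.mito_chrom}


def stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(config.seed * 8 + _STAGE_OFFSET[stage])


def solve_pq(k: float, ratio: float) -> tuple[float, float]:
    """Transition/transversion proportions (P, Q) with Q = ratio * P whose
    K2P distance equals ``k``; raises SaturationError when none exists."""
    if k < 0:
        raise ValueError("planted K must be >= 0")
    if k == 0:
        return 0.0, 0.0

    def f(p: float) -> float:
        return kimura_k(p, ratio * p) - k

    # largest admissible P before either log argument saturates
    p_max = 1.0 / (2.0 + ratio)
    if ratio > 0:
        p_max = min(p_max, 1.0 / (2.0 * ratio))
    lo, hi = 1e-12, p_max * (1 - 1e-9)
    try:
        if f(hi) < 0:
            raise SaturationError(
                f"planted K={k} not attainable with transversion:transition ratio {ratio}"
            )
        p = brentq(f, lo, hi, xtol=1e-14)
    except SaturationError:
        raise
    return float(p), float(ratio * p)


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=probs)


def mutate_copy(
    consensus: np.ndarray, k: float, ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply i.i.d. per-site substitutions with expected proportions (P, Q).

    Transitions occur with probability P and transversions with probability Q
    (uniform over the two transversion partners); no back-mutation
    bookkeeping, so the planted K is the target of the expected proportions.
    """
    p, q = solve_pq(k, ratio)
    n = consensus.size
    u = rng.random(n)
    copy = consensus.copy()
    ts = u < p
    tv = (u >= p) & (u < p + q)
    if ts.any():
        src = consensus[ts].astype("U1")
        copy[ts] = np.array([TRANSITION[b] for b in src], dtype="S1")
    if tv.any():
        src = consensus[tv].astype("U1")
        pick = rng.integers(0, 2, size=int(tv.sum()))
        copy[tv] = np.array(
            [TRANSVERSIONS[b][i] for b, i in zip(src, pick)], dtype="S1"
        )
    return copy


def _draw_k(plan, idx: int, rng: np.random.Generator) -> float:
    if plan.k_values is not None:
        return float(plan.k_values[idx % len(plan.k_values)])
    if rng.random() < plan.young_fraction:
        return float(rng.uniform(*plan.k_young))
    return float(rng.uniform(*plan.k_old))


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build chromosomes with planted TE copies and gene annotations.

    TE copies and genes are laid out left to right per chromosome as
    non-overlapping blocks separated by random gaps; a planted fraction of
    Class C genes is emitted as a (MULE copy, short gap, gene) block so the
    copy is guaranteed within the configured distance. Gaps flanking Class A
    genes are shrunk by the configured weight, planting the shorter
    intergenic distances of the core compartment.
    """
    config.validate()
    rng = stage_rng(config, "genome")
    ratio = config.transversion_transition_ratio
    fam_by_name = {f.name: f for f in config.te_library}

    consensi = {
        f.name: random_sequence(rng, f.consensus_length, config.gc_content)
        for f in config.te_library
    }

    # --- TE copy specs -----------------------------------------------------
    te_specs = []  # (te_id, family, superfamily, planted_k, copy array)
    for name, plan in config.copy_plan.items():
        fam = fam_by_name[name]
        for i in range(plan.n_copies):
            k = _draw_k(plan, i, rng)
            frac = rng.uniform(*plan.length_fraction)
            length = max(int(round(frac * fam.consensus_length)), 50)
            cons_piece = consensi[name][:length]
            copy = mutate_copy(cons_piece, k, ratio, rng)
            te_id = f"{name}_copy{i:04d}"
            te_specs.append((te_id, name, fam.superfamily, k, cons_piece, copy))

    # --- gene specs --------------------------------------------------------
    gp = config.gene_plan
    gene_specs = []  # (gene_id, class, length, domains, repeat_overlap)
    gid = 0
    for cls, n in gp.class_counts.items():
        pool = CLASS_DOMAINS[cls]
        for _ in range(n):
            length = int(rng.integers(gp.length_range[0], gp.length_range[1] + 1))
            domains = (str(rng.choice(pool)),) if pool else ()
            gene_specs.append((f"gene_{gid:05d}", cls, length, domains, cls == "B_HCN"))
            gid += 1

    # --- pair Class C genes with MULE copies -------------------------------
    mule_ids = [s[0] for s in te_specs if fam_by_name[s[1]].superfamily.startswith("DNA/MULE")]
    c_genes = [g for g in gene_specs if g[1].startswith("C_")]
    n_paired = int(round(gp.near_mule_fraction * len(c_genes)))
    if n_paired > len(mule_ids):
        raise ConfigurationError(
            f"{n_paired} near-MULE genes requested but only {len(mule_ids)} MULE copies planted"
        )
    paired_gene_ids = {g[0] for g in c_genes[:n_paired]}
    paired_mules = dict(zip(sorted(paired_gene_ids), rng.permutation(mule_ids)[:n_paired]))

    # --- assemble blocks ---------------------------------------------------
    te_by_id = {s[0]: s for s in te_specs}
    blocks = []  # list of ("pair"|"te"|"gene", payload)
    used_tes = set(paired_mules.values())
    for gene in gene_specs:
        if gene[0] in paired_gene_ids:
            gap = int(rng.integers(1, gp.mule_distance + 1))
            blocks.append(("pair", (te_by_id[paired_mules[gene[0]]], gap, gene)))
        else:
            blocks.append(("gene", gene))
    for spec in te_specs:
        if spec[0] not in used_tes:
            blocks.append(("te", spec))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    def block_len(b) -> int:
        kind, payload = b
        if kind == "te":
            return payload[5].size
        if kind == "gene":
            return payload[2]
        te, gap, gene = payload
        return te[5].size + gap + gene[2]

    # round-robin chromosomes, bailing out if a chromosome overflows
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom: dict[str, list] = {c: [] for c in chrom_names}
    fill = dict.fromkeys(chrom_names, 0)
    for b in blocks:
        target = min(chrom_names, key=lambda c: fill[c])
        fill[target] += block_len(b)
        per_chrom[target].append(b)
    for c, used in fill.items():
        if used >= config.chrom_length:
            raise ConfigurationError(
                f"{c}: planted features ({used} bp) exceed chromosome length "
                f"({config.chrom_length} bp)"
            )

    # --- realize coordinates and sequences ---------------------------------
    sequences: dict[str, str] = {}
    te_rows, gene_records, aln = [], [], []
    gene_class_of = {}
    for chrom in chrom_names:
        seq = random_sequence(rng, config.chrom_length, config.gc_content)
        chosen = per_chrom[chrom]
        free = config.chrom_length - sum(block_len(b) for b in chosen)
        # gap weights: exponential, shrunk next to Class A genes
        weights = rng.exponential(1.0, size=len(chosen) + 1)
        for i, b in enumerate(chosen):
            if b[0] == "gene" and b[1][1] == "A":
                weights[i] *= gp.class_a_gap_weight
                weights[i + 1] *= gp.class_a_gap_weight
        gaps = np.floor(free * weights / weights.sum()).astype(int)
        cursor = 0
        strands = rng.choice(np.array(["+", "-"]), size=len(chosen))

        def place_te(spec, start):
            te_id, famname, superfam, k, cons_piece, copy = spec
            end = start + copy.size
            seq[start:end] = copy
            te_rows.append((te_id, famname, superfam, chrom, start, end, k))
            aln.append(
                PairwiseAlignment(
                    copy_id=te_id, family=famname, superfamily=superfam,
                    consensus=cons_piece.tobytes().decode(),
                    copy=copy.tobytes().decode(),
                    chrom=chrom, start=start, end=end,
                )
            )
            return end

        for i, b in enumerate(chosen):
            cursor += int(gaps[i])
            kind, payload = b
            if kind == "te":
                cursor = place_te(payload, cursor)
            elif kind == "gene":
                gene_id, cls, length, domains, rep_ov = payload
                gene_records.append(
                    GeneRecord(gene_id, chrom, cursor, cursor + length,
                               strand=str(strands[i]), domains=domains,
                               repeat_overlap=rep_ov)
                )
                gene_class_of[gene_id] = cls
                cursor += length
            else:
                te_spec, gap, gene = payload
                cursor = place_te(te_spec, cursor)
                cursor += gap
                gene_id, cls, length, domains, rep_ov = gene
                gene_records.append(
                    GeneRecord(gene_id, chrom, cursor, cursor + length,
                               strand=str(strands[i]), domains=domains,
                               repeat_overlap=rep_ov)
                )
                gene_class_of[gene_id] = cls
                cursor += length
        sequences[chrom] = seq.tobytes().decode()

    mito = random_sequence(rng, config.mito_length, config.gc_content)
    sequences["mito"] = mito.tobytes().decode()

    te_table = pd.DataFrame(
        te_rows, columns=["te_id", "family", "superfamily", "chrom", "start", "end", "planted_k"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # planted expression flags: young copies transcribe more often
    young = te_table["planted_k"] < config.srna_model.young_k_cutoff
    p_expr = np.where(young, config.p_expressed_young_te, config.p_expressed_old_te)
    te_table["expressed"] = rng.random(len(te_table)) < p_expr

    gene_truth_rows = []
    for g in gene_records:
        cls = gene_class_of[g.gene_id]
        key = "C" if cls.startswith("C_") else cls
        expressed = bool(rng.random() < gp.p_expressed[key])
        gene_truth_rows.append(
            (g.gene_id, cls, g.gene_id in paired_gene_ids,
             paired_mules.get(g.gene_id), expressed)
        )
    gene_truth = pd.DataFrame(
        gene_truth_rows,
        columns=["gene_id", "gene_class", "near_mule", "paired_mule", "expressed"],
    )

    truth = SyntheticTruth(
        te=te_table.copy(),
        genes=gene_truth,
        subfamilies=pd.DataFrame(
            [(f.name, config.expression_design.planted_log2fc.get(f.name, 0.0))
             for f in config.te_library],
            columns=["subfamily", "planted_log2fc"],
        ),
    )
    return SyntheticGenome(
        sequences=sequences, mito_chrom="mito",
        te_table=te_table.drop(columns=["planted_k", "expressed"]),
        alignments=aln, gene_records=gene_records, truth=truth,
    )


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def generate_methylome(genome: SyntheticGenome, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cytosine methylation records with planted bimodal structure.

    Every CpG yields a plus- and a minus-strand record. Each annotated locus
    (TE copy or gene) is assigned a high or low beta component with the
    configured per-class probability; its sites draw a latent frequency from
    that component, and each strand reports a binomial realization at its own
    coverage. Background CpGs mix per site. The component assignment per
    locus is recorded in ``genome.truth.methylation``.
    """
    mm = config.methylation_model
    if rng is None:
        rng = stage_rng(config, "methylome")
    te_truth = genome.truth.te.set_index("te_id")
    gene_cls = genome.truth.genes.set_index("gene_id")["gene_class"]

    features = []  # (chrom, start, end, locus_id, feature_class)
    for row in genome.te_table.itertuples(index=False):
        cls = "TE_expressed" if te_truth.at[row.te_id, "expressed"] else "TE_nonexpressed"
        features.append((row.chrom, row.start, row.end, row.te_id, cls))
    for g in genome.gene_records:
        cls = gene_cls[g.gene_id]
        key = "C" if cls.startswith("C_") else cls
        features.append((g.chrom, g.start, g.end, g.gene_id, key))
    for _, _, _, _, cls in features:
        if cls not in mm.p_high:
            raise ConfigurationError(f"feature class {cls!r} missing from methylation mixing table")
    if "background" not in mm.p_high:
        raise ConfigurationError("methylation mixing table needs a 'background' entry")

    feat_by_chrom: dict[str, list] = {}
    for f in features:
        feat_by_chrom.setdefault(f[0], []).append(f)

    chroms, poss, strands, freqs, covs = [], [], [], [], []
    comp_rows = []

    def emit(chrom: str, sites: np.ndarray, p_latent: np.ndarray) -> None:
        for offset, strand in ((0, "+"), (1, "-")):
            cov = rng.poisson(mm.coverage_mean, size=sites.size) + 1
            meth = rng.binomial(cov, p_latent)
            chroms.append(np.repeat(chrom, sites.size))
            poss.append(sites + offset)
            strands.append(np.repeat(strand, sites.size))
            freqs.append(meth / cov)
            covs.append(cov)

    for chrom, seq in genome.sequences.items():
        cpg = _cpg_positions(seq)
        if cpg.size == 0:
            continue
        owner = np.full(cpg.size, -1)
        feats = sorted(feat_by_chrom.get(chrom, []), key=lambda f: f[1])
        starts = np.array([f[1] for f in feats], dtype=int)
        ends = np.array([f[2] for f in feats], dtype=int)
        if feats:
            idx = np.searchsorted(starts, cpg, side="right") - 1
            ok = (idx >= 0) & (cpg < ends[np.clip(idx, 0, None)])
            owner[ok] = idx[ok]
        for fi, f in enumerate(feats):
            sites = cpg[owner == fi]
            if sites.size == 0:
                comp_rows.append((f[3], f[4], "none", 0))
                continue
            high = rng.random() < mm.p_high[f[4]]
            a, b = mm.high if high else mm.low
            p_latent = rng.beta(a, b, size=sites.size)
            comp_rows.append((f[3], f[4], "high" if high else "low", int(sites.size)))
            emit(chrom, sites, p_latent)
        bg = cpg[owner == -1]
        if bg.size:
            high = rng.random(bg.size) < mm.p_high["background"]
            a_hi, b_hi = mm.high
            a_lo, b_lo = mm.low
            p_latent = np.where(high, rng.beta(a_hi, b_hi, bg.size), rng.beta(a_lo, b_lo, bg.size))
            emit(chrom, bg, p_latent)

    records = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(poss).astype(int),
            "strand": np.concatenate(strands),
            "meth_freq": np.concatenate(freqs),
            "coverage": np.concatenate(covs).astype(int),
        }
    ).sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    genome.truth.methylation = pd.DataFrame(
        comp_rows, columns=["locus_id", "feature_class", "component", "n_cpg"]
    )
    return records


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def generate_srna_reads(
    genome: SyntheticGenome, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthesize sRNA reads for the untreated/oxidized/TraPR libraries.

    Returns (reads, counts, sample_sheet): a collapsed read table pooled per
    library, a planted-locus x (library x replicate) count matrix for
    enrichment testing, and its sample sheet. Planted truth (origin labels,
    enrichment flags, mito flags) lands in ``genome.truth.srna``.
    """
    sm = config.srna_model
    if rng is None:
        rng = stage_rng(config, "srna")
    te = genome.truth.te
    if te.empty:
        raise ConfigurationError("sRNA model requires a TE annotation with planted divergences")

    loci = []  # (locus_id, chrom, start, end, origin, is_mito, host_id)
    young = te[te["planted_k"] < sm.young_k_cutoff]
    li = 0
    for row in young.itertuples(index=False):
        if rng.random() >= sm.p_locus_per_young_te:
            continue
        span = row.end - row.start
        length = int(rng.integers(*sm.locus_length))
        length = min(length, span)
        start = int(row.start + rng.integers(0, span - length + 1))
        origin = "TE_expressed" if row.expressed else "TE_nonexpressed"
        loci.append((f"srna_{li:04d}", row.chrom, start, start + length, origin, False, row.te_id))
        li += 1

    expressed_genes = genome.truth.genes[genome.truth.genes["expressed"]]
    gene_pos = {g.gene_id: (g.chrom, g.start, g.end) for g in genome.gene_records}
    pick = rng.permutation(expressed_genes["gene_id"].to_numpy())[: sm.n_genic_loci]
    for gene_id in pick:
        chrom, gstart, gend = gene_pos[gene_id]
        span = gend - gstart
        length = min(int(rng.integers(*sm.locus_length)), span)
        start = int(gstart + rng.integers(0, span - length + 1))
        loci.append((f"srna_{li:04d}", chrom, start, start + length, "genic", False, gene_id))
        li += 1

    # unannotated loci: rejection-sample free windows on nuclear chromosomes
    occupied: dict[str, list[tuple[int, int]]] = {}
    for row in genome.te_table.itertuples(index=False):
        occupied.setdefault(row.chrom, []).append((row.start, row.end))
    for g in genome.gene_records:
        occupied.setdefault(g.chrom, []).append((g.start, g.end))
    nuclear = list(genome.nuclear_lengths.items())
    nuclear_len = dict(nuclear)
    te_nuclear = genome.te_table[genome.te_table["chrom"].isin(nuclear_len)]
    n_near = int(round(sm.unannotated_near_te_fraction * sm.n_unannotated_loci))

    def free(chrom: str, start: int, end: int) -> bool:
        return not any(s < end and start < e for s, e in occupied.get(chrom, []))

    # TE-adjacent unannotated loci: a short gap off a random copy's edge
    placed = 0
    attempts = 0
    while placed < n_near and attempts < 20000:
        attempts += 1
        row = te_nuclear.iloc[int(rng.integers(0, len(te_nuclear)))]
        length = int(rng.integers(*sm.locus_length))
        gap = int(rng.integers(1, sm.near_te_distance + 1))
        if rng.random() < 0.5:
            start = row["end"] + gap
        else:
            start = row["start"] - gap - length
        end = start + length
        if start < 0 or end > nuclear_len[row["chrom"]] or not free(row["chrom"], start, end):
            continue
        loci.append((f"srna_{li:04d}", row["chrom"], start, end, "unannotated", False, None))
        occupied.setdefault(row["chrom"], []).append((start, end))
        li += 1
        placed += 1

    # remaining unannotated loci: uniform over free nuclear space
    attempts = 0
    while placed < sm.n_unannotated_loci and attempts < 10000:
        attempts += 1
        chrom, clen = nuclear[int(rng.integers(0, len(nuclear)))]
        length = int(rng.integers(*sm.locus_length))
        start = int(rng.integers(0, clen - length))
        end = start + length
        if not free(chrom, start, end):
            continue
        loci.append((f"srna_{li:04d}", chrom, start, end, "unannotated", False, None))
        occupied.setdefault(chrom, []).append((start, end))
        li += 1
        placed += 1

    mlen = genome.chrom_lengths[genome.mito_chrom]
    for _ in range(sm.n_mito_loci):
        length = int(rng.integers(*sm.locus_length))
        start = int(rng.integers(0, mlen - length))
        loci.append((f"srna_{li:04d}", genome.mito_chrom, start, start + length,
                     "unannotated", True, None))
        li += 1

    locus_df = pd.DataFrame(
        loci, columns=["locus_id", "chrom", "start", "end", "origin", "is_mito", "host_id"]
    )

    # enrichment / depletion flags (mito loci handled by depletion instead)
    n = len(locus_df)
    u = rng.random(n)
    enriched = (u < sm.enriched_fraction) & ~locus_df["is_mito"].to_numpy()
    depleted = (u >= sm.enriched_fraction) & (u < sm.enriched_fraction + sm.depleted_fraction)
    depleted &= ~locus_df["is_mito"].to_numpy()
    which = rng.random(n)
    ox_enr = enriched & (which < 0.6)          # 0.6 overlap -> some dual
    tr_enr = enriched & (which >= 0.4)
    base = rng.lognormal(np.log(sm.reads_per_locus_mean), sm.reads_per_locus_sigma, size=n)
    base = np.where(locus_df["is_mito"], base * sm.mito_read_multiplier, base)

    factor = {
        "untreated": np.ones(n),
        "oxidized": np.where(ox_enr, sm.enrich_factor, np.where(depleted, 1 / sm.enrich_factor, 1.0)),
        "trapr": np.where(tr_enr, sm.enrich_factor, np.where(depleted, 1 / sm.enrich_factor, 1.0)),
    }
    for lib in ("oxidized", "trapr"):
        factor[lib] = np.where(locus_df["is_mito"], sm.mito_depletion, factor[lib])

    lengths = np.array(list(sm.length_probs.keys()))
    length_p = np.array(list(sm.length_probs.values()))
    nts = np.array(list(sm.first_nt_probs.keys()))
    nt_p = np.array(list(sm.first_nt_probs.values()))

    read_rows = []
    count_cols: dict[str, np.ndarray] = {}
    for lib in ("untreated", "oxidized", "trapr"):
        lam = base * factor[lib]
        totals = rng.poisson(lam)
        for r in range(sm.n_replicates):
            count_cols[f"{lib}_rep{r + 1}"] = rng.poisson(lam)
        for i, row in enumerate(locus_df.itertuples(index=False)):
            n_reads = int(totals[i])
            if n_reads == 0:
                continue
            n_forms = min(n_reads, 12)
            form_counts = rng.multinomial(n_reads, np.ones(n_forms) / n_forms)
            strand_major = "+" if rng.random() < 0.5 else "-"
            for c in form_counts[form_counts > 0]:
                L = int(rng.choice(lengths, p=length_p))
                span = row.end - row.start
                L = min(L, span)
                start = int(row.start + rng.integers(0, span - L + 1))
                strand = strand_major if rng.random() < sm.majority_strand_fraction else (
                    "-" if strand_major == "+" else "+"
                )
                first = str(rng.choice(nts, p=nt_p))
                tail = rng.choice(BASES, size=L - 1).tobytes().decode()
                read_rows.append(
                    (row.chrom, start, start + L, strand, first + tail, lib, int(c))
                )

    reads = pd.DataFrame(
        read_rows, columns=["chrom", "start", "end", "strand", "sequence", "library", "count"]
    ).sort_values(["chrom", "start", "library"]).reset_index(drop=True)

    counts = pd.DataFrame(count_cols, index=locus_df["locus_id"])
    counts.index.name = "locus_id"
    sample_sheet = pd.DataFrame(
        [
            (f"{lib}_rep{r + 1}", lib, r + 1)
            for lib in ("untreated", "oxidized", "trapr")
            for r in range(sm.n_replicates)
        ],
        columns=["sample", "library", "replicate"],
    )

    locus_df["oxidized_enriched"] = ox_enr
    locus_df["trapr_enriched"] = tr_enr
    locus_df["depleted"] = depleted
    genome.truth.srna = locus_df
    return reads, counts, sample_sheet


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_expression_counts(
    genome: SyntheticGenome, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Count matrices for genes, TE subfamilies and TE loci over the design.

    Returns {'genes', 'te_subfamilies', 'te_loci', 'sample_sheet', 'lengths'}.
    Planted subfamily log2 fold changes apply in every non-control condition;
    non-expressed features draw from near-zero means so the published
    expression filters recover the planted expressed sets.
    """
    ed = config.expression_design
    if ed.dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    if rng is None:
        rng = stage_rng(config, "expression")
    samples = [
        (f"{cond}_r{r + 1}", cond, r + 1)
        for cond in ed.conditions
        for r in range(ed.n_replicates)
    ]
    sample_sheet = pd.DataFrame(samples, columns=["sample", "condition", "replicate"])
    names = sample_sheet["sample"].tolist()

    def matrix(index, base_mean, lfc_per_feature=None) -> pd.DataFrame:
        cols = {}
        for sample, cond, _ in samples:
            mu = base_mean.copy()
            if lfc_per_feature is not None and cond != ed.conditions[0]:
                mu = mu * np.exp2(lfc_per_feature)
            cols[sample] = _nb(rng, mu, ed.dispersion)
        return pd.DataFrame(cols, index=index, columns=names)

    gene_truth = genome.truth.genes
    g_mean = np.where(
        gene_truth["expressed"],
        rng.lognormal(np.log(ed.expressed_mean), ed.expressed_sigma, len(gene_truth)),
        ed.silent_gene_mean,
    )
    genes_m = matrix(pd.Index(gene_truth["gene_id"], name="feature"), g_mean)

    te_truth = genome.truth.te
    sub = genome.truth.subfamilies.set_index("subfamily")
    sub_mean = np.full(len(sub), ed.subfamily_mean)
    sub_lfc = sub["planted_log2fc"].to_numpy()
    sub_m = matrix(pd.Index(sub.index, name="feature"), sub_mean, sub_lfc)

    loc_mean = np.where(
        te_truth["expressed"],
        rng.lognormal(np.log(ed.expressed_mean), ed.expressed_sigma, len(te_truth)),
        ed.silent_te_mean,
    )
    loci_m = matrix(pd.Index(te_truth["te_id"], name="feature"), loc_mean)

    lengths = pd.Series(
        (te_truth["end"] - te_truth["start"]).to_numpy(),
        index=te_truth["te_id"], name="length",
    )
    return {
        "genes": genes_m,
        "te_subfamilies": sub_m,
        "te_loci": loci_m,
        "sample_sheet": sample_sheet,
        "lengths": lengths,
    }
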