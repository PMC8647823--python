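"""End-to-end orchestration: simulate -> divergence -> methylome -> gene
classes -> proximity -> expression -> sRNA -> report.

Every stage reads the previous stage's in-memory products (and writes its
tables under the run directory), applies the published thresholds, and
contributes headline numbers to a JSON report mirroring the figure-level
summaries: the repeat landscape, site-level bimodality fractions, per-class
mCG distributions, nearest-TE tests, sRNA profiles and origin counts, and
the shuffled-locus distance null.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence, expression, genes as gene_classes, io, methylome, proximity, srna
from .config import SimulationConfig
from .srna import LocusCallParams
from .synthetic import (
    SyntheticGenome,
    generate_expression_counts,
    generate_genome,
    generate_methylome,
    generate_srna_reads,
)

log = logging.getLogger("rhizoepi")

ALL_STAGES = (
    "simulate", "divergence", "methylome", "gene_classes",
    "proximity", "expression", "srna",
)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "rhizoepi_run"
    stages: tuple[str, ...] = ALL_STAGES
    locus_params: LocusCallParams = field(default_factory=LocusCallParams)
    gene_meth_threshold: float = 0.5
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    n_shuffles: int = 1
    drop_unenriched: bool = False
    write_outputs: bool = True

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.simulation.validate()


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the report dictionary."""
    cfg.validate()
    out = Path(cfg.outdir)
    if cfg.write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.simulation.seed, "parameters": {
        "pad": cfg.locus_params.pad,
        "mincov_rpmm": cfg.locus_params.mincov_rpmm,
        "dicermin": cfg.locus_params.dicermin,
        "dicermax": cfg.locus_params.dicermax,
        "strand_cutoff": cfg.locus_params.strand_cutoff,
        "gene_meth_threshold": cfg.gene_meth_threshold,
        "lfc_threshold": cfg.lfc_threshold,
        "fdr_threshold": cfg.fdr_threshold,
        "n_shuffles": cfg.n_shuffles,
    }}

    # ------------------------------------------------------------------ simulate
    log.info("simulate: generating synthetic genome (seed=%d)", cfg.simulation.seed)
    genome = generate_genome(cfg.simulation)
    meth_records = generate_methylome(genome, cfg.simulation)
    reads, srna_counts, srna_samples = generate_srna_reads(genome, cfg.simulation)
    expr = generate_expression_counts(genome, cfg.simulation)
    if cfg.write_outputs:
        io.write_fasta(genome.sequences, out / "genome.fa")
        io.write_repeatmasker_out(genome.te_table, out / "te_annotation.out")
        io.write_genes_gff3(genome.gene_records, out / "genes.gff3")
        io.write_alignments(genome.alignments, out / "te_alignments.afa")
        io.write_tsv(meth_records, out / "methylation.tsv")
        io.write_tsv(reads, out / "srna_reads.tsv")
        io.write_tsv(srna_counts.reset_index(), out / "srna_counts.tsv")
        io.write_tsv(genome.truth.te, out / "truth_te.tsv")
        io.write_tsv(genome.truth.genes, out / "truth_genes.tsv")
        (out / "config.yaml").write_text(cfg.simulation.to_yaml())
    report["simulate"] = {
        "n_chromosomes": cfg.simulation.n_chromosomes,
        "genome_bp": sum(genome.chrom_lengths.values()),
        "n_te_copies": len(genome.te_table),
        "n_genes": len(genome.gene_records),
        "n_srna_reads": int(reads["count"].sum()),
    }
    if set(cfg.stages) == {"simulate"}:
        return _finish(report, out, cfg)

    # ---------------------------------------------------------------- divergence
    estimates = {}
    if "divergence" in cfg.stages:
        log.info("divergence: estimating CpG-adjusted K2P per copy")
        rows = []
        landscape_input = []
        genome_bp = sum(genome.nuclear_lengths.values())
        for aln in genome.alignments:
            est = divergence.kimura_distance(aln, cpg_adjust=True)
            estimates[aln.copy_id] = est
            rows.append((aln.copy_id, est.P, est.Q, est.K, est.percent, est.n_sites))
            landscape_input.append((est, aln.end - aln.start, aln.superfamily))
        est_df = pd.DataFrame(rows, columns=["te_id", "P", "Q", "K", "K_pct", "n_sites"])
        landscape = divergence.build_landscape(landscape_input, genome_bp)
        truth_k = genome.truth.te.set_index("te_id")["planted_k"]
        merged = est_df.set_index("te_id").join(truth_k)
        mae = float((merged["K"] - merged["planted_k"]).abs().mean())
        if cfg.write_outputs:
            io.write_tsv(est_df, out / "kimura_estimates.tsv")
            io.write_tsv(landscape, out / "repeat_landscape.tsv")
        report["divergence"] = {
            "n_copies": len(est_df),
            "kimura_recovery_mae": mae,
            "te_coverage_pct": float(landscape["coverage_pct"].sum()),
        }

    # ------------------------------------------------------------------ methylome
    sites = te_scores = gene_scores = None
    if "methylome" in cfg.stages:
        log.info("methylome: merging symmetric CpG calls and scoring loci")
        sites = methylome.merge_symmetric_cg(meth_records)
        f_hi, f_lo, f_mid = methylome.classify_sites(sites)
        te_loci = genome.te_table.rename(columns={"te_id": "locus_id"})
        te_scores = methylome.score_loci(sites, te_loci)
        gene_df = pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genome.gene_records],
            columns=["locus_id", "chrom", "start", "end", "strand"],
        )
        gene_scores = methylome.score_loci(sites, gene_df)
        defined = gene_scores[gene_scores["n_sites"] > 0]
        labels = methylome.classify_gene_methylation(defined, cfg.gene_meth_threshold)
        profile = methylome.metagene_profile(te_loci.assign(strand="+"), sites)
        if cfg.write_outputs:
            io.write_tsv(te_scores, out / "te_mcg_scores.tsv")
            io.write_tsv(gene_scores, out / "gene_mcg_scores.tsv")
            io.write_tsv(profile, out / "te_metagene.tsv")
        report["methylome"] = {
            "n_merged_sites": len(sites),
            "frac_sites_high": f_hi,
            "frac_sites_low": f_lo,
            "frac_sites_intermediate": f_mid,
            "pct_genes_high_meth": 100.0 * float((labels == "high").mean()),
        }

    # --------------------------------------------------------------- gene classes
    class_table = None
    if "gene_classes" in cfg.stages:
        log.info("gene_classes: applying blocklist and class rules")
        class_table = gene_classes.classify_genes(genome.gene_records)
        truth_cls = genome.truth.genes[["gene_id", "gene_class"]]
        merged = class_table.merge(truth_cls, on="gene_id", suffixes=("", "_truth"))
        accuracy = float((merged["gene_class"] == merged["gene_class_truth"]).mean())
        dist = gene_classes.intergenic_distances(genome.gene_records)
        dist = dist.merge(class_table, on="gene_id")
        pooled = dist.melt(
            id_vars=["gene_id", "gene_class"], value_vars=["dist_5p", "dist_3p"],
            value_name="gap",
        ).dropna(subset=["gap"])
        groups = {
            "A": pooled.loc[pooled["gene_class"] == "A", "gap"].to_numpy(),
            "B_or_C": pooled.loc[
                pooled["gene_class"].str.startswith(("B_", "C_")), "gap"
            ].to_numpy(),
        }
        from .stats import kruskal_h

        h_gap, p_gap = kruskal_h(groups["A"], groups["B_or_C"])
        if cfg.write_outputs:
            io.write_tsv(class_table, out / "gene_classes.tsv")
            io.write_tsv(dist, out / "intergenic_distances.tsv")
        report["gene_classes"] = {
            "class_counts": class_table["gene_class"].value_counts().to_dict(),
            "classification_accuracy": accuracy,
            "median_gap_A": float(np.median(groups["A"])),
            "median_gap_B_or_C": float(np.median(groups["B_or_C"])),
            "intergenic_kw_p": p_gap,
        }

    # ------------------------------------------------------------------ proximity
    if "proximity" in cfg.stages and class_table is not None:
        log.info("proximity: nearest-TE assignment and enrichment tests")
        gene_df = pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end) for g in genome.gene_records],
            columns=["gene_id", "chrom", "start", "end"],
        )
        nearest = proximity.nearest_te(gene_df, genome.te_table)
        pooled_c = class_table.copy()
        pooled_c.loc[pooled_c["gene_class"].str.startswith("C_"), "gene_class"] = "C"
        mule_family = next(
            (f.name for f in cfg.simulation.te_library if "MULE" in f.superfamily), None
        )
        fisher = proximity.closest_family_enrichment(
            nearest, pooled_c, family=mule_family, gene_class="C", reference="A"
        )
        dist_tests = proximity.distance_class_test(nearest, pooled_c)
        if cfg.write_outputs:
            io.write_tsv(nearest, out / "nearest_te.tsv")
            io.write_tsv(
                pd.DataFrame(
                    [(t.comparison, t.statistic, t.p, t.p_adj, t.skipped) for t in dist_tests],
                    columns=["comparison", "H", "p", "p_adj", "skipped"],
                ),
                out / "proximity_tests.tsv",
            )
        report["proximity"] = {
            "mule_c_vs_a_odds_ratio": fisher.statistic,
            "mule_c_vs_a_fisher_p": fisher.p,
            "n_tests": len(dist_tests),
        }

    # ----------------------------------------------------------------- expression
    expressed_te_ids: set[str] = set()
    expressed_gene_ids: set[str] = set()
    if "expression" in cfg.stages:
        log.info("expression: normalization, filters, differential test")
        gene_norm = expression.normalize(expr["genes"])
        expressed_gene_ids = set(
            expression.apply_expression_filters(expr["genes"], gene_norm, "gene")
        )
        te_norm = expression.normalize(expr["te_loci"])
        expressed_te_ids = set(
            expression.apply_expression_filters(
                expr["te_loci"], te_norm, "te_locus", lengths=expr["lengths"]
            )
        )
        sub_norm = expression.normalize(expr["te_subfamilies"])
        expressed_subs = set(
            expression.apply_expression_filters(expr["te_subfamilies"], sub_norm, "te_subfamily")
        )
        sheet = expr["sample_sheet"]
        control = sheet.loc[sheet["condition"] == "0h", "sample"].tolist()
        treated = sheet.loc[sheet["condition"] == "48h_exudate", "sample"].tolist()
        de = expression.simple_de(
            sub_norm, control, treated,
            lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.fdr_threshold,
        )
        truth_sub = genome.truth.subfamilies.set_index("subfamily")
        planted = truth_sub.index[truth_sub["planted_log2fc"] != 0]
        recovered = de.loc[list(planted), "significant"].mean() if len(planted) else float("nan")
        gene_truth = genome.truth.genes.set_index("gene_id")["expressed"]
        te_truth = genome.truth.te.set_index("te_id")["expressed"]
        gene_acc = float(
            (gene_truth.index.isin(expressed_gene_ids) == gene_truth.to_numpy()).mean()
        )
        te_acc = float(
            (te_truth.index.isin(expressed_te_ids) == te_truth.to_numpy()).mean()
        )
        if cfg.write_outputs:
            io.write_tsv(de.reset_index(), out / "subfamily_de.tsv")
        report["expression"] = {
            "n_expressed_genes": len(expressed_gene_ids),
            "n_expressed_te_loci": len(expressed_te_ids),
            "n_expressed_subfamilies": len(expressed_subs),
            "gene_filter_accuracy": gene_acc,
            "te_filter_accuracy": te_acc,
            "planted_subfamily_de_sensitivity": float(recovered),
        }

        # Fig 2E analog: expressed TEs have lower mCG than non-expressed
        if te_scores is not None:
            sc = te_scores.dropna(subset=["mcg_score"])
            expr_scores = sc.loc[sc["locus_id"].isin(expressed_te_ids), "mcg_score"]
            non_scores = sc.loc[~sc["locus_id"].isin(expressed_te_ids), "mcg_score"]
            from .stats import kruskal_h

            h_e, p_e = kruskal_h(expr_scores.to_numpy(), non_scores.to_numpy())
            report["expression"]["expressed_te_mcg_kw_p"] = p_e
            report["expression"]["median_mcg_expressed_te"] = float(expr_scores.median())
            report["expression"]["median_mcg_nonexpressed_te"] = float(non_scores.median())

    # ----------------------------------------------------------------------- sRNA
    if "srna" in cfg.stages:
        log.info("srna: locus calling, enrichment, origin, shuffle null")
        called = srna.call_loci(reads, cfg.locus_params)
        # aggregate planted replicate counts onto called loci by best overlap
        planted = genome.truth.srna
        assign = {}
        called_by_chrom = {c: g for c, g in called.groupby("chrom")}
        for row in planted.itertuples(index=False):
            g = called_by_chrom.get(row.chrom)
            if g is None:
                continue
            ov = np.minimum(g["end"].to_numpy(), row.end) - np.maximum(
                g["start"].to_numpy(), row.start
            )
            if ov.max() > 0:
                assign[row.locus_id] = g["locus_id"].to_numpy()[int(np.argmax(ov))]
        counts = srna_counts.copy()
        counts["called"] = counts.index.map(assign)
        called_counts = counts.dropna(subset=["called"]).groupby("called").sum()
        called_counts.index.name = "locus_id"
        samples = srna_samples
        unt = samples.loc[samples["library"] == "untreated", "sample"].tolist()
        ox = samples.loc[samples["library"] == "oxidized", "sample"].tolist()
        tr = samples.loc[samples["library"] == "trapr", "sample"].tolist()
        norm = expression.normalize(called_counts)
        de_ox = expression.simple_de(norm, unt, ox, lfc_threshold=0.0,
                                     fdr_threshold=cfg.fdr_threshold)
        de_tr = expression.simple_de(norm, unt, tr, lfc_threshold=0.0,
                                     fdr_threshold=cfg.fdr_threshold)
        de_ox = de_ox.rename(columns={"fdr": "fdr", "log2fc": "log2fc"})
        flags = srna.enrichment_classify(
            de_ox, de_tr, fdr_threshold=cfg.fdr_threshold,
            drop_unenriched=cfg.drop_unenriched,
        )
        retained_ids = set(flags.index[flags["retained"]])
        retained = called[called["locus_id"].isin(retained_ids)]
        gene_df = pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end) for g in genome.gene_records],
            columns=["gene_id", "chrom", "start", "end"],
        )
        origins = srna.assign_origin(
            retained, genome.te_table, expressed_te_ids, gene_df, expressed_gene_ids
        )
        production = srna.te_srna_production(
            retained, genome.te_table,
            kimura_percent=pd.Series(
                {tid: est.percent for tid, est in estimates.items()}
            ) if estimates else None,
        )
        # shuffle null per origin class (unannotated and genic separately),
        # nuclear genome only
        annotated = retained.merge(origins, on="locus_id")
        annotated = annotated[annotated["chrom"] != genome.mito_chrom]
        rng = np.random.default_rng(cfg.simulation.seed * 8 + 5)
        null_results = {}
        for origin_class in ("unannotated", "genic"):
            sub = annotated[annotated["origin"] == origin_class]
            if len(sub) < 2:
                continue
            observed, shuffled, null_test = srna.shuffle_null_distance(
                sub, genome.te_table, genome.nuclear_lengths,
                n_sets=cfg.n_shuffles, seed=rng,
            )
            null_results[origin_class] = {
                "H": null_test.statistic,
                "p": null_test.p,
                "median_observed": float(np.median(observed)),
                "median_shuffled": float(np.median(shuffled)),
                "n_observed": int(observed.size),
            }
        profiles = {
            lib: srna.profile_reads(reads, lib) for lib in srna.LIBRARIES
        }
        mito_share = {
            lib: float(
                reads.loc[
                    (reads["library"] == lib) & (reads["chrom"] == genome.mito_chrom),
                    "count",
                ].sum()
            ) / max(float(reads.loc[reads["library"] == lib, "count"].sum()), 1.0)
            for lib in srna.LIBRARIES
        }
        origin_counts = origins["origin"].value_counts().to_dict()
        if cfg.write_outputs:
            io.write_tsv(called, out / "srna_loci.tsv")
            io.write_tsv(flags.reset_index(), out / "srna_enrichment.tsv")
            io.write_tsv(origins, out / "srna_origins.tsv")
            io.write_tsv(production.drop(columns=["kimura_bins"], errors="ignore"),
                         out / "srna_te_production.tsv")
            for lib, prof in profiles.items():
                io.write_tsv(prof.reset_index(names="length"), out / f"srna_profile_{lib}.tsv")
        peak = {
            lib: int(prof.sum(axis=1).idxmax()) if prof.to_numpy().sum() else 0
            for lib, prof in profiles.items()
        }
        report["srna"] = {
            "n_called_loci": len(called),
            "n_retained_loci": len(retained),
            "n_enriched_either": int((flags["oxidized_enriched"] | flags["trapr_enriched"]).sum()),
            "n_enriched_both": int(flags["dual_enriched"].sum()),
            "n_depleted": int(flags["depleted"].sum()),
            "origin_counts": origin_counts,
            "frac_te_derived": float(
                (origins["origin"].str.startswith("TE_")).mean()
            ) if len(origins) else float("nan"),
            "mito_read_share": mito_share,
            "modal_read_length": peak,
            "shuffle_null": null_results,
        }

    return _finish(report, out, cfg)


def _finish(report: dict, out: Path, cfg: PipelineConfig) -> dict:
    report = _json_safe(report)
    if cfg.write_outputs:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
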