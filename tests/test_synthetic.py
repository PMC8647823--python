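"""Parameter recovery and planted structure of the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config

from rhizoepi.config import (
    ConfigurationError,
    CopyPlan,
    ExpressionDesign,
    MethylationModel,
    SimulationConfig,
    SrnaModel,
    TEFamily,
)
from rhizoepi.divergence import SaturationError, kimura_distance
from rhizoepi.synthetic import (
    generate_expression_counts,
    generate_genome,
    generate_methylome,
    generate_srna_reads,
    mutate_copy,
    solve_pq,
)


class TestSolvePq:
    def test_zero_k_gives_zero_proportions(self):
        assert solve_pq(0.0, 0.5) == (0.0, 0.0)

    @pytest.mark.parametrize("k", [0.05, 0.1, 0.2, 0.4])
    @pytest.mark.parametrize("ratio", [0.0, 0.5, 1.0])
    def test_solution_satisfies_k2p(self, k, ratio):
        from rhizoepi.divergence import kimura_k

        p, q = solve_pq(k, ratio)
        assert kimura_k(p, q) == pytest.approx(k, abs=1e-10)
        assert q == pytest.approx(ratio * p, abs=1e-12)

    def test_unattainable_k_saturates(self):
        # admissible (P, Q) keep both log arguments positive, which bounds K
        with pytest.raises(SaturationError):
            solve_pq(50.0, 2.0)


class TestGenerateGenome:
    def test_zero_divergence_copy_equals_consensus(self, rng):
        cons = np.frombuffer(b"ACGT" * 250, dtype="S1").copy()
        copy = mutate_copy(cons, 0.0, 0.5, rng)
        assert bytes(copy) == bytes(cons)

    def test_same_seed_reproduces_identical_bytes(self):
        cfg_a = small_config(seed=11)
        cfg_b = small_config(seed=11)
        ga, gb = generate_genome(cfg_a), generate_genome(cfg_b)
        assert ga.sequences == gb.sequences
        assert ga.te_table.equals(gb.te_table)
        assert ga.truth.genes.equals(gb.truth.genes)

    def test_different_seeds_differ(self):
        ga = generate_genome(small_config(seed=1))
        gb = generate_genome(small_config(seed=2))
        assert ga.sequences != gb.sequences

    def test_annotation_coordinates_match_fasta(self, small_genome):
        # the planted copy sequence is literally at its annotated interval
        for aln in small_genome.alignments[:25]:
            assert small_genome.sequences[aln.chrom][aln.start:aln.end] == aln.copy

    def test_features_do_not_overlap(self, small_genome):
        intervals = {}
        for row in small_genome.te_table.itertuples(index=False):
            intervals.setdefault(row.chrom, []).append((row.start, row.end))
        for g in small_genome.gene_records:
            intervals.setdefault(g.chrom, []).append((g.start, g.end))
        for chrom, ivs in intervals.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2, f"overlap on {chrom}"

    def test_every_annotation_has_one_truth_entry(self, small_genome):
        assert set(small_genome.te_table["te_id"]) == set(small_genome.truth.te["te_id"])
        assert {g.gene_id for g in small_genome.gene_records} == set(
            small_genome.truth.genes["gene_id"]
        )
        assert small_genome.truth.genes["gene_id"].is_unique

    def test_planted_k_recovered_within_tolerance(self):
        # >= 50 copies of >= 2 kb at a fixed planted K
        cfg = small_config(seed=3)
        cfg.copy_plan = {
            "Gypsy1": CopyPlan(n_copies=50, k_values=[0.10], length_fraction=(0.45, 0.45))
        }
        cfg.gene_plan.class_counts = {k: 0 for k in cfg.gene_plan.class_counts}
        cfg.gene_plan.near_mule_fraction = 0.0
        g = generate_genome(cfg)
        ks = [kimura_distance(a, cpg_adjust=False).K for a in g.alignments]
        assert len(ks) == 50
        assert abs(np.mean(ks) - 0.10) < 0.02

    def test_near_mule_genes_within_planted_distance(self, small_genome):
        truth = small_genome.truth.genes
        paired = truth[truth["near_mule"]]
        assert len(paired) > 0
        te = small_genome.te_table.set_index("te_id")
        genes = {g.gene_id: g for g in small_genome.gene_records}
        for row in paired.itertuples(index=False):
            mule = te.loc[row.paired_mule]
            gene = genes[row.gene_id]
            gap = gene.start - mule["end"]
            assert 0 < gap <= 500
            assert gene.chrom == mule["chrom"]

    def test_saturating_copy_plan_rejected(self):
        cfg = small_config(seed=0)
        cfg.copy_plan = {"Gypsy1": CopyPlan(n_copies=1, k_values=[50.0])}
        with pytest.raises(SaturationError):
            generate_genome(cfg)


class TestGenerateMethylome:
    def _genome(self, seed=0, p_high=None):
        cfg = small_config(seed=seed)
        if p_high is not None:
            cfg.methylation_model.p_high = p_high
        g = generate_genome(cfg)
        return cfg, g

    def test_records_only_at_cpg_dinucleotides_both_strands(self):
        cfg, g = self._genome()
        rec = generate_methylome(g, cfg)
        plus = rec[rec["strand"] == "+"]
        minus = rec[rec["strand"] == "-"]
        assert len(plus) == len(minus)
        for row in plus.head(50).itertuples(index=False):
            assert g.sequences[row.chrom][row.pos:row.pos + 2] == "CG"

    def test_all_high_class_loci_have_high_medians(self):
        p_high = {k: 1.0 for k in MethylationModel().p_high}
        cfg, g = self._genome(p_high=p_high)
        rec = generate_methylome(g, cfg)
        from rhizoepi.methylome import merge_symmetric_cg, score_loci

        sites = merge_symmetric_cg(rec)
        loci = g.te_table.rename(columns={"te_id": "locus_id"})
        scores = score_loci(sites, loci)
        ok = scores[scores["n_sites"] >= 20]
        assert len(ok) > 10
        assert (ok["mcg_score"] > 0.8).all()

    def test_all_low_class_loci_have_low_medians(self):
        p_high = {k: 0.0 for k in MethylationModel().p_high}
        cfg, g = self._genome(p_high=p_high)
        rec = generate_methylome(g, cfg)
        from rhizoepi.methylome import merge_symmetric_cg, score_loci

        sites = merge_symmetric_cg(rec)
        loci = g.te_table.rename(columns={"te_id": "locus_id"})
        scores = score_loci(sites, loci)
        ok = scores[scores["n_sites"] >= 20]
        assert (ok["mcg_score"] < 0.2).all()

    def test_component_classification_accuracy(self):
        cfg, g = self._genome()
        rec = generate_methylome(g, cfg)
        from rhizoepi.methylome import merge_symmetric_cg, score_loci

        sites = merge_symmetric_cg(rec)
        all_loci = pd.concat([
            g.te_table.rename(columns={"te_id": "locus_id"})[["locus_id", "chrom", "start", "end"]],
            pd.DataFrame(
                [(x.gene_id, x.chrom, x.start, x.end) for x in g.gene_records],
                columns=["locus_id", "chrom", "start", "end"],
            ),
        ])
        scores = score_loci(sites, all_loci).set_index("locus_id")
        truth = g.truth.methylation.set_index("locus_id")
        joined = truth.join(scores)
        joined = joined[(joined["n_cpg"] >= 5) & (joined["component"] != "none")]
        predicted = np.where(joined["mcg_score"] > 0.5, "high", "low")
        accuracy = float((predicted == joined["component"]).mean())
        assert accuracy >= 0.95

    def test_missing_feature_class_rejected(self):
        cfg = small_config(seed=0)
        cfg.methylation_model.p_high = {"background": 0.3}
        g = generate_genome(cfg)
        with pytest.raises(ConfigurationError, match="missing"):
            generate_methylome(g, cfg)


@pytest.fixture(scope="module")
def srna_data():
    cfg = small_config(seed=5)
    g = generate_genome(cfg)
    reads, counts, samples = generate_srna_reads(g, cfg)
    return cfg, g, reads, counts, samples


class TestGenerateSrna:
    def test_first_nt_frequencies_within_three_sd(self, srna_data):
        # each collapsed read form draws its first nucleotide independently,
        # so the binomial check runs over forms, not over total read counts
        cfg, g, reads, _, _ = srna_data
        first = reads["sequence"].str[0]
        n = len(reads)
        assert n > 1000
        for nt, p in cfg.srna_model.first_nt_probs.items():
            obs = (first == nt).mean()
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * sd + 1e-3, nt

    def test_read_lengths_peak_at_24(self, srna_data):
        _, _, reads, _, _ = srna_data
        lengths = (reads["end"] - reads["start"]).to_frame("L").assign(c=reads["count"])
        modal = lengths.groupby("L")["c"].sum().idxmax()
        assert modal == 24

    def test_mito_share_depleted_in_treated_libraries(self, srna_data):
        _, g, reads, _, _ = srna_data
        shares = {}
        for lib in ("untreated", "oxidized", "trapr"):
            sub = reads[reads["library"] == lib]
            shares[lib] = sub.loc[sub["chrom"] == "mito", "count"].sum() / sub["count"].sum()
        assert shares["oxidized"] < shares["untreated"]
        assert shares["trapr"] < shares["untreated"]

    def test_planted_enrichment_factor_recovered(self, srna_data):
        cfg, g, _, counts, _ = srna_data
        truth = g.truth.srna.set_index("locus_id")
        enriched = truth[truth["oxidized_enriched"]]
        unt = counts[[c for c in counts if c.startswith("untreated")]].sum(axis=1)
        ox = counts[[c for c in counts if c.startswith("oxidized")]].sum(axis=1)
        ratio = (ox.loc[enriched.index].sum() + 1) / (unt.loc[enriched.index].sum() + 1)
        assert ratio == pytest.approx(cfg.srna_model.enrich_factor, rel=0.25)

    def test_empty_te_annotation_rejected(self):
        cfg = small_config(seed=0)
        cfg.copy_plan = {name: CopyPlan(n_copies=0) for name in cfg.copy_plan}
        cfg.gene_plan.near_mule_fraction = 0.0
        g = generate_genome(cfg)
        with pytest.raises(ConfigurationError):
            generate_srna_reads(g, cfg)


class TestGenerateExpression:
    def test_design_has_twenty_samples(self, small_genome):
        cfg = small_config(seed=0)
        out = generate_expression_counts(small_genome, cfg)
        assert out["genes"].shape[1] == 20
        assert len(out["sample_sheet"]) == 20
        assert out["sample_sheet"]["condition"].nunique() == 5

    def test_all_zero_feature_stays_zero(self, small_genome):
        cfg = small_config(seed=0)
        cfg.expression_design.silent_gene_mean = 0.0
        out = generate_expression_counts(small_genome, cfg)
        truth = small_genome.truth.genes.set_index("gene_id")
        silent = truth.index[~truth["expressed"]]
        assert (out["genes"].loc[silent].to_numpy() == 0).all()

    def test_planted_fold_change_shifts_means(self, small_genome):
        cfg = small_config(seed=0)
        cfg.expression_design.planted_log2fc = {"MULE1": 2.0}
        out = generate_expression_counts(small_genome, cfg)
        sheet = out["sample_sheet"]
        control = sheet.loc[sheet["condition"] == "0h", "sample"]
        treated = sheet.loc[sheet["condition"] != "0h", "sample"]
        m = out["te_subfamilies"]
        ratio = m.loc["MULE1", treated].mean() / m.loc["MULE1", control].mean()
        assert ratio == pytest.approx(4.0, rel=0.3)

    def test_nonpositive_dispersion_rejected(self, small_genome):
        cfg = small_config(seed=0)
        cfg.expression_design.dispersion = -1.0
        with pytest.raises(ConfigurationError):
            generate_expression_counts(small_genome, cfg)


class TestConfigValidation:
    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ConfigurationError, match="20 samples"):
            ExpressionDesign(n_replicates=3).validate()

    def test_bad_probability_table_rejected(self):
        with pytest.raises(ConfigurationError):
            SrnaModel(first_nt_probs={"T": 0.9, "A": 0.3, "C": 0.1, "G": 0.1}).validate()

    def test_negative_length_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(chrom_length=-5).validate()

    def test_unknown_copy_plan_family_rejected(self):
        cfg = SimulationConfig()
        cfg.copy_plan["NoSuchFam"] = CopyPlan(n_copies=1)
        with pytest.raises(ConfigurationError, match="unknown family"):
            cfg.validate()

    def test_yaml_dump_round_trips_scalars(self):
        import yaml

        cfg = SimulationConfig(seed=42)
        data = yaml.safe_load(cfg.to_yaml())
        assert data["seed"] == 42
        assert data["expression_design"]["n_replicates"] == 4

    def test_yaml_load_merges_partials_and_rejects_unknown_keys(self):
        cfg = SimulationConfig.from_yaml(
            "seed: 7\nsrna_model:\n  enrich_factor: 8.0\n"
        )
        assert cfg.seed == 7
        assert cfg.srna_model.enrich_factor == 8.0
        assert cfg.srna_model.mito_depletion == 0.05  # default retained
        with pytest.raises(ConfigurationError, match="unknown config key"):
            SimulationConfig.from_yaml("chromosome_count: 4\n")
        with pytest.raises(ConfigurationError, match="unknown key"):
            SimulationConfig.from_yaml("srna_model:\n  typo_field: 1\n")
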