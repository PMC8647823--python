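"""sRNA locus calling, profiles, enrichment flags, origins, shuffle null."""

import numpy as np
import pandas as pd
import pytest

from rhizoepi.srna import (
    LocusCallParams,
    assign_origin,
    call_loci,
    enrichment_classify,
    profile_reads,
    shuffle_loci,
    shuffle_null_distance,
    te_srna_production,
)


def _reads(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "sequence", "library", "count"]
    )


def _read(chrom, start, length=24, strand="+", lib="untreated", count=1, first="T"):
    return (chrom, start, start + length, strand, first + "A" * (length - 1), lib, count)


class TestCallLoci:
    def test_pad_merges_and_splits_islands(self):
        # reads 150 bp apart merge; 250 bp apart do not (pad=200)
        near = _reads([_read("chr1", 0), _read("chr1", 174)])
        far = _reads([_read("chr1", 0), _read("chr1", 274)])
        p = LocusCallParams(mincov_rpmm=0.0)
        assert len(call_loci(near, p)) == 1
        assert len(call_loci(far, p)) == 2

    def test_mincov_threshold_boundary(self):
        # total 10^6 reads -> threshold exactly 10 pooled reads at 10 rpmm
        filler = _read("chr2", 0, count=10**6 - 10)
        island9 = _reads([filler, _read("chr1", 0, count=9)])
        island10 = _reads([filler, _read("chr1", 0, count=10)])
        p = LocusCallParams(mincov_rpmm=10.0)
        assert "chr1" not in call_loci(island9, p)["chrom"].tolist()
        assert "chr1" in call_loci(island10, p)["chrom"].tolist()

    def test_strand_cutoff(self):
        rows = [_read("chr1", 0, strand="+", count=85), _read("chr1", 10, strand="-", count=15)]
        loci = call_loci(_reads(rows), LocusCallParams(mincov_rpmm=0.0))
        assert loci.iloc[0]["strand_fraction"] == pytest.approx(0.85)
        assert bool(loci.iloc[0]["stranded"])
        rows = [_read("chr1", 0, strand="+", count=70), _read("chr1", 10, strand="-", count=30)]
        loci = call_loci(_reads(rows), LocusCallParams(mincov_rpmm=0.0))
        assert not bool(loci.iloc[0]["stranded"])

    def test_dicer_call_uses_modal_length(self):
        rows = [_read("chr1", 0, length=24, count=10), _read("chr1", 5, length=40, count=3)]
        loci = call_loci(_reads(rows), LocusCallParams(mincov_rpmm=0.0))
        assert loci.iloc[0]["major_length"] == 24
        assert bool(loci.iloc[0]["dicer_call"])
        rows = [_read("chr1", 0, length=40, count=10), _read("chr1", 5, length=24, count=3)]
        loci = call_loci(_reads(rows), LocusCallParams(mincov_rpmm=0.0))
        assert not bool(loci.iloc[0]["dicer_call"])

    def test_per_library_counts_assigned(self):
        rows = [_read("chr1", 0, lib="untreated", count=5),
                _read("chr1", 10, lib="oxidized", count=7),
                _read("chr1", 20, lib="trapr", count=2)]
        loci = call_loci(_reads(rows), LocusCallParams(mincov_rpmm=0.0))
        row = loci.iloc[0]
        assert (row["count_untreated"], row["count_oxidized"], row["count_trapr"]) == (5, 7, 2)

    def test_zero_total_reads_rejected(self):
        with pytest.raises(ValueError):
            call_loci(_reads([_read("chr1", 0, count=0)]), LocusCallParams())

    def test_idempotent_on_own_intervals(self, rng):
        rows = [_read("chr1", int(s), count=int(c))
                for s, c in zip(rng.integers(0, 20_000, 60), rng.integers(1, 30, 60))]
        p = LocusCallParams(mincov_rpmm=0.0)
        loci = call_loci(_reads(rows), p)
        # feed the locus intervals back as reads: clustering must not change them
        again = call_loci(
            _reads([
                (r["chrom"], r["start"], r["end"], "+", "T", "untreated", r["total_count"])
                for _, r in loci.iterrows()
            ]),
            p,
        )
        assert again[["chrom", "start", "end"]].equals(loci[["chrom", "start", "end"]])


class TestProfileReads:
    def test_single_read_lands_in_cell(self):
        mat = profile_reads(_reads([_read("chr1", 0, length=24, first="T")]), "untreated")
        assert mat.at[24, "U"] == 1
        assert mat.to_numpy().sum() == 1

    def test_row_sums_match_length_histogram(self, rng):
        rows = []
        for _ in range(300):
            L = int(rng.integers(18, 36))
            rows.append(_read("chr1", int(rng.integers(0, 1000)), length=L,
                              first=str(rng.choice(list("ACGT"))), count=int(rng.integers(1, 5))))
        reads = _reads(rows)
        mat = profile_reads(reads, "untreated")
        hist = (reads["end"] - reads["start"]).to_frame("L").assign(c=reads["count"]).groupby("L")["c"].sum()
        for L, total in hist.items():
            assert mat.loc[L].sum() == total

    def test_empty_library_gives_zero_matrix(self):
        mat = profile_reads(_reads([_read("chr1", 0)]), "trapr")
        assert mat.to_numpy().sum() == 0


class TestEnrichmentClassify:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "fdr"],
                            index=[f"l{i}" for i in range(len(rows))])

    def test_dual_enriched_and_retained(self):
        flags = enrichment_classify(self._de([(2.0, 0.001)]), self._de([(1.5, 0.01)]))
        row = flags.iloc[0]
        assert row["dual_enriched"] and row["retained"] and not row["depleted"]

    def test_depleted_in_one_treatment_removed(self):
        flags = enrichment_classify(self._de([(-3.0, 1e-4)]), self._de([(0.1, 0.9)]))
        row = flags.iloc[0]
        assert row["depleted"] and not row["retained"]

    def test_unenriched_but_not_depleted_retained_by_default(self):
        flags = enrichment_classify(self._de([(0.1, 0.9)]), self._de([(0.0, 1.0)]))
        assert bool(flags.iloc[0]["retained"])
        strict = enrichment_classify(self._de([(0.1, 0.9)]), self._de([(0.0, 1.0)]),
                                     drop_unenriched=True)
        assert not bool(strict.iloc[0]["retained"])

    def test_mismatched_designs_rejected(self):
        a = self._de([(1.0, 0.01)])
        b = self._de([(1.0, 0.01), (0.0, 1.0)])
        with pytest.raises(ValueError, match="same loci"):
            enrichment_classify(a, b)

    def test_retained_never_depleted(self, rng):
        n = 200
        a = pd.DataFrame({"log2fc": rng.normal(0, 2, n), "fdr": rng.random(n)})
        b = pd.DataFrame({"log2fc": rng.normal(0, 2, n), "fdr": rng.random(n)})
        flags = enrichment_classify(a, b)
        assert not (flags["retained"] & flags["depleted"]).any()


class TestAssignOrigin:
    def _loci(self, rows):
        return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])

    def _tes(self, rows):
        return pd.DataFrame(rows, columns=["te_id", "family", "superfamily", "chrom", "start", "end"])

    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def test_hierarchy_te_beats_gene(self):
        loci = self._loci([("l1", "chr1", 100, 200)])
        tes = self._tes([("t1", "f", "s", "chr1", 150, 400)])
        genes = self._genes([("g1", "chr1", 0, 500)])
        out = assign_origin(loci, tes, set(), genes, {"g1"})
        assert out.iloc[0]["origin"] == "TE_nonexpressed"

    def test_expressed_te_flag(self):
        loci = self._loci([("l1", "chr1", 100, 200)])
        tes = self._tes([("t1", "f", "s", "chr1", 150, 400)])
        out = assign_origin(loci, tes, {"t1"}, self._genes([]), set())
        assert out.iloc[0]["origin"] == "TE_expressed"

    def test_larger_overlap_wins_conflict(self):
        loci = self._loci([("l1", "chr1", 100, 300)])
        tes = self._tes([("big", "f", "s", "chr1", 100, 280),
                         ("small", "f", "s", "chr1", 280, 400)])
        out = assign_origin(loci, tes, {"small"}, self._genes([]), set())
        assert out.iloc[0]["matched_id"] == "big"
        assert out.iloc[0]["origin"] == "TE_nonexpressed"

    def test_exact_tie_goes_to_expressed(self):
        loci = self._loci([("l1", "chr1", 100, 300)])
        tes = self._tes([("x", "f", "s", "chr1", 100, 200),
                         ("y", "f", "s", "chr1", 200, 300)])
        out = assign_origin(loci, tes, {"y"}, self._genes([]), set())
        assert out.iloc[0]["matched_id"] == "y"

    def test_nonexpressed_gene_falls_through_to_unannotated(self):
        loci = self._loci([("l1", "chr1", 100, 200)])
        genes = self._genes([("g1", "chr1", 0, 500)])
        out = assign_origin(loci, self._tes([]), set(), genes, set())
        assert out.iloc[0]["origin"] == "unannotated"
        assert out.attrs["nonexpressed_gene_overlaps"] == 1

    def test_no_overlap_unannotated(self):
        out = assign_origin(self._loci([("l1", "chr1", 0, 50)]), self._tes([]),
                            set(), self._genes([]), set())
        assert out.iloc[0]["origin"] == "unannotated"

    def test_planted_origins_recovered_exactly(self, small_genome):
        from conftest import small_config
        from rhizoepi.synthetic import generate_srna_reads

        cfg = small_config(seed=0)
        generate_srna_reads(small_genome, cfg)
        planted = small_genome.truth.srna
        te_truth = small_genome.truth.te
        expressed_tes = set(te_truth.loc[te_truth["expressed"], "te_id"])
        gene_truth = small_genome.truth.genes
        expressed_genes = set(gene_truth.loc[gene_truth["expressed"], "gene_id"])
        genes = pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end) for g in small_genome.gene_records],
            columns=["gene_id", "chrom", "start", "end"],
        )
        out = assign_origin(planted, small_genome.te_table, expressed_tes,
                            genes, expressed_genes)
        merged = out.merge(planted[["locus_id", "origin"]], on="locus_id",
                           suffixes=("_called", "_truth"))
        assert (merged["origin_called"] == merged["origin_truth"]).all()


class TestShuffleNull:
    def _loci(self, rng, n=40):
        starts = rng.integers(0, 90_000, n)
        return pd.DataFrame(
            {"locus_id": [f"l{i}" for i in range(n)], "chrom": "chr1",
             "start": starts, "end": starts + rng.integers(50, 400, n)},
        )

    def _tes(self, rng, n=30):
        starts = rng.integers(0, 95_000, n)
        return pd.DataFrame(
            {"te_id": [f"t{i}" for i in range(n)], "family": "f", "superfamily": "s",
             "chrom": "chr1", "start": starts, "end": starts + rng.integers(200, 2000, n)},
        )

    def test_fixed_seed_reproducible(self, rng):
        loci = self._loci(rng)
        lengths = {"chr1": 100_000, "chr2": 50_000}
        a = shuffle_loci(loci, lengths, np.random.default_rng(7))
        b = shuffle_loci(loci, lengths, np.random.default_rng(7))
        assert a.equals(b)

    def test_shuffle_preserves_length_multiset(self, rng):
        loci = self._loci(rng)
        out = shuffle_loci(loci, {"chr1": 100_000, "chr2": 50_000}, rng)
        assert sorted(out["end"] - out["start"]) == sorted(loci["end"] - loci["start"])

    def test_locus_longer_than_every_chromosome_rejected(self, rng):
        loci = pd.DataFrame({"locus_id": ["l"], "chrom": ["chr1"], "start": [0], "end": [5000]})
        with pytest.raises(ValueError, match="longer"):
            shuffle_loci(loci, {"chr1": 1000}, rng)

    def test_loci_planted_inside_tes_significant(self, rng):
        tes = self._tes(rng)
        inside = []
        for i in range(40):
            t = tes.iloc[int(rng.integers(len(tes)))]
            inside.append((f"l{i}", "chr1", t["start"], min(t["end"], t["start"] + 100)))
        loci = pd.DataFrame(inside, columns=["locus_id", "chrom", "start", "end"])
        observed, shuffled, res = shuffle_null_distance(
            loci, tes, {"chr1": 100_000}, n_sets=3, seed=5
        )
        assert np.median(observed) == 0
        assert res.p < 0.01


class TestTeSrnaProduction:
    def test_percentage_arithmetic(self):
        tes = pd.DataFrame(
            [(f"t{i}", "Gypsy1", "LTR/Gypsy", "chr1", i * 1000, i * 1000 + 500) for i in range(8)],
            columns=["te_id", "family", "superfamily", "chrom", "start", "end"],
        )
        loci = pd.DataFrame(
            [("l1", "chr1", 100, 200)], columns=["locus_id", "chrom", "start", "end"]
        )
        out = te_srna_production(loci, tes)
        assert out.iloc[0]["pct_producing"] == pytest.approx(12.5)
        assert out.iloc[0]["n_srna_loci"] == 1

    def test_no_loci_all_zero(self):
        tes = pd.DataFrame(
            [("t1", "f", "s", "chr1", 0, 100)],
            columns=["te_id", "family", "superfamily", "chrom", "start", "end"],
        )
        loci = pd.DataFrame(columns=["locus_id", "chrom", "start", "end"])
        out = te_srna_production(loci, tes)
        assert out.iloc[0]["pct_producing"] == 0.0

    def test_counts_match_bruteforce_overlap(self, rng):
        tes = pd.DataFrame(
            [(f"t{i}", "f", "s", "chr1", s := int(rng.integers(0, 50_000)),
              s + int(rng.integers(100, 2000))) for i in range(30)],
            columns=["te_id", "family", "superfamily", "chrom", "start", "end"],
        )
        loci = pd.DataFrame(
            [(f"l{i}", "chr1", s := int(rng.integers(0, 50_000)),
              s + int(rng.integers(50, 500))) for i in range(40)],
            columns=["locus_id", "chrom", "start", "end"],
        )
        out = te_srna_production(loci, tes)
        brute = 0
        for t in tes.itertuples(index=False):
            brute += sum(
                1 for l in loci.itertuples(index=False)
                if l.start < t.end and t.start < l.end
            )
        assert out["n_srna_loci"].sum() == brute
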