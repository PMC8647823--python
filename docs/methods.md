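# Methods

This note documents the models, defaults and design choices behind
`rhizoepi`, in the order the pipeline runs them.

## Synthetic study conditions

The generator (`rhizoepi.synthetic`) is first-class, tested code; its
defaults define the conditions every downstream claim is evaluated under.

**Genome.** Four 500-kb chromosomes of i.i.d. bases at 40% GC plus a 30-kb
mitochondrial contig. CpG density under this background (~4% of positions)
is ample for locus-level methylation scoring; no isochore or repeat-seeded
CpG-island structure is modeled.

**TE copies.** Eight families spanning the superfamilies typical of a
repeat-rich fungal genome (MULE-MuDR, CMC-EnSpm, hAT, TcMar, Gypsy, Copia,
LINE, Helitron), 500 copies total, consensus lengths 1.8–5 kb. Each copy is
the consensus prefix (length fraction uniform on 0.08–0.40, matching a
~15% classified-TE genome share) mutated with i.i.d. per-site
substitutions. Transition probability P and transversion probability Q are
solved numerically so that the Kimura 2-parameter distance of the
*expected* proportions equals the planted K, with Q = P/2 by default (the
estimator, not the substitution model, is what matters downstream; the
ratio is configurable). No back-mutation bookkeeping: at the planted
divergences (≤ 0.35) double hits are rare, and recovery is asserted in
expectation with a stated tolerance (MAE < 0.02 over ≥ 50 copies of ≥ 2 kb),
not per copy. Planted K values follow a two-wave mixture — half the copies
uniform on [0.01, 0.08] ("young"), half on [0.15, 0.35] ("old") — giving
the bimodal landscape characteristic of episodic TE expansion. A planted K
whose (P, Q) solution would saturate the K2P logarithms is rejected with a
saturation error.

**Layout.** TE copies and genes are non-overlapping blocks laid left to
right per chromosome with random exponential gaps. A planted fraction
(default 0.6) of Class C genes is emitted as a literal (MULE copy, gap ≤
500 bp, gene) block, so MULE adjacency is guaranteed by construction
rather than by rejection sampling. Gaps flanking Class A genes are shrunk
3.3-fold, planting the shorter intergenic spacing of a gene-dense core
compartment. Gene domain labels are drawn per class from fixed token pools
(Class B genes carry none); the repeat-overlap flag that splits B_HCN from
B_LCN is planted directly as annotation, not derived from coordinates.

**Methylome.** Every CpG yields a plus- and a minus-strand record. Each
annotated locus is assigned the high or low beta component — Beta(50, 2)
vs Beta(2, 50) — with a per-class probability (non-expressed TEs 0.9,
expressed TEs 0.1, Class A 0.05, orphans ~0.5, background CpGs mix per
site at 0.25). Sites draw a latent frequency from their component; each
strand reports a binomial realization at Poisson(20)+1 coverage. The
component assignment is the truth for classification-accuracy checks.

**Small RNA.** Producing loci come from young TE copies (planted K below
0.10, probability 0.6 per copy), 25 expressed genes, 100 unannotated
windows, and 8 mitochondrial windows. All unannotated loci are planted
within 60 bp of a TE copy, mirroring the strong TE adjacency of intergenic
sRNA production that the analysis is designed to detect; at the ~15% TE
coverage of the default genome a uniformly placed locus sits a median
~900 bp from the nearest TE, so the planted signal is unambiguous. Read
lengths follow a 24-nt-peaked categorical distribution (20–27 nt), first
nucleotides draw from U 0.5 / A 0.3 / C 0.1 / G 0.1, and each locus has a
0.9 majority-strand share. 30% of non-mitochondrial loci are planted
enriched (×4 in the oxidized and/or TraPR libraries, with overlap giving
dual-enriched loci), 10% depleted (×1/4); mitochondrial loci are abundant
in the untreated library (×8 base rate) and scaled to 0.05 in both treated
libraries. Reads are emitted as collapsed forms with counts; sequences are
synthesized from the first-nucleotide table plus random tails and are not
substrings of the genome (nothing downstream aligns them). A replicate
count matrix (3 libraries × 3 replicates, Poisson around the library
rates) supports the enrichment test.

**Expression.** Negative-binomial counts (dispersion 0.1) over five
conditions (0 h, 24 h mock/exudate, 48 h mock/exudate) × four replicates.
Expressed features draw log-normal means around 150; silent genes/TE loci
draw means 0.1/0.05 so the published filters separate the planted sets
essentially perfectly. Planted subfamily log2 fold changes (defaults:
MULE1 +2, Gypsy1 −2) apply in every non-control condition.

## Divergence estimation

Only columns with unambiguous A/C/G/T on both rows are counted; gaps and
ambiguity codes are skipped. CpG context is read on the gap-stripped
consensus (a C immediately followed by G; both positions of the
dinucleotide count as context). With CpG adjustment on (the default),
transitions at context columns carry weight 1/10 — the RepeatMasker
convention — so the adjusted K never exceeds the unadjusted K. Saturation
((1−2P−Q) ≤ 0 or (1−2Q) ≤ 0) and empty alignments raise typed errors
rather than returning sentinels. Landscape bins are floor(100·K) clamped
to [0, 50]; clamped copies are counted in the frame's metadata. Coverage
sums per-copy lengths, so overlapping annotations (not produced by the
generator) would be double-counted.

## Methylome scoring

Strand merging keys each CpG on its plus-strand C and combines the two
strand records by coverage-weighted mean (total methylated-read mass is
conserved exactly); duplicate same-strand records are an input error.
Locus scores are the median site frequency over the 0-based half-open
interval — sites at the interval end are excluded — matching a
`bedtools map -median` workflow; a locus with no covered CpG is undefined
and excluded downstream, never treated as 0. Site bimodality uses strict
inequalities (> 0.8, < 0.2). The gene high/low methylation cut defaults to
mCG > 0.5 and is exposed as a parameter, since the figure-level outcome it
feeds (fraction of highly methylated genes) depends on it. Metagene
profiles use fixed 100-bp flank bins over 2-kb flanks and 50 scaled body
bins, with minus-strand loci mirrored so bin order always reads 5′→3′.

## Gene classification

Rules apply in fixed precedence: the 17-token transposon blocklist
(case-insensitive substring over free-text domain tokens — robust to
annotation variants, and auditable because the list is a module constant),
then crinkler, then the five Class C families in declaration order, then
Class B (no domain; HCN iff repeat overlap), remainder Class A. A gene
carrying both crinkler and Class C tokens goes to crinkler by default
(configurable to raise instead); conflicts are counted in the output
metadata. No numeric copy-number cutoff is invented for "high copy
number": repeat overlap alone decides, as the written rule states.
Intergenic distances are gaps between adjacent gene bounds per chromosome
(0 on overlap, undefined at chromosome ends), with 5′/3′ orientation
following gene strand.

## Proximity tests

Distance is edge-to-edge between half-open intervals, strand-agnostic,
0 on any overlap; ties go to the leftmost TE start, then the smallest copy
id. Genes on TE-free chromosomes are excluded from tests with a count.
Transposon-related genes are excluded from all proximity tests (they are
themselves TE-derived). Kruskal–Wallis H uses mid-ranks with tie
correction and the chi-square approximation; all-identical input returns
H = 0, p = 1. Fisher's exact test is two-sided by hypergeometric tail
summation; odds ratios use a Haldane +0.5 correction when a cell is zero.
Dunn's post hoc z-tests run on pooled ranks with the standard tie term;
BH adjustment is applied within each panel's family of comparisons, not
globally, matching per-panel reporting.

## Small-RNA analysis

Locus calling pools all libraries, merges reads whose intervals are within
200 bp (pad) into islands, and drops islands below 10 reads-per-million-
mapped of the pooled total. Strandedness (majority share ≥ 0.8) and the
dicer call (count-weighted modal read length in [20, 27]) follow the
published parameter set. Secondary-structure (fold-size) analysis of the
published clusterer is deliberately not implemented — RNA folding is out
of scope — so locus calls can differ from that tool's output on real data.

Enrichment uses the moderated differential test on per-locus replicate
counts for oxidized-vs-untreated and TraPR-vs-untreated; a locus is
enriched when log2FC > 0 at FDR < 0.05, depleted when log2FC < 0 at FDR
< 0.05 in either treatment. The retained set removes depleted loci only;
a stricter flag additionally removes loci enriched by neither treatment.
Origin assignment is hierarchical — any ≥ 1 bp TE overlap wins (split by
the TE's expression flag; conflicting overlaps resolved by larger overlap,
exact ties to the expressed copy), then expressed-gene overlap, else
unannotated — and overlaps with non-expressed genes fall through to
unannotated with a logged count.

The shuffle null re-places each locus uniformly at random: chromosome
drawn proportional to length, start uniform so the locus fits, length
preserved; shuffled loci may overlap annotations and each other, and one
shuffled set of equal size is drawn by default. Observed and shuffled
nearest-TE distance distributions are compared per origin class
(unannotated and genic separately) with the Kruskal–Wallis test. Type-I
error of this construction is calibrated at ~5% over 500 null simulations
in the acceptance suite.

## Expression analysis

Size factors are median-of-ratios over features positive in every sample.
Note the exact algebra: scaling one of m samples by k scales its factor by
k^(1−1/m) (the geometric-mean reference moves too) and rescales the
normalized matrix by a single global constant k^(1/m) — relative structure
is preserved, which is what downstream tests consume. "≥ 100 normalized
counts" for subfamilies is read per-sample in at least one sample; the
summed-across-samples reading is available behind a flag. The TE-locus
filter is strict at 100 bp (a 100-bp locus is excluded). The differential
test is an explicit simplification of a negative-binomial fit: a moderated
t on log2(normalized + 1), with per-feature pooled variances shrunk toward
an empirical-Bayes scaled-inverse-chi-square prior fitted by method of
moments on log variances (complete shrinkage when observed spread is
within sampling noise). At the study design (4 vs 4, dispersion 0.1) this
reaches ≥ 90% power at |log2FC| = 2 on a 20-feature panel while the null
keeps an empty significant set in ≥ 95% of simulated designs. Externally
computed differential tables can be supplied instead via TSV.

## What passing tests do and do not show

The generator plants exactly the structures the analyses claim to detect,
with effect sizes chosen as a realistic-strong regime where the published
effects are qualitative (the sources give no quantitative effect sizes for
"young TEs produce more sRNA" or for TE-adjacency of intergenic loci).
Passing therefore demonstrates correctness of the estimators, thresholds
and permutation machinery — not that real data would show these effects,
nor their magnitudes. Features of real data not emulated: sequencing
error, mapping ambiguity in repeats, indels in TE copies (alignments are
substitution-only and gap handling is exercised separately), CHG/CHH
methylation, isochore structure, and library-preparation biases beyond
per-library scaling. The genic sRNA TE-adjacency signal is not planted
(genes are placed by the genome layout), so the genic shuffle test is
reported but not asserted.

## Problem sizes and determinism

Default problem sizes — 2-Mb genome, 500 copies, 800 genes, ~100k sRNA
reads, 20-sample design — were chosen so a full run completes in seconds
while every statistic retains clear power at its planted effect. All
randomness flows through explicit numpy Generators; each pipeline stage
derives its generator from the study seed plus a fixed offset, so stages
are individually and jointly byte-reproducible, and re-running from the
echoed config reproduces outputs exactly.
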