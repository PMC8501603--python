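# Methods

## The mappability statistic

For every transcript sequence (the spliced exon sequence, reverse-complemented
for minus-strand models) of length ℓ, reads of window length L are generated
at offsets 0, 1, 2, … (stride `step`, default 1), giving n = ℓ − L + 1 reads;
a transcript shorter than L contributes a single full-length read and is
flagged `short` rather than skipped, so every transcript is scored. Each read
is located in the whole transcriptome; a read found at N ≥ 1 distinct
(transcript, offset) locations contributes 1/N to each location. A
transcript's recovery mass m is the mass its own reads deposit back inside
it, and its mappability is m/n ∈ (0, 1]. The anchors are analytic: a sequence
with a single verbatim copy elsewhere scores exactly 1/2, c verbatim copies
score 1/(c + 1), and a globally unique sequence scores 1.

At gene level, reads from all isoforms of a gene are pooled
(n_gene = Σ n_t) and mass landing anywhere inside the gene counts toward
m_gene, so multi-mapping between isoforms of the same gene — shared exons —
is recovered. Gene mappability therefore always dominates the pooled
transcript score.

Window lengths 50, 100 and 150 are the conventional short-read lengths; the
default is 100. Stride 1 is the densest deterministic choice and makes n a
pure function of length.

**Exact search instead of an aligner.** Every generated window is an exact
substring of the transcriptome, so the complete multi-map set is well defined
without alignment heuristics: an exact-substring location index (hash of all
L-mers, plus the lengths of sub-window transcripts) answers each query
completely. Reads containing N are generated (they count in n) but never
match, so a transcript consisting entirely of Ns is reported with m = 0 and
flagged. A brute-force scanner with the same contract serves as the testing
oracle, and an adapter accepts externally aligned reads (SAM, query names
`tx:offset`) for users who prefer an aligner's notion of the multi-map set.

**Crediting rule.** When a read occurs several times inside one transcript
(a tandem repeat), each occurrence is a distinct location and each
contributes its 1/N to that transcript. The alternative — at most one 1/N
per read per transcript — is available as `per_read_max_one`. Searching the
reverse complement is off by default (the transcriptome is stranded) and
available as a flag.

**Conservation ledger.** The mappability numerator m is own-read recovery,
so Σ m over transcripts is *less* than the mapped-read count whenever mass
leaks across entities (that leak is exactly what the statistic measures).
The `assigned` column carries the complementary ledger — total 1/N mass
deposited into each entity by all reads — and sums exactly to the
mapped-read count; tests assert this identity to 1e-9.

## Annotation complexity summary

`summarize_annotation` reports: gene and transcript counts; genomic exon
coverage (bases under at least one exon, strand-insensitive interval union,
divided by the summed lengths of the supplied sequences, Ns included); mean
transcripts per gene; and the mean per-gene percentage of unique exons,
100 × distinct (chrom, start, end, strand) intervals / exon records, where
the denominator sums exon records over the gene's isoforms. Deduplication is
within genes only. Coordinates are 0-based half-open internally and converted
to/from the 1-based inclusive GTF convention only at file boundaries.

## Count simulation

Counts follow the NB2 model per transcript isoform i and replicate j:

    Y_ij(Control) ~ NB(mean = μ_i,     var = μ_i (1 + φ_i μ_i))
    Y_ij(Case)    ~ NB(mean = θ_i μ_i, var = θ_i μ_i (1 + φ_i θ_i μ_i))

with dispersion φ_i ≥ 0 and regulating factor (fold-change) θ_i > 0, θ_i = 1
exactly for non-differentially-expressed transcripts. NB(mean, variance) is
realized as size r = 1/φ and success probability r/(r + mean) — the unique
parameterization with variance μ + φμ² — and φ = 0 degenerates to
Poisson(mean) (the continuous limit, not an error).

The parameter generator draws μ_i log-normally (default meanlog = ln 50,
sdlog = 1.3, spanning roughly three orders of magnitude of abundance as bulk
libraries do), sets φ_i by the decreasing trend φ = 3/μ + 0.05 (dispersion
shrinking with abundance, the shape of fitted dispersion trends; a constant
law is also available), and gives a `de_fraction` share of transcripts
(default 0.3) θ = 2^±lfc with equiprobable sign (default |log2 θ| = 1, the
boundary of the true-DE definition) and the rest θ = 1. Replicates default
to n = 3 per group.

Reads are simulated error-free, single-end, with uniform start positions and
exactly Y_ij reads per (transcript, sample); transcripts shorter than the
read length emit full-length copies. Read ids encode origin and sample, so
alignment can be scored exactly. Sequencing errors, positional/GC bias,
fragment-length models and paired-end layout are deliberately out of scope:
the generator exists to exercise the multi-mapping ambiguity channel, not to
emulate a sequencer.

## Quantification

Reads are aligned by exact substring search (each read's mapped set is the
full set of transcripts containing it). Within each sample, reads collapse
to equivalence classes by mapped set, and abundances come from expectation
maximization: E-step splits each class's count across members in proportion
to current abundances, M-step renormalizes; uniform initialization,
convergence when max |Δα| < 1e-8, capped at 1000 iterations. The EM conserves
mass at every iteration and its log-likelihood is non-decreasing (both
asserted in tests, the optimum cross-checked against a grid-search oracle on
the probability simplex).

CPM scales each count column to 10^6. Log scale is log2(CPM + 1), the prior
chosen so a zero count maps to 0; the identical transform is applied to
estimates and ground truth so rank metrics are unaffected.

## Evaluation

* **Ground-truth filter:** transcripts under 0.25 CPM in *any* ground-truth
  sample are removed before the quantification and DE evaluations ("under"
  is strict: exactly 0.25 survives).
* **Alignment:** TP = reads whose mapped set contains their origin
  transcript, FP = mapped reads without it, FN = unmapped reads;
  recall, precision and their harmonic mean F1. Undefined ratios are
  reported as missing, never 0.
* **Quantification:** Spearman's rho and NRMSE of log2 CPM over kept
  (transcript, sample) pairs. NRMSE normalizes RMSE by the range
  (max − min) of the true values — scale-free and common; a standard
  deviation normalizer is a one-line switch.
* **DE caller:** log2 fold-change is the difference of group means of
  log2 CPM; p-values from Welch's unequal-variance t-test; q-values by
  Benjamini–Hochberg step-up over all transcripts tested after the filter;
  a call requires |log2FC| ≥ 1 and q < 0.05. Zero variance in both groups
  gives p = 1 at equal means and p = 0 otherwise.
* **DE metrics:** ROC AUC of the ranking score (−p-value, ties broken by
  |log2FC|, then midranks) against the true-DE labels (θ ≥ 2 or θ ≤ 1/2,
  i.e. fold-change magnitude ≥ 2 — θ is positive, so "magnitude" refers to
  the fold change, not a literal absolute value); Spearman's rho and NRMSE
  of estimated versus true log2 θ; confusion counts of the call rule.
  Single-class cells yield missing AUC.
* **Grouping:** ids are sorted ascending (ties broken by id, stable) and cut
  at ceil(N/3) and ceil(2N/3) into three equal-sized-as-possible terciles,
  so N = 10 splits 4/3/3. Mappability terciles are computed over the
  post-filter (evaluated) set so cells stay balanced. Quantification facets
  use each (transcript, sample) pair's own true CPM; DE facets use the mean
  true CPM across all ground-truth samples. Cells under 10 members are
  flagged unreliable; empty cells are reported as missing, never zero.

## Synthetic fixtures

The fixture generator lays out non-overlapping multi-exon genes on
i.i.d.-uniform background chromosomes (default 4 × 300 kb, 200 genes, 1–3
isoforms of 3–6 exons of 80–200 bp). Isoform 1 carries the gene's base
exons; each further isoform shares `share_level` of them and receives its
own private exons, so sharing is controlled per gene (the default cycles
through 0, 0.5 and 0.8 for a mix of simple and complex gene models). A
`dup_gene_fraction` (default 0.25) of genes is copied verbatim to a second
locus under a new gene id — the 0.5 mappability anchor. The manifest records
duplication and exon-sharing partners per transcript; a noise model built
from it can redistribute a (1 − mappability) × strength share of counts to
sequence-sharing partners while conserving column totals, for experiments
that corrupt counts without simulating reads.

Identical spec + seed reproduces FASTA/GTF/manifest byte-for-byte. The
background has no repeat families, GC structure or intronic realism; passing
tests therefore demonstrate the machinery's correctness and the direction of
mappability effects, not performance on real genomes.

## Problem sizes and runtime

The default end-to-end benchmark (200 genes → ~500 transcripts after
duplication, ~350 k reads over 6 samples) was chosen so the whole pipeline —
fixture, three mappability passes, simulation, alignment, EM, evaluation —
completes in well under a minute on one core while leaving ~50 transcripts
per tercile × facet cell. One master seed derives per-stage substream seeds
via `numpy.random.SeedSequence`, so every stage is independently
reproducible.

## Known limitations

* Exact substring search defines the multi-map set without mismatches; an
  aligner with mismatch tolerance would report slightly larger N for
  near-duplicate (not verbatim-duplicate) sequences. The SAM adapter exists
  for that comparison.
* Exact alignment of error-free reads is perfect by construction (F1 = 1),
  so the alignment step here is a sanity check, not a discriminating
  benchmark.
* At the default library depth the low-abundance facet is power-limited with
  n = 3 replicates: its AUC ceiling is well below 1 even at high
  mappability, which compresses the low-abundance AUC gain; the largest AUC
  gain can land in the middle-abundance facet, while quantification rho
  shows the expected largest-gain-at-low-abundance pattern clearly. Deeper
  libraries move the AUC pattern toward the rho pattern.
* The EM quantifier has no effective-length correction or bootstrap
  uncertainty; it is a reference implementation for propagating multi-map
  ambiguity, not a replacement for production quantifiers.
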