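# annocomplex

Gene-annotation complexity profiling and its impact on RNA-seq
differential-expression (DE) analysis.

Human gene catalogues (GENCODE, RefSeq, NONCODE, …) keep growing, and genes
with many isoforms sharing exons — or whole loci duplicated elsewhere — make
short RNA-seq reads ambiguous: a read can no longer identify the transcript
it came from. `annocomplex` is for bioinformaticians who want to *measure*
that ambiguity for a given annotation and see how it propagates through each
step of a DE pipeline (alignment → quantification → DE testing), using fully
synthetic ground truth so every error is attributable.

## The statistic

For a transcript sequence S of length ℓ, generate n = ℓ − L + 1 sliding-window
reads of length L (defaults: L ∈ {50, 100, 150}, stride 1). Locate every read
in the whole transcriptome; a read found at N distinct locations contributes
1/N to each. With m the mass that S's own reads deposit back inside S,

    mappability(S) = m / n  ∈ (0, 1]

Mappability 1 means every read identifies S uniquely; a transcript with one
verbatim copy elsewhere scores exactly 1/2, with c copies 1/(c+1). At gene
level, reads of all isoforms are pooled and mass landing anywhere in the gene
counts, so intra-gene exon sharing is recovered.

Ground-truth counts for benchmarking follow the NB2 model per isoform i,
replicate j:

    Y_ij^Control ~ NB(μ_i,    μ_i (1 + φ_i μ_i))
    Y_ij^Case    ~ NB(θ_i μ_i, θ_i μ_i (1 + φ_i θ_i μ_i))

with dispersion φ_i and fold-change θ_i (θ_i = 1 for non-DE transcripts; a
true DE has fold-change magnitude ≥ 2). Error-free origin-tracked reads, an
equivalence-class EM quantifier, and the metric suite (recall/precision/F1;
Spearman's ρ and NRMSE of log2 CPM; ROC AUC of the DE ranking; the
|log2FC| ≥ 1 & FDR < 0.05 call rule; 0.25-CPM ground-truth filter; tercile
grouping by mappability × true abundance) complete the pipeline. See
`docs/methods.md` for the full model and every numerical choice.

## Worked example

```python
from annocomplex import run_demo

demo = run_demo(seed=1)   # 200-gene synthetic fixture, 3 replicates/group
print(f"transcripts: {len(demo.txome)}")
print(f"mean transcript mappability (L=100): {demo.mappability.mean_mappability():.3f}")
r = demo.report
print(f"alignment F1: {r.value('alignment', 'f1'):.3f}")
print(f"quantification Spearman rho (overall): {r.value('quantification', 'spearman_rho'):.3f}")
print(f"DE AUC (overall): {r.value('de', 'auc'):.3f}")
for facet in ("low", "middle", "high"):
    aucs = [r.value("de", "auc", g, facet) for g in ("low", "middle", "high")]
    print(f"AUC, {facet}-abundance facet, mappability low->high: "
          + " -> ".join(f"{a:.3f}" for a in aucs))
```

prints

```
transcripts: 497
mean transcript mappability (L=100): 0.675
alignment F1: 1.000
quantification Spearman rho (overall): 0.859
DE AUC (overall): 0.785
AUC, low-abundance facet, mappability low->high: 0.556 -> 0.656 -> 0.733
AUC, middle-abundance facet, mappability low->high: 0.716 -> 0.782 -> 0.954
AUC, high-abundance facet, mappability low->high: 0.805 -> 0.902 -> 0.991
```

Reading: the fixture deliberately mixes unique genes (mappability 1),
exon-sharing isoforms and duplicated loci (mappability ≤ 0.5). Exact
alignment of error-free reads is perfect (F1 = 1), yet DE performance climbs
steeply with mappability within every abundance band — the damage done by
ambiguous reads happens in the quantification step and propagates to the DE
calls, not in alignment.

The same stages are available from the shell:

```sh
annocomplex synth --n-genes 200 --seed 1 -o fixtures/
annocomplex mappability --gtf fixtures/annotation.gtf --genome fixtures/genome.fa -L 100 -o map.tsv
annocomplex stats --gtf fixtures/annotation.gtf --genome fixtures/genome.fa -o summary.tsv
annocomplex filter --gtf fixtures/annotation.gtf --min-mappability 0.9 --mappability-tsv map.tsv -o tailored.gtf
annocomplex demo --seed 1 -o demo_out/
```

`filter` implements annotation tailoring: dropping transcripts by
mappability, abundance (CPM), biotype or source class (e.g. keeping only
`BestRefSeq`/`Curated Genomic` records of a RefSeq GFF3) to reduce
complexity before analysis.

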