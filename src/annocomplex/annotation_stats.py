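"""Annotation complexity statistics.

Summarizes an annotation by the descriptors that differ most between human
gene catalogues: gene/transcript counts, the fraction of the genome covered
by exons, mean isoforms per gene, and the mean per-gene percentage of unique
exons (distinct exon intervals over exon records) — the latter dropping as
isoforms of a gene share more exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .annotation_model import Annotation, GeneModel

__all__ = ["AnnotationSummary", "summarize_annotation", "pct_unique_exons"]


@dataclass(frozen=True)
class AnnotationSummary:
    n_genes: int
    n_transcripts: int
    exon_genomic_coverage: float  # fraction of genome bases under >=1 exon
    avg_tx_per_gene: float
    avg_pct_unique_exons: float  # mean over genes, in percent

    def as_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_transcripts": self.n_transcripts,
            "exon_genomic_coverage": self.exon_genomic_coverage,
            "avg_tx_per_gene": self.avg_tx_per_gene,
            "avg_pct_unique_exons": self.avg_pct_unique_exons,
        }


def pct_unique_exons(gene: GeneModel) -> float:
    """Percent of a gene's exon records that are distinct intervals.

    100 x |distinct (chrom, start, end, strand) intervals across the gene's
    transcripts| / (total exon records).  A single-transcript gene scores
    100; two identical single-exon isoforms score 50.
    """
    records = [
        (e.chrom, e.start, e.end, e.strand)
        for tx in gene.transcripts
        for e in tx.exons
    ]
    return 100.0 * len(set(records)) / len(records)


def _merged_exon_bases(ann: Annotation) -> dict[str, int]:
    """Bases covered by >=1 exon per chromosome (strand-insensitive union)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for tx in ann.transcripts():
        for e in tx.exons:
            by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
    covered: dict[str, int] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        total = 0
        cur_start, cur_end = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total += cur_end - cur_start
        covered[chrom] = total
    return covered


def summarize_annotation(
    ann: Annotation, genome_lengths: Mapping[str, int]
) -> AnnotationSummary:
    """Compute the complexity summary for an annotation.

    ``genome_lengths`` maps every chromosome used by the annotation to its
    sequence length; coverage is the exon-union base count divided by the sum
    of all supplied lengths.
    """
    covered = _merged_exon_bases(ann)
    missing = sorted(set(covered) - set(genome_lengths))
    if missing:
        raise KeyError(f"no genome length supplied for chromosome(s): {missing}")
    genome_total = sum(genome_lengths.values())
    n_genes = ann.n_genes
    n_tx = ann.n_transcripts
    return AnnotationSummary(
        n_genes=n_genes,
        n_transcripts=n_tx,
        exon_genomic_coverage=(sum(covered.values()) / genome_total if genome_total else 0.0),
        avg_tx_per_gene=(n_tx / n_genes if n_genes else 0.0),
        avg_pct_unique_exons=(
            sum(pct_unique_exons(g) for g in ann.genes.values()) / n_genes
            if n_genes
            else 0.0
        ),
    )
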