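"""Gene-model containers and GTF/GFF3/FASTA ingestion.

The in-memory model is a three-level hierarchy ``Annotation`` -> ``GeneModel``
-> ``TranscriptModel`` -> ``Exon``.  Coordinates are stored 0-based half-open
internally; the GTF convention (1-based, inclusive) applies only at file
boundaries, so conversions happen exactly once on read and once on write.

A ``Transcriptome`` is the set of spliced transcript sequences implied by an
annotation plus a genome: exon subsequences concatenated in genomic order,
reverse-complemented for minus-strand transcripts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "Exon",
    "TranscriptModel",
    "GeneModel",
    "Annotation",
    "Transcriptome",
    "GtfParseError",
    "AnnotationValidationError",
    "CoordinateError",
    "parse_gtf",
    "parse_gff3",
    "extract_transcript_sequences",
    "filter_annotation",
    "write_gtf",
    "reverse_complement",
    "classify_biotype",
]


class GtfParseError(ValueError):
    """Malformed GTF/GFF3 content; message carries the offending line number."""


class AnnotationValidationError(ValueError):
    """A gene model violates a structural invariant."""


class CoordinateError(ValueError):
    """An exon lies outside its chromosome sequence."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: biotype labels collapsed into the three-way mRNA / lncRNA / other grouping
_MRNA_BIOTYPES = {"protein_coding", "mRNA"}
_LNCRNA_BIOTYPES = {"lncRNA", "lnc_RNA", "lincRNA", "antisense", "lncrna"}


def classify_biotype(raw: str | None) -> str:
    """Collapse a raw biotype label into ``{mRNA, lncRNA, other}``."""
    if raw is None:
        return "other"
    if raw in _MRNA_BIOTYPES:
        return "mRNA"
    if raw in _LNCRNA_BIOTYPES:
        return "lncRNA"
    return "other"


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon interval, 0-based half-open, on a stranded chromosome."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationValidationError(
                f"invalid exon interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """An isoform: an ordered chain of exons sharing chromosome and strand."""

    transcript_id: str
    gene_id: str
    exons: list[Exon]
    biotype: str = "other"
    source_class: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} mixes chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise AnnotationValidationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationValidationError(f"gene {self.gene_id} has no transcripts")
        bad = [t.transcript_id for t in self.transcripts if t.gene_id != self.gene_id]
        if bad:
            raise AnnotationValidationError(
                f"gene {self.gene_id} contains transcripts of another gene: {bad}"
            )


@dataclass
class Annotation:
    """A keyed collection of gene models with unique gene and transcript ids."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene in self.genes.values():
            for tx in gene.transcripts:
                if tx.transcript_id in seen:
                    raise AnnotationValidationError(
                        f"duplicate transcript_id {tx.transcript_id}"
                    )
                seen.add(tx.transcript_id)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts()]

    def tx2gene(self) -> dict[str, str]:
        return {t.transcript_id: t.gene_id for t in self.transcripts()}


@dataclass
class Transcriptome:
    """Spliced transcript sequences plus the transcript -> gene mapping."""

    sequences: dict[str, str]
    tx2gene: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.sequences) - set(self.tx2gene)
        if missing:
            raise AnnotationValidationError(
                f"transcripts without a gene assignment: {sorted(missing)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for tx_id, seq in self.sequences.items():
                fh.write(f">{tx_id} gene={self.tx2gene[tx_id]}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path, tx2gene: Mapping[str, str] | None = None) -> "Transcriptome":
        sequences: dict[str, str] = {}
        genes: dict[str, str] = {}
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, read_long_names=True)
        for long_name in fa.keys():
            tx_id = long_name.split()[0]
            sequences[tx_id] = str(fa[long_name][:])
            m = re.search(r"gene=(\S+)", long_name)
            genes[tx_id] = m.group(1) if m else tx_id
        if tx2gene is not None:
            genes = {t: tx2gene[t] for t in sequences}
        return cls(sequences=sequences, tx2gene=genes)


_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')

# attribute keys probed, in order, for a raw biotype label
_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type")


def _assemble(
    records: dict[str, dict],
    provenance: str,
) -> Annotation:
    """Build an Annotation from per-transcript exon records (dedup + sort)."""
    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, rec in records.items():
        exons = sorted(set(rec["exons"]), key=lambda e: e.start)
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=rec["gene_id"],
            exons=exons,
            biotype=classify_biotype(rec.get("biotype")),
            source_class=rec.get("source_class", ""),
        )
        genes.setdefault(tx.gene_id, []).append(tx)
    return Annotation(
        genes={gid: GeneModel(gene_id=gid, transcripts=txs) for gid, txs in genes.items()},
        provenance=provenance,
    )


def parse_gtf(path: str | Path) -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    Only ``exon`` feature lines are used; gene and transcript structure is
    assembled from their ``gene_id``/``transcript_id`` attributes.  Duplicate
    exon lines for a transcript are deduplicated by coordinates.

    Raises
    ------
    GtfParseError
        On a line that is not 9-field GTF or whose attributes lack
        ``gene_id``/``transcript_id`` (the message names the line number).
    AnnotationValidationError
        On an exon with start > end.
    """
    records: dict[str, dict] = {}
    n_exon_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            n_exon_lines += 1
            attrs = dict(_GTF_ATTR_RE.findall(attr_s))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start1 > end1:
                raise AnnotationValidationError(
                    f"{path}: line {lineno}: exon start {start1} > end {end1}"
                )
            exon = Exon(chrom=chrom, start=start1 - 1, end=end1, strand=strand)
            rec = records.setdefault(
                attrs["transcript_id"],
                {"gene_id": attrs["gene_id"], "exons": [], "source_class": source if source != "." else ""},
            )
            rec["exons"].append(exon)
            if "biotype" not in rec:
                for key in _BIOTYPE_KEYS:
                    if key in attrs:
                        rec["biotype"] = attrs[key]
                        break
    if n_exon_lines == 0:
        logger.warning("%s: no exon features found; annotation is empty", path)
    return _assemble(records, provenance=f"GTF:{path}")


def _gff3_attrs(attr_s: str) -> dict[str, str]:
    out = {}
    for part in attr_s.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(path: str | Path) -> Annotation:
    """Minimal GFF3 reader for RefSeq-style annotations.

    Any feature carrying an ``ID`` that has ``exon`` children is treated as a
    transcript; its gene is resolved through the ``Parent`` chain (falling
    back to the transcript's own ID for parentless features).  The GFF3
    *source* column (e.g. ``BestRefSeq``, ``Curated Genomic``) becomes the
    transcript's ``source_class``.
    """
    feature_parent: dict[str, str] = {}
    feature_type: dict[str, str] = {}
    feature_source: dict[str, str] = {}
    exon_rows: list[tuple[int, str, Exon]] = []  # (lineno, parent_id, exon)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            attrs = _gff3_attrs(attr_s)
            if ftype == "exon":
                if "Parent" not in attrs:
                    raise GtfParseError(f"{path}: line {lineno}: exon lacks Parent attribute")
                start1, end1 = int(start_s), int(end_s)
                if start1 > end1:
                    raise AnnotationValidationError(
                        f"{path}: line {lineno}: exon start {start1} > end {end1}"
                    )
                exon = Exon(chrom=chrom, start=start1 - 1, end=end1, strand=strand)
                for parent in attrs["Parent"].split(","):
                    exon_rows.append((lineno, parent, exon))
            elif "ID" in attrs:
                fid = attrs["ID"]
                feature_type[fid] = ftype
                feature_source[fid] = source
                if "Parent" in attrs:
                    feature_parent[fid] = attrs["Parent"].split(",")[0]

    def gene_of(tx_id: str) -> str:
        cur = tx_id
        while cur in feature_parent:
            parent = feature_parent[cur]
            if feature_type.get(parent) == "gene":
                return parent
            cur = parent
        return feature_parent.get(tx_id, tx_id)

    records: dict[str, dict] = {}
    for _lineno, parent, exon in exon_rows:
        rec = records.setdefault(
            parent,
            {
                "gene_id": gene_of(parent),
                "exons": [],
                "source_class": feature_source.get(parent, ""),
                "biotype": feature_type.get(parent),
            },
        )
        rec["exons"].append(exon)
    if not records:
        logger.warning("%s: no exon features found; annotation is empty", path)
    return _assemble(records, provenance=f"GFF3:{path}")


def extract_transcript_sequences(
    ann: Annotation, genome: str | Path | Mapping[str, str]
) -> Transcriptome:
    """Extract spliced, uppercase transcript sequences from a genome FASTA.

    Exon subsequences are concatenated in ascending genomic order;
    minus-strand transcripts are reverse-complemented afterwards, so the
    result reads 5'->3' in transcript orientation.

    ``genome`` may be a FASTA path (random access via pyfaidx) or an
    in-memory ``{chrom: sequence}`` mapping.
    """
    if isinstance(genome, (str, Path)):
        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        get = lambda chrom: fa[chrom]  # noqa: E731
        length_of = lambda chrom: len(fa[chrom])  # noqa: E731
        chroms = set(fa.keys())
    else:
        get = lambda chrom: genome[chrom]  # noqa: E731
        length_of = lambda chrom: len(genome[chrom])  # noqa: E731
        chroms = set(genome)

    sequences: dict[str, str] = {}
    tx2gene: dict[str, str] = {}
    for tx in ann.transcripts():
        if tx.chrom not in chroms:
            raise CoordinateError(
                f"transcript {tx.transcript_id}: chromosome {tx.chrom} absent from genome"
            )
        chrom_len = length_of(tx.chrom)
        parts = []
        for exon in tx.exons:
            if exon.end > chrom_len:
                raise CoordinateError(
                    f"transcript {tx.transcript_id}: exon [{exon.start}, {exon.end}) "
                    f"exceeds {tx.chrom} length {chrom_len}"
                )
            parts.append(str(get(tx.chrom)[exon.start : exon.end]).upper())
        seq = "".join(parts)
        if tx.strand == "-":
            seq = reverse_complement(seq)
        sequences[tx.transcript_id] = seq
        tx2gene[tx.transcript_id] = tx.gene_id
    return Transcriptome(sequences=sequences, tx2gene=tx2gene)


def filter_annotation(
    ann: Annotation,
    *,
    min_mappability: float | None = None,
    mappability: "Mapping[str, float] | None" = None,
    min_abundance_cpm: float | None = None,
    counts=None,
    biotypes: Iterable[str] | None = None,
    source_classes: Iterable[str] | None = None,
) -> Annotation:
    """Return a new annotation keeping transcripts that pass every active criterion.

    Criteria
    --------
    min_mappability
        Keep transcripts with mappability >= threshold; requires
        ``mappability`` (a transcript_id -> score mapping, e.g.
        ``MappabilityResult.mappability_series()``).
    min_abundance_cpm
        Keep transcripts whose CPM is >= threshold in *every* sample of
        ``counts`` (a transcripts x samples DataFrame of raw counts).
    biotypes / source_classes
        Keep transcripts whose label is in the given set.

    Genes left without transcripts are dropped.  Input objects are never
    modified.  The operation is idempotent for a fixed predicate.
    """
    biotypes = set(biotypes) if biotypes is not None else None
    source_classes = set(source_classes) if source_classes is not None else None

    tx_ids = ann.transcript_ids()
    if min_mappability is not None:
        if mappability is None:
            raise ValueError("min_mappability requires a mappability table")
        missing = [t for t in tx_ids if t not in mappability]
        if missing:
            raise KeyError(f"transcripts missing from mappability table: {missing[:10]}")
    cpm = None
    if min_abundance_cpm is not None:
        if counts is None:
            raise ValueError("min_abundance_cpm requires a count matrix")
        missing = [t for t in tx_ids if t not in counts.index]
        if missing:
            raise KeyError(f"transcripts missing from count matrix: {missing[:10]}")
        totals = counts.sum(axis=0)
        cpm = counts / totals * 1e6

    def keep(tx: TranscriptModel) -> bool:
        if biotypes is not None and tx.biotype not in biotypes:
            return False
        if source_classes is not None and tx.source_class not in source_classes:
            return False
        if min_mappability is not None and mappability[tx.transcript_id] < min_mappability:
            return False
        if cpm is not None and not bool((cpm.loc[tx.transcript_id] >= min_abundance_cpm).all()):
            return False
        return True

    genes: dict[str, GeneModel] = {}
    for gid, gene in ann.genes.items():
        kept = [replace(t, exons=list(t.exons)) for t in gene.transcripts if keep(t)]
        if kept:
            genes[gid] = GeneModel(gene_id=gid, transcripts=kept)
    return Annotation(genes=genes, provenance=ann.provenance + " | filtered")


def write_gtf(ann: Annotation, path: str | Path) -> None:
    """Write exon-level GTF; round-trips coordinates, strands, ids and biotype."""
    with open(path, "w") as fh:
        fh.write(f"# annocomplex GTF export | {ann.provenance}\n")
        for gene in ann.genes.values():
            for tx in gene.transcripts:
                source = tx.source_class or "annocomplex"
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'transcript_biotype "{tx.biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                source,
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
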