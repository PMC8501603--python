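"""Synthetic genomes and annotations with controlled sequence sharing.

The generator lays out multi-exon genes on i.i.d.-uniform background
chromosomes and controls the two complexity axes that drive transcriptome
mappability in real annotations:

* ``share_level`` — the fraction of a gene's exons shared between its
  isoforms (shared exons create intra-gene multi-mapping, which gene-level
  mappability recovers but transcript-level does not);
* ``dup_gene_fraction`` — a fraction of genes copied verbatim to a second
  locus under a new gene id, giving their transcripts an analytically known
  mappability of exactly 0.5 (1/(c+1) for c extra copies).

Random background makes unannotated k-mer collisions vanishingly unlikely at
the default lengths, so un-shared, un-duplicated transcripts score 1 — the
generator's two anchors bracket the statistic without any aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_model import (
    Annotation,
    Exon,
    GeneModel,
    TranscriptModel,
    write_gtf,
)
from .mappability import MappabilityResult

__all__ = ["FixtureSpec", "FixtureResult", "make_fixture", "make_noise_model"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic genome + annotation fixture.

    Ranges are inclusive ``(lo, hi)`` bounds for per-gene/per-exon uniform
    draws.  ``share_level`` may be a single fraction or a tuple cycled over
    genes (mixed complexity); ``n_fraction`` optionally injects Ns into the
    background for edge-case tests.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 300_000
    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (40, 120)
    share_level: float | tuple[float, ...] = (0.0, 0.5, 0.8)
    dup_gene_fraction: float = 0.25
    intergenic_gap: int = 200
    n_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.dup_gene_fraction <= 1:
            raise ValueError("dup_gene_fraction must lie in [0, 1]")
        shares = self.share_level if isinstance(self.share_level, tuple) else (self.share_level,)
        if any(not 0 <= s <= 1 for s in shares):
            raise ValueError("share_level fractions must lie in [0, 1]")
        if self.chrom_length <= 0 or self.exon_length[0] <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class FixtureResult:
    genome: dict[str, str]
    annotation: Annotation
    manifest: pd.DataFrame  # per transcript: duplication and sharing bookkeeping
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "manifest": outdir / "manifest.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_gtf(self.annotation, paths["annotation"])
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        return paths


def _share_of(spec: FixtureSpec, gene_index: int) -> float:
    if isinstance(spec.share_level, tuple):
        return spec.share_level[gene_index % len(spec.share_level)]
    return spec.share_level


def make_fixture(spec: FixtureSpec) -> FixtureResult:
    """Build a deterministic genome/annotation/manifest triple from a spec.

    Raises ``ValueError`` when the requested genes do not fit the genome.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i+1}" for i in range(spec.n_chroms)]
    chroms: dict[str, bytearray] = {}
    for name in chrom_names:
        codes = rng.integers(0, 4, size=spec.chrom_length)
        arr = _BASES[codes]
        if spec.n_fraction > 0:
            mask = rng.random(spec.chrom_length) < spec.n_fraction
            arr = arr.copy()
            arr[mask] = ord("N")
        chroms[name] = bytearray(arr.tobytes())

    cursors = {name: 0 for name in chrom_names}

    def allocate(span: int) -> tuple[str, int]:
        for name in chrom_names:
            if cursors[name] + span + spec.intergenic_gap <= spec.chrom_length:
                start = cursors[name]
                cursors[name] = start + span + spec.intergenic_gap
                return name, start
        raise ValueError(
            f"genome too short: cannot place a {span}-bp gene "
            f"({spec.n_chroms} x {spec.chrom_length} bp, {spec.n_genes} genes requested)"
        )

    genes: dict[str, GeneModel] = {}
    manifest_rows: list[dict] = []
    gene_spans: dict[str, tuple[str, int, int]] = {}  # gene_id -> (chrom, start, end)
    gene_tx_slots: dict[str, dict[str, list[int]]] = {}  # gene -> tx -> slot ids

    lo_i, hi_i = spec.isoforms_per_gene
    lo_e, hi_e = spec.exons_per_transcript
    lo_el, hi_el = spec.exon_length
    lo_il, hi_il = spec.intron_length

    for g in range(spec.n_genes):
        gene_id = f"gene_{g+1:04d}"
        share = _share_of(spec, g)
        n_iso = int(rng.integers(lo_i, hi_i + 1))
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        n_shared = round(share * n_ex)
        n_priv = n_ex - n_shared

        # slot layout: base exons plus each extra isoform's private exons,
        # interleaved at random, separated by introns
        slots: list[tuple[str, int]] = [("base", i) for i in range(n_ex)]
        for iso in range(1, n_iso):
            slots += [("priv", iso) for _ in range(n_priv)]
        slots = [slots[i] for i in rng.permutation(len(slots))]
        slot_lengths = rng.integers(lo_el, hi_el + 1, size=len(slots))
        introns = rng.integers(lo_il, hi_il + 1, size=max(len(slots) - 1, 0))
        span = int(slot_lengths.sum() + introns.sum())
        chrom, gstart = allocate(span)
        strand = "+" if rng.random() < 0.5 else "-"

        slot_coords: list[tuple[int, int]] = []
        pos = gstart
        for si, sl in enumerate(slot_lengths):
            slot_coords.append((pos, pos + int(sl)))
            pos += int(sl) + (int(introns[si]) if si < len(introns) else 0)
        gene_spans[gene_id] = (chrom, gstart, pos)

        base_slots = [si for si, (kind, _) in enumerate(slots) if kind == "base"]
        priv_slots: dict[int, list[int]] = {}
        for si, (kind, owner) in enumerate(slots):
            if kind == "priv":
                priv_slots.setdefault(owner, []).append(si)

        transcripts: list[TranscriptModel] = []
        tx_slots: dict[str, list[int]] = {}
        for iso in range(n_iso):
            tx_id = f"{gene_id}.t{iso+1}"
            if iso == 0:
                my_slots = sorted(base_slots)
            else:
                shared = sorted(
                    rng.choice(base_slots, size=n_shared, replace=False).tolist()
                )
                my_slots = sorted(shared + priv_slots.get(iso, []))
            if not my_slots:  # share rounding left an isoform empty: give it one base exon
                my_slots = [base_slots[0]]
            exons = [
                Exon(chrom=chrom, start=slot_coords[si][0], end=slot_coords[si][1], strand=strand)
                for si in my_slots
            ]
            transcripts.append(
                TranscriptModel(transcript_id=tx_id, gene_id=gene_id, exons=exons, biotype="mRNA")
            )
            tx_slots[tx_id] = my_slots
        genes[gene_id] = GeneModel(gene_id=gene_id, transcripts=transcripts)
        gene_tx_slots[gene_id] = tx_slots
        for tx in transcripts:
            manifest_rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "gene_id": gene_id,
                    "n_exons": len(tx.exons),
                    "share_level": share,
                    "is_duplicate": False,
                    "dup_partner": "",
                }
            )

    # duplicated loci: copy the genomic span verbatim under a new gene id
    n_dup = round(spec.dup_gene_fraction * spec.n_genes)
    dup_sources = sorted(
        rng.choice(sorted(gene_spans), size=n_dup, replace=False).tolist()
    )
    for src_gene in dup_sources:
        chrom, start, end = gene_spans[src_gene]
        span = end - start
        tchrom, tstart = allocate(span)
        chroms[tchrom][tstart : tstart + span] = chroms[chrom][start:end]
        offset = tstart - start
        dup_gene = f"{src_gene}_dup"
        dup_txs: list[TranscriptModel] = []
        for tx in genes[src_gene].transcripts:
            dup_txs.append(
                TranscriptModel(
                    transcript_id=f"{tx.transcript_id}_dup",
                    gene_id=dup_gene,
                    exons=[
                        Exon(chrom=tchrom, start=e.start + offset, end=e.end + offset, strand=e.strand)
                        for e in tx.exons
                    ],
                    biotype=tx.biotype,
                )
            )
        genes[dup_gene] = GeneModel(gene_id=dup_gene, transcripts=dup_txs)
        for tx in genes[src_gene].transcripts:
            manifest_rows.append(
                {
                    "transcript_id": f"{tx.transcript_id}_dup",
                    "gene_id": dup_gene,
                    "n_exons": len(tx.exons),
                    "share_level": _share_of(spec, int(src_gene.split("_")[1]) - 1),
                    "is_duplicate": True,
                    "dup_partner": tx.transcript_id,
                }
            )

    manifest = pd.DataFrame(manifest_rows)
    # mark originals with their duplicate as partner (symmetric bookkeeping)
    dup_of = {r["dup_partner"]: r["transcript_id"] for r in manifest_rows if r["is_duplicate"]}
    manifest["dup_partner"] = [
        dup_of.get(t, p) for t, p in zip(manifest["transcript_id"], manifest["dup_partner"])
    ]

    # sequence-sharing partners: same-gene isoforms sharing >=1 exon slot,
    # plus the verbatim duplicate counterpart (and its isoform partners)
    partners: dict[str, set[str]] = {t: set() for t in manifest["transcript_id"]}
    for gene_id, tx_slots in gene_tx_slots.items():
        items = list(tx_slots.items())
        for i, (tx_a, slots_a) in enumerate(items):
            for tx_b, slots_b in items[i + 1 :]:
                if set(slots_a) & set(slots_b):
                    partners[tx_a].add(tx_b)
                    partners[tx_b].add(tx_a)
                    for a, b in ((tx_a, tx_b), (tx_b, tx_a)):
                        if a in dup_of:
                            partners[dup_of[a]].add(dup_of.get(b, b))
    for orig, dup in dup_of.items():
        partners[orig].add(dup)
        partners[dup].add(orig)
        for p in list(partners[orig]):
            if p != dup:
                partners[dup].add(p)
                partners[p].add(dup)
    manifest["partners"] = [
        ";".join(sorted(partners[t])) for t in manifest["transcript_id"]
    ]

    genome = {name: chroms[name].decode("ascii") for name in chrom_names}
    annotation = Annotation(
        genes=genes, provenance=f"synthetic fixture seed={spec.seed} n_genes={spec.n_genes}"
    )
    return FixtureResult(
        genome=genome,
        annotation=annotation,
        manifest=manifest,
        genome_lengths={name: len(seq) for name, seq in genome.items()},
    )


def make_noise_model(
    map_result: MappabilityResult,
    manifest: pd.DataFrame,
    strength: float,
):
    """Build a count-corruption function emulating multi-map misassignment.

    The returned function moves a ``(1 - mappability) * strength`` share of
    each transcript's counts to its sequence-sharing partners (equally),
    within each sample, so column totals are preserved exactly.  Transcripts
    with mappability 1 or no partners are untouched; ``strength = 0`` is the
    identity.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    mapp = map_result.mappability_series()
    partner_lists = {
        row.transcript_id: [p for p in row.partners.split(";") if p]
        for row in manifest.itertuples()
    }

    def corrupt(counts: pd.DataFrame) -> pd.DataFrame:
        ids = list(counts.index)
        pos = {t: i for i, t in enumerate(ids)}
        M = np.eye(len(ids))
        for t in ids:
            plist = [p for p in partner_lists.get(t, []) if p in pos]
            if not plist:
                continue
            leak = (1.0 - float(mapp.get(t, 1.0))) * strength
            if leak <= 0:
                continue
            i = pos[t]
            M[i, i] -= leak
            for p in plist:
                M[pos[p], i] += leak / len(plist)
        return pd.DataFrame(M @ counts.to_numpy(), index=counts.index, columns=counts.columns)

    return corrupt
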