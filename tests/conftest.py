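import numpy as np
import pytest

from annocomplex.annotation_model import (
    Annotation,
    Exon,
    GeneModel,
    TranscriptModel,
    Transcriptome,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def make_txome(sequences: dict[str, str], tx2gene: dict[str, str] | None = None) -> Transcriptome:
    if tx2gene is None:
        tx2gene = {t: f"g_{t}" for t in sequences}
    return Transcriptome(sequences=dict(sequences), tx2gene=tx2gene)


def random_txome(seed: int, n_tx: int = 10, length: tuple[int, int] = (60, 200)) -> Transcriptome:
    """Random transcriptome with deliberate ambiguity: some duplicated and
    some substring-sharing transcripts, so multi-mapping actually occurs."""
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for i in range(n_tx):
        l = int(rng.integers(*length))
        name = f"t{i:02d}"
        r = rng.random()
        prev = list(seqs.values())
        if prev and r < 0.25:  # exact duplicate of an earlier transcript
            seqs[name] = prev[int(rng.integers(len(prev)))]
        elif prev and r < 0.5:  # shares a chunk with an earlier transcript
            donor = prev[int(rng.integers(len(prev)))]
            k = min(len(donor), max(30, l // 2))
            start = int(rng.integers(0, len(donor) - k + 1))
            seqs[name] = donor[start : start + k] + random_seq(rng, max(l - k, 5))
        else:
            seqs[name] = random_seq(rng, l)
    return make_txome(seqs)


def simple_annotation(exon_sets: dict[str, dict[str, list[tuple[str, int, int, str]]]]) -> Annotation:
    """Build an Annotation from {gene: {tx: [(chrom, start0, end0, strand), ...]}}."""
    genes = {}
    for gid, txs in exon_sets.items():
        models = [
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                exons=[Exon(chrom=c, start=s, end=e, strand=st) for c, s, e, st in exons],
            )
            for tid, exons in txs.items()
        ]
        genes[gid] = GeneModel(gene_id=gid, transcripts=models)
    return Annotation(genes=genes)


@pytest.fixture
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(7)
    return {"chr1": random_seq(rng, 60), "chr2": random_seq(rng, 20)}


@pytest.fixture
def toy_genome_fasta(tmp_path, toy_genome):
    path = tmp_path / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in toy_genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 30):
                fh.write(seq[i : i + 30] + "\n")
    return path
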