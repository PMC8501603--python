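"""Transcriptome mappability: the m/n sliding-window uniqueness statistic.

For each transcript of length l, reads of window length L are taken at every
``step`` offsets (n = floor((l-L)/step)+1 reads; a transcript shorter than L
emits one full-length read).  Every read is located exactly in the whole
transcriptome; a read found at N distinct locations contributes 1/N to each.
A transcript's m is the mass its own reads deposit back inside it, and its
mappability is m/n in (0, 1]: 1 means every read identifies the transcript
uniquely, 0.5 is the signature of a perfect two-copy duplication.

At gene level, locations inside *any* isoform of the origin gene count
toward m, so intra-gene multi-mapping (shared exons) is recovered and the
gene score is always at least the pooled transcript score.

Exact substring search replaces a read aligner here: every generated window
is an exact substring of the transcriptome, so the complete multi-map set N
is well defined without alignment heuristics.  An adapter for externally
aligned reads (SAM) is provided for users who prefer an aligner's notion
of N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .annotation_model import Transcriptome, reverse_complement

__all__ = [
    "WindowRead",
    "MappabilityResult",
    "LocationIndex",
    "generate_windows",
    "build_location_index",
    "compute_mappability",
    "brute_force_mappability",
    "mappability_from_alignments",
    "read_sam_alignments",
]

DEFAULT_WINDOW_LENGTHS = (50, 100, 150)


@dataclass(frozen=True)
class WindowRead:
    origin_tx: str
    origin_offset: int  # 0-based within the transcript
    length: int


@dataclass
class MappabilityResult:
    """Per-id (n, m, m/n) table at one window length.

    ``scores`` is indexed by transcript or gene id with columns ``n`` (reads
    generated), ``m`` (fractional reads recovered), ``mappability`` (m/n),
    ``assigned`` (total 1/N mass deposited into the entity by *all* reads,
    the conservation ledger: it sums to the mapped-read count) and ``short``
    (True when a transcript shorter than the window contributed).
    """

    level: str  # "transcript" | "gene"
    window_length: int
    scores: pd.DataFrame

    def mappability_series(self) -> pd.Series:
        return self.scores["mappability"]

    def mean_mappability(self) -> float:
        return float(self.scores["mappability"].mean())

    def to_tsv(self, path) -> None:
        out = self.scores.reset_index(names="id")
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def generate_windows(
    txome: Transcriptome, L: int, step: int = 1
) -> Iterator[WindowRead]:
    """Yield sliding-window reads over every transcript.

    A transcript of length l >= L yields reads at offsets 0, step, 2*step, ...
    up to l-L; one shorter than L yields a single read covering it entirely.
    """
    if L <= 0 or step <= 0:
        raise ValueError("window length and step must be positive")
    for tx_id, seq in txome.sequences.items():
        l = len(seq)
        if l < L:
            yield WindowRead(tx_id, 0, l)
        else:
            for off in range(0, l - L + 1, step):
                yield WindowRead(tx_id, off, L)


class LocationIndex:
    """Exact-substring location index over a transcriptome.

    Answers, for a query of length L (or the length of any transcript shorter
    than L), the complete set of (transcript_id, offset) occurrences.
    Substrings containing N are not indexed and queries containing N never
    match.
    """

    def __init__(self, txome: Transcriptome, lengths: set[int]):
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._txome = txome
        for k in lengths:
            table: dict[str, list[tuple[str, int]]] = {}
            for tx_id, seq in txome.sequences.items():
                for i in range(len(seq) - k + 1):
                    sub = seq[i : i + k]
                    if "N" in sub:
                        continue
                    table.setdefault(sub, []).append((tx_id, i))
            self._tables[k] = table

    @classmethod
    def from_transcriptome(cls, txome: Transcriptome, L: int) -> "LocationIndex":
        lengths = {L}
        lengths.update(
            len(s) for s in txome.sequences.values() if 0 < len(s) < L
        )
        return cls(txome, lengths)

    def lookup(self, seq: str) -> list[tuple[str, int]]:
        """All (transcript_id, offset) exact occurrences of ``seq``."""
        table = self._tables.get(len(seq))
        if table is None:
            # fall back to scanning for off-catalogue query lengths
            return [
                (tx_id, i)
                for tx_id, s in self._txome.sequences.items()
                for i in _find_all(s, seq)
            ]
        return table.get(seq, [])


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    if "N" in needle:
        return
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def build_location_index(txome: Transcriptome, L: int) -> LocationIndex:
    return LocationIndex.from_transcriptome(txome, L)


def _aggregate(
    txome: Transcriptome,
    L: int,
    step: int,
    level: str,
    locate_read,
    per_read_max_one: bool,
) -> MappabilityResult:
    """Shared n/m accounting over a read -> locations resolver."""
    if level not in ("transcript", "gene"):
        raise ValueError(f"unknown level {level!r}")
    tx2gene = txome.tx2gene
    n: dict[str, float] = {}
    m: dict[str, float] = {}
    assigned: dict[str, float] = {}
    short: dict[str, bool] = {}
    for read in generate_windows(txome, L, step):
        locs = list(locate_read(read))
        N = len(locs)
        key = read.origin_tx if level == "transcript" else tx2gene[read.origin_tx]
        n[key] = n.get(key, 0.0) + 1.0
        short[key] = short.get(key, False) or (read.length < L)
        if N == 0:
            continue  # read contains N (or external aligner missed it): counts in n only
        for loc in locs:
            owner = loc[0] if level == "transcript" else tx2gene[loc[0]]
            assigned[owner] = assigned.get(owner, 0.0) + 1.0 / N
        if level == "transcript":
            hits = sum(1 for loc in locs if loc[0] == read.origin_tx)
        else:
            gene = tx2gene[read.origin_tx]
            hits = sum(1 for loc in locs if tx2gene[loc[0]] == gene)
        if per_read_max_one:
            hits = min(hits, 1)
        m[key] = m.get(key, 0.0) + hits / N
    ids = list(n)
    df = pd.DataFrame(
        {
            "n": [n[i] for i in ids],
            "m": [m.get(i, 0.0) for i in ids],
            "assigned": [assigned.get(i, 0.0) for i in ids],
            "short": [short[i] for i in ids],
        },
        index=pd.Index(ids, name="id"),
    )
    df["mappability"] = df["m"] / df["n"]
    return MappabilityResult(
        level=level,
        window_length=L,
        scores=df[["n", "m", "mappability", "assigned", "short"]],
    )


def compute_mappability(
    txome: Transcriptome,
    L: int,
    step: int = 1,
    level: str = "transcript",
    search_revcomp: bool = False,
    per_read_max_one: bool = False,
    index: LocationIndex | None = None,
) -> MappabilityResult:
    """Compute m/n mappability via the exact-substring location index.

    Parameters
    ----------
    L, step
        Window length and stride (bases).  The conventional window lengths
        are 50, 100 and 150; stride defaults to 1 so n = l-L+1.
    level
        ``"transcript"`` scores each isoform; ``"gene"`` pools reads of a
        gene's isoforms and credits mass landing anywhere in the gene.
    search_revcomp
        Also count reverse-complement occurrences as mapped locations
        (off by default: the transcriptome is stranded).
    per_read_max_one
        Alternative crediting rule: a read contributes at most one 1/N to
        its origin even when it occurs several times inside it.
    """
    if index is None:
        index = LocationIndex.from_transcriptome(txome, L)

    def locate_read(read: WindowRead) -> list[tuple]:
        seq = txome.sequences[read.origin_tx][
            read.origin_offset : read.origin_offset + read.length
        ]
        locs: list[tuple] = [(t, o, "+") for t, o in index.lookup(seq)]
        if search_revcomp:
            locs += [(t, o, "-") for t, o in index.lookup(reverse_complement(seq))]
        return locs

    return _aggregate(txome, L, step, level, locate_read, per_read_max_one)


def brute_force_mappability(
    txome: Transcriptome,
    L: int,
    step: int = 1,
    level: str = "transcript",
    search_revcomp: bool = False,
    per_read_max_one: bool = False,
) -> MappabilityResult:
    """Oracle implementation: locate every read by scanning every transcript.

    Same contract as :func:`compute_mappability`; quadratic, intended for
    small inputs and cross-checks.
    """

    def locate_read(read: WindowRead) -> list[tuple]:
        seq = txome.sequences[read.origin_tx][
            read.origin_offset : read.origin_offset + read.length
        ]
        locs: list[tuple] = [
            (tx_id, i, "+")
            for tx_id, s in txome.sequences.items()
            for i in _find_all(s, seq)
        ]
        if search_revcomp:
            rc = reverse_complement(seq)
            locs += [
                (tx_id, i, "-")
                for tx_id, s in txome.sequences.items()
                for i in _find_all(s, rc)
            ]
        return locs

    return _aggregate(txome, L, step, level, locate_read, per_read_max_one)


def read_sam_alignments(path) -> dict[str, list[tuple[str, int]]]:
    """Read a SAM file into query_name -> [(reference, 0-based pos)] lists.

    Unmapped records yield empty lists.  Secondary/supplementary alignments
    are included: they are exactly the extra locations N counts.
    """
    import pysam

    out: dict[str, list[tuple[str, int]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            out.setdefault(rec.query_name, [])
            if not rec.is_unmapped:
                out[rec.query_name].append((rec.reference_name, rec.reference_start))
    return out


def mappability_from_alignments(
    txome: Transcriptome,
    L: int,
    alignments: Mapping[str, list[tuple[str, int]]],
    step: int = 1,
    level: str = "transcript",
    per_read_max_one: bool = False,
) -> MappabilityResult:
    """Score mappability from external aligner output instead of the index.

    Query names must encode the read origin as ``tx:offset`` so reads can be
    matched to the windows :func:`generate_windows` would emit.
    """

    def locate_read(read: WindowRead) -> list[tuple]:
        return [
            (t, o, "+")
            for t, o in alignments.get(f"{read.origin_tx}:{read.origin_offset}", [])
        ]

    return _aggregate(txome, L, step, level, locate_read, per_read_max_one)
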