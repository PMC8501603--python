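"""Reference quantification: exact alignment, equivalence-class EM, CPM.

Reads are aligned by exact substring search (every simulated read is an
error-free substring of its origin transcript, so the mapped set is the full
multi-map set).  Within each sample, reads are collapsed to equivalence
classes — groups of reads compatible with an identical transcript set — and
transcript abundances are obtained by expectation maximization: the E-step
splits each class's reads across its transcripts in proportion to current
abundances, the M-step renormalizes.  CPM scales a count column to a million.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_model import Transcriptome
from .mappability import LocationIndex
from .simulate import ReadSet

__all__ = [
    "AlignmentTable",
    "QuantResult",
    "align_reads_exact",
    "em_quantify",
    "quantify_samples",
    "cpm_transform",
    "alignment_table_from_sam",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class AlignmentTable:
    """read_id -> set of transcripts the read maps to (empty = unmapped)."""

    rows: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.rows)

    def n_mapped(self) -> int:
        return sum(1 for s in self.rows.values() if s)


@dataclass
class QuantResult:
    est_counts: pd.DataFrame
    cpm: pd.DataFrame
    log2cpm: pd.DataFrame


def align_reads_exact(
    reads: ReadSet,
    txome: Transcriptome,
    index: LocationIndex | None = None,
    read_length: int | None = None,
) -> AlignmentTable:
    """Map each read to every transcript containing it as an exact substring."""
    if index is None:
        if read_length is None:
            read_length = max((len(s) for _, s in reads.reads), default=1)
        index = LocationIndex.from_transcriptome(txome, read_length)
    rows = {
        rid: frozenset(tx for tx, _off in index.lookup(seq))
        for rid, seq in reads.reads
    }
    return AlignmentTable(rows=rows)


def em_quantify(
    aln: AlignmentTable,
    transcripts: list[str] | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    return_info: bool = False,
):
    """Estimate per-transcript read counts from ambiguous alignments by EM.

    Returns a Series of estimated counts (summing to the number of mapped
    reads).  With ``return_info=True`` also returns a dict with the
    per-iteration total mass and log-likelihood traces and the iteration
    count, for convergence diagnostics.
    """
    classes = Counter(s for s in aln.rows.values() if s)
    if not classes:
        raise ValueError("all reads are unmapped; nothing to quantify")
    if transcripts is None:
        transcripts = sorted(set().union(*classes))
    tx_pos = {t: i for i, t in enumerate(transcripts)}
    n_tx = len(transcripts)
    class_members = [np.array([tx_pos[t] for t in cls], dtype=int) for cls in classes]
    class_counts = np.array(list(classes.values()), dtype=float)
    total = class_counts.sum()

    alpha = np.full(n_tx, 1.0 / n_tx)
    mass_trace: list[float] = []
    ll_trace: list[float] = []
    for it in range(1, max_iter + 1):
        assigned = np.zeros(n_tx)
        ll = 0.0
        for members, k in zip(class_members, class_counts):
            a = alpha[members]
            denom = a.sum()
            if denom <= 0:
                # degenerate class mass; split evenly
                assigned[members] += k / len(members)
                continue
            assigned[members] += k * a / denom
            ll += k * np.log(denom)
        mass_trace.append(float(assigned.sum()))
        ll_trace.append(float(ll))
        new_alpha = assigned / total
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            break
    est = pd.Series(alpha * total, index=pd.Index(transcripts, name="transcript_id"))
    if return_info:
        return est, {"iterations": it, "mass": mass_trace, "loglik": ll_trace}
    return est


def quantify_samples(
    aln: AlignmentTable,
    read_sample: Mapping[str, str],
    transcripts: list[str] | None = None,
    prior_cpm: float = 1.0,
) -> QuantResult:
    """Run EM per sample and assemble est_counts / CPM / log2 CPM matrices.

    ``read_sample`` assigns each read_id to its sample (e.g. the ``sample``
    column of the simulator's origin table).  ``transcripts`` fixes the row
    universe (missing transcripts get 0).
    """
    by_sample: dict[str, dict[str, frozenset[str]]] = {}
    for rid, mapped in aln.rows.items():
        by_sample.setdefault(read_sample[rid], {})[rid] = mapped
    est_cols = {}
    for sample in sorted(by_sample):
        est_cols[sample] = em_quantify(AlignmentTable(by_sample[sample]), transcripts)
    est = pd.DataFrame(est_cols)
    if transcripts is not None:
        est = est.reindex(transcripts).fillna(0.0)
    else:
        est = est.fillna(0.0)
    est.index.name = "transcript_id"
    cpm = cpm_transform(est)
    log2cpm = cpm_transform(est, log2=True, prior=prior_cpm)
    return QuantResult(est_counts=est, cpm=cpm, log2cpm=log2cpm)


def cpm_transform(counts: pd.DataFrame, log2: bool = False, prior: float = 1.0) -> pd.DataFrame:
    """Counts-per-million per column; optionally log2(CPM + prior).

    The prior (in CPM units) is added before the log so zero counts map to
    log2(prior); with the default prior of 1 CPM a zero count gives 0.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    cpm = counts / totals * 1e6
    if log2:
        return np.log2(cpm + prior)
    return cpm


def alignment_table_from_sam(path) -> AlignmentTable:
    """Build an AlignmentTable from a SAM file (query name = read_id)."""
    from .mappability import read_sam_alignments

    alignments = read_sam_alignments(path)
    return AlignmentTable(
        rows={rid: frozenset(t for t, _ in locs) for rid, locs in alignments.items()}
    )
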