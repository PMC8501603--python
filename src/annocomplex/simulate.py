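"""Ground-truth RNA-seq count simulation and origin-tracked read generation.

Counts follow the NB2 model per transcript isoform i and replicate j:

    Y_ij(Control) ~ NB(mean = mu_i,          var = mu_i (1 + phi_i mu_i))
    Y_ij(Case)    ~ NB(mean = theta_i mu_i,  var = theta_i mu_i (1 + phi_i theta_i mu_i))

where phi_i is the dispersion and theta_i the regulating factor (fold-change
of Case over Control; theta_i = 1 for non-DE transcripts).  NB(mean, var) is
parameterized by size r = 1/phi and success probability r/(r + mean); phi = 0
degenerates to Poisson(mean).

Reads are simulated error-free and single-end: exactly Y_ij reads per
(transcript, sample) with uniformly random start positions, each tagged with
its origin so alignment recall/precision can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import Transcriptome

__all__ = [
    "SimulationParams",
    "CountMatrix",
    "ReadSet",
    "draw_counts",
    "make_sim_params",
    "simulate_reads",
]


@dataclass
class SimulationParams:
    """Per-transcript NB parameters plus the replicate count and seed.

    ``table`` is indexed by transcript_id with columns ``mu`` (> 0), ``phi``
    (>= 0) and ``theta`` (> 0; exactly 1 for non-DE transcripts).
    """

    table: pd.DataFrame
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        required = {"mu", "phi", "theta"}
        if not required <= set(self.table.columns):
            raise ValueError(f"params table needs columns {sorted(required)}")
        if (self.table["phi"] < 0).any():
            raise ValueError("dispersion phi must be >= 0")
        if (self.table["mu"] <= 0).any() or (self.table["theta"] <= 0).any():
            raise ValueError("mu and theta must be > 0")

    def to_tsv(self, path) -> None:
        self.table.reset_index(names="transcript_id").to_csv(path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Integer transcripts x samples counts with group labels and theta truth."""

    values: pd.DataFrame
    groups: dict[str, str]  # sample -> "Control" | "Case"
    truth: pd.Series  # transcript -> theta

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.groups):
            raise ValueError("group labels must cover exactly the sample columns")
        if set(self.groups.values()) - {"Control", "Case"}:
            raise ValueError("groups must be Control or Case")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def cpm(self) -> pd.DataFrame:
        totals = self.values.sum(axis=0)
        return self.values / totals * 1e6

    def to_tsv(self, counts_path, sidecar_path=None) -> None:
        self.values.reset_index(names="transcript_id").to_csv(
            counts_path, sep="\t", index=False
        )
        if sidecar_path is not None:
            side = pd.DataFrame(
                {"transcript_id": self.truth.index, "theta": self.truth.values}
            )
            with open(sidecar_path, "w") as fh:
                for sample, grp in self.groups.items():
                    fh.write(f"# sample\t{sample}\t{grp}\n")
                side.to_csv(fh, sep="\t", index=False)


@dataclass
class ReadSet:
    """Simulated single-end reads: (read_id, sequence) pairs."""

    reads: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n{seq}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReadSet":
        reads: list[tuple[str, str]] = []
        rid, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if rid is not None:
                        reads.append((rid, "".join(chunks)))
                    rid, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if rid is not None:
            reads.append((rid, "".join(chunks)))
        return cls(reads=reads)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray, size) -> np.ndarray:
    """Draw NB(mean, mean(1+phi*mean)) counts; phi == 0 rows are Poisson."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), size)
    out = np.empty(size, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def draw_counts(params: SimulationParams) -> CountMatrix:
    """Sample the Control/Case count matrix from the NB model.

    Deterministic given ``params.seed``; columns are ``control_1..n`` then
    ``case_1..n``.
    """
    rng = np.random.default_rng(params.seed)
    tab = params.table
    n_tx, n_reps = len(tab), params.n_reps
    mu = tab["mu"].to_numpy()
    phi = tab["phi"].to_numpy()
    theta = tab["theta"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for j in range(1, n_reps + 1):
        cols[f"control_{j}"] = _nb_draw(rng, mu, phi, (n_tx,))
        groups[f"control_{j}"] = "Control"
    for j in range(1, n_reps + 1):
        cols[f"case_{j}"] = _nb_draw(rng, theta * mu, phi, (n_tx,))
        groups[f"case_{j}"] = "Case"
    values = pd.DataFrame(cols, index=tab.index)
    return CountMatrix(values=values, groups=groups, truth=tab["theta"].copy())


def make_sim_params(
    n_tx: int | None = None,
    de_fraction: float = 0.3,
    lfc: float = 1.0,
    mu_law: tuple = ("lognormal", math.log(50.0), 1.3),
    phi_law: tuple = ("trend", 3.0, 0.05),
    n_reps: int = 3,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> SimulationParams:
    """Draw a synthetic parameter set (mu, phi, theta) per transcript.

    A ``de_fraction`` share of transcripts (``round(de_fraction * n_tx)`` of
    them) receives theta = 2**(+-lfc) with equiprobable sign; the rest get
    theta = 1 exactly.  mu follows ``("lognormal", meanlog, sdlog)``; phi
    follows ``("constant", c)`` or the mean-dependent trend
    ``("trend", a, b)`` giving phi = a/mu + b (dispersion shrinking with
    abundance, as fitted dispersion trends do).
    """
    if ids is not None:
        ids = list(ids)
        n_tx = len(ids)
    if n_tx is None:
        raise ValueError("provide n_tx or ids")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if ids is None:
        width = len(str(n_tx))
        ids = [f"tx_{i:0{width}d}" for i in range(1, n_tx + 1)]
    rng = np.random.default_rng(seed)

    law, *law_args = mu_law
    if law == "lognormal":
        meanlog, sdlog = law_args
        mu = rng.lognormal(meanlog, sdlog, n_tx)
    else:
        raise ValueError(f"unknown mu law {law!r}")

    law, *law_args = phi_law
    if law == "constant":
        phi = np.full(n_tx, float(law_args[0]))
    elif law == "trend":
        a, b = law_args
        phi = a / mu + b
    else:
        raise ValueError(f"unknown phi law {law!r}")
    if (phi < 0).any():
        raise ValueError("phi law produced negative dispersion")

    theta = np.ones(n_tx)
    n_de = round(de_fraction * n_tx)
    de_idx = rng.choice(n_tx, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    theta[de_idx] = 2.0 ** (signs * lfc)

    table = pd.DataFrame(
        {"mu": mu, "phi": phi, "theta": theta},
        index=pd.Index(ids, name="transcript_id"),
    )
    return SimulationParams(table=table, n_reps=n_reps, seed=int(rng.integers(2**31)))


def simulate_reads(
    counts: CountMatrix,
    txome: Transcriptome,
    read_length: int = 100,
    seed: int = 0,
) -> tuple[ReadSet, pd.DataFrame]:
    """Generate exactly Y_ij error-free reads per (transcript, sample).

    Start positions are uniform over the transcript; transcripts shorter than
    ``read_length`` emit full-length copies.  Returns the reads plus an
    origin table (index read_id, columns transcript_id / sample) for exact
    alignment scoring.  Read ids are ``origin|sample|serial``.
    """
    missing = [t for t in counts.values.index if t not in txome.sequences]
    if missing:
        raise KeyError(f"transcripts absent from transcriptome: {missing[:10]}")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    origin_ids: list[str] = []
    origin_tx: list[str] = []
    origin_sample: list[str] = []
    for sample in counts.values.columns:
        col = counts.values[sample]
        for tx_id, y in col.items():
            y = int(y)
            if y == 0:
                continue
            seq = txome.sequences[tx_id]
            l = len(seq)
            if l <= read_length:
                starts = np.zeros(y, dtype=int)
                rl = l
            else:
                starts = rng.integers(0, l - read_length + 1, size=y)
                rl = read_length
            for k, s in enumerate(starts, start=1):
                rid = f"{tx_id}|{sample}|{k}"
                reads.append((rid, seq[s : s + rl]))
                origin_ids.append(rid)
                origin_tx.append(tx_id)
                origin_sample.append(sample)
    origin = pd.DataFrame(
        {"transcript_id": origin_tx, "sample": origin_sample},
        index=pd.Index(origin_ids, name="read_id"),
    )
    return ReadSet(reads=reads), origin
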