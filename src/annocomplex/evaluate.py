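"""Benchmarking metrics for alignment, quantification and DE calling.

The evaluation mirrors a three-step DE pipeline assessment:

* alignment — per-read recall / precision / F1 against known read origins;
* quantification — Spearman's rho and range-normalized RMSE of log2 CPM
  between estimates and the ground-truth count matrix;
* DE — AUC of a p-value ranking against the true-DE labels (|log2 theta| >= 1),
  plus rho/NRMSE of the estimated versus true log2 fold-change and the
  confusion counts of the call rule |log2FC| >= 1 and BH FDR < 0.05.

Transcripts under 0.25 CPM in any ground-truth sample are removed before the
quantification and DE evaluations to avoid metric inflation.  Results are
reported within terciles of transcript mappability, faceted by true
abundance, so the dependence of each step on annotation complexity is
visible directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .quantify import AlignmentTable, cpm_transform
from .simulate import CountMatrix

__all__ = [
    "AlignmentMetrics",
    "MetricsReport",
    "alignment_metrics",
    "ground_truth_filter",
    "quant_metrics",
    "nrmse",
    "simple_de_test",
    "true_de_labels",
    "de_metrics",
    "ranking_auc",
    "tercile_groups",
    "grouped_report",
]

DEFAULT_CPM_THRESHOLD = 0.25
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_FDR_THRESHOLD = 0.05
TERCILE_LABELS = ("low", "middle", "high")


@dataclass(frozen=True)
class AlignmentMetrics:
    tp: int
    fp: int
    fn: int
    recall: float  # NaN when undefined
    precision: float
    f1: float


@dataclass
class MetricsReport:
    """Tidy per-group metric table plus the tercile interval bounds."""

    table: pd.DataFrame  # columns: step, metric, mappability_group, abundance_group, value, n, reliable
    mappability_bounds: dict = field(default_factory=dict)
    abundance_bounds: dict = field(default_factory=dict)

    def value(self, step: str, metric: str, map_group: str = "all", ab_group: str = "all") -> float:
        t = self.table
        row = t[
            (t["step"] == step)
            & (t["metric"] == metric)
            & (t["mappability_group"] == map_group)
            & (t["abundance_group"] == ab_group)
        ]
        if row.empty:
            return math.nan
        return float(row["value"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def alignment_metrics(
    origin: pd.DataFrame,
    aln: AlignmentTable,
    read_ids: Iterable[str] | None = None,
) -> AlignmentMetrics:
    """Score read alignment against known origins.

    TP: reads whose mapped set contains the origin transcript; FP: mapped
    reads whose set does not; FN: unmapped reads.  Undefined ratios (zero
    denominator) are NaN, never 0.
    """
    ids = list(read_ids) if read_ids is not None else list(aln.rows)
    tp = fp = fn = 0
    origin_tx = origin["transcript_id"]
    for rid in ids:
        mapped = aln.rows[rid]
        if not mapped:
            fn += 1
        elif origin_tx[rid] in mapped:
            tp += 1
        else:
            fp += 1
    recall = tp / (tp + fn) if tp + fn else math.nan
    precision = tp / (tp + fp) if tp + fp else math.nan
    if not math.isnan(recall) and not math.isnan(precision) and (recall + precision) > 0:
        f1 = 2 * recall * precision / (recall + precision)
    else:
        f1 = math.nan
    return AlignmentMetrics(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision, f1=f1)


def ground_truth_filter(
    true_counts: CountMatrix, threshold_cpm: float = DEFAULT_CPM_THRESHOLD
) -> list[str]:
    """Transcripts at or above the CPM threshold in *every* ground-truth sample.

    "Under threshold" is strict, so a transcript sitting exactly at the
    threshold in all samples survives.
    """
    cpm = true_counts.cpm()
    kept = cpm.index[(cpm >= threshold_cpm).all(axis=1)]
    return list(kept)


def nrmse(est: np.ndarray, true: np.ndarray) -> float:
    """RMSE normalized by the range (max - min) of the true values."""
    est = np.asarray(est, dtype=float)
    true = np.asarray(true, dtype=float)
    rng = true.max() - true.min()
    if rng == 0:
        return math.nan
    return float(np.sqrt(np.mean((est - true) ** 2)) / rng)


def quant_metrics(
    est_log2cpm: pd.DataFrame,
    true_log2cpm: pd.DataFrame,
    kept: Iterable[str],
) -> tuple[float, float]:
    """Spearman's rho and NRMSE of log2 CPM over kept (transcript, sample) pairs."""
    kept = list(kept)
    if len(kept) < 3:
        raise ValueError("need at least 3 kept transcripts")
    cols = list(true_log2cpm.columns)
    est = est_log2cpm.loc[kept, cols].to_numpy().ravel()
    true = true_log2cpm.loc[kept, cols].to_numpy().ravel()
    rho = stats.spearmanr(est, true).statistic
    return float(rho), nrmse(est, true)


def simple_de_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    prior_cpm: float = 1.0,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Minimal reference DE caller on log2 CPM.

    Per transcript: log2fc = mean(Case log2 CPM) - mean(Control log2 CPM);
    p-value from Welch's unequal-variance t-test across replicates; q-value
    by Benjamini-Hochberg step-up over all tested transcripts; the call is
    |log2fc| >= lfc_threshold and q < fdr_threshold.  A transcript with zero
    variance in both groups gets p = 1 when the group means are equal and
    p = 0 otherwise.
    """
    ctrl = [s for s, g in groups.items() if g == "Control"]
    case = [s for s, g in groups.items() if g == "Case"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need at least 2 replicates per group")
    log2cpm = cpm_transform(counts, log2=True, prior=prior_cpm)
    a = log2cpm[case].to_numpy()
    b = log2cpm[ctrl].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    pvals[degenerate & (lfc == 0)] = 1.0
    pvals[degenerate & (lfc != 0)] = 0.0
    pvals = np.nan_to_num(pvals, nan=1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    call = (np.abs(lfc) >= lfc_threshold) & (qvals < fdr_threshold)
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvals, "qvalue": qvals, "call": call},
        index=counts.index.copy(),
    )


def true_de_labels(theta: pd.Series) -> pd.Series:
    """True-DE labels: fold-change magnitude >= 2 (theta >= 2 or <= 1/2)."""
    return (theta >= 2) | (theta <= 0.5)


def _midrank_score(pvalue: np.ndarray, abs_lfc: np.ndarray) -> np.ndarray:
    """Midranks of the (-pvalue, |log2fc|) sort key (higher = more DE-like)."""
    n = len(pvalue)
    keys = list(zip(-np.asarray(pvalue, dtype=float), np.asarray(abs_lfc, dtype=float)))
    order = sorted(range(n), key=lambda i: keys[i])
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and keys[order[j + 1]] == keys[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1  # 1-based midrank
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def ranking_auc(pvalue: np.ndarray, abs_lfc: np.ndarray, y_true: np.ndarray) -> float:
    """ROC AUC of the -pvalue ranking (ties broken by |log2fc|) vs truth.

    Computed via the rank (Mann-Whitney) formula; NaN when only one class is
    present.
    """
    y = np.asarray(y_true, dtype=bool)
    if y.all() or not y.any():  # single class: AUC undefined
        return math.nan
    score = _midrank_score(pvalue, abs_lfc)
    return float(roc_auc_score(y, score))


def de_metrics(
    de: pd.DataFrame,
    theta: pd.Series,
    kept: Iterable[str],
) -> dict:
    """AUC, fold-change rho/NRMSE and confusion counts over kept transcripts."""
    kept = [t for t in kept if t in de.index]
    sub = de.loc[kept]
    truth = true_de_labels(theta.loc[kept])
    auc = ranking_auc(sub["pvalue"].to_numpy(), np.abs(sub["log2fc"].to_numpy()), truth.to_numpy())
    true_lfc = np.log2(theta.loc[kept].to_numpy())
    est_lfc = sub["log2fc"].to_numpy()
    if len(kept) >= 3 and np.ptp(true_lfc) > 0:
        rho = float(stats.spearmanr(est_lfc, true_lfc).statistic)
        err = nrmse(est_lfc, true_lfc)
    else:
        rho, err = math.nan, math.nan
    call = sub["call"].to_numpy()
    t = truth.to_numpy()
    return {
        "auc": auc,
        "spearman_rho_lfc": rho,
        "nrmse_lfc": err,
        "tp": int((call & t).sum()),
        "fp": int((call & ~t).sum()),
        "tn": int((~call & ~t).sum()),
        "fn": int((~call & t).sum()),
        "n": len(kept),
    }


def tercile_groups(
    values: pd.Series, k: int = 3
) -> tuple[pd.Series, dict[str, tuple[float, float]]]:
    """Split ids into k equal-sized-as-possible groups by ascending value.

    Ties are broken by id (stable); boundaries fall at ceil(i*N/k), so for
    N = 10 and k = 3 the sizes are (4, 3, 3).  Returns the label per id and
    the [min, max] value span of each group (intervals are half-open except
    the last).
    """
    if len(values) < k:
        raise ValueError(f"need at least {k} ids to form {k} groups")
    order = sorted(values.index, key=lambda i: (values[i], str(i)))
    n = len(order)
    labels = list(TERCILE_LABELS) if k == 3 else [f"g{i+1}" for i in range(k)]
    assignment: dict = {}
    bounds: dict[str, tuple[float, float]] = {}
    prev = 0
    for gi in range(k):
        cut = math.ceil((gi + 1) * n / k)
        members = order[prev:cut]
        for ident in members:
            assignment[ident] = labels[gi]
        bounds[labels[gi]] = (float(values[members[0]]), float(values[members[-1]]))
        prev = cut
    out = pd.Series(assignment, name="group").reindex(values.index)
    return out, bounds


def _report_row(step, metric, map_g, ab_g, value, n, min_cell):
    return {
        "step": step,
        "metric": metric,
        "mappability_group": map_g,
        "abundance_group": ab_g,
        "value": value,
        "n": n,
        "reliable": bool(n >= min_cell),
    }


def grouped_report(
    *,
    true_counts: CountMatrix,
    est_counts: pd.DataFrame,
    mappability: pd.Series,
    origin: pd.DataFrame | None = None,
    aln: AlignmentTable | None = None,
    threshold_cpm: float = DEFAULT_CPM_THRESHOLD,
    min_cell_size: int = 10,
    prior_cpm: float = 1.0,
) -> MetricsReport:
    """Full per-tercile evaluation of an estimated quantification.

    Quantification metrics are computed over (transcript, sample) pairs and
    faceted by the pair's own true CPM tercile; DE metrics are computed per
    transcript and faceted by mean true CPM across all ground-truth samples.
    Mappability terciles are shared by both.  Cells smaller than
    ``min_cell_size`` are flagged unreliable; empty cells are reported as
    missing (NaN), never zero.
    """
    kept = [
        t
        for t in ground_truth_filter(true_counts, threshold_cpm)
        if t in est_counts.index and t in mappability.index
    ]
    if len(kept) < 9:
        raise ValueError("too few transcripts survive the ground-truth filter")

    true_cpm = true_counts.cpm()
    true_log2 = np.log2(true_cpm + prior_cpm)
    est_log2 = cpm_transform(est_counts, log2=True, prior=prior_cpm)
    samples = list(true_counts.values.columns)

    map_groups, map_bounds = tercile_groups(mappability.loc[kept])
    mean_cpm = true_cpm.loc[kept].mean(axis=1)
    de_ab_groups, de_ab_bounds = tercile_groups(mean_cpm)

    rows: list[dict] = []

    # ---- alignment step ------------------------------------------------
    if origin is not None and aln is not None:
        am = alignment_metrics(origin, aln)
        for metric in ("recall", "precision", "f1"):
            rows.append(
                _report_row("alignment", metric, "all", "all", getattr(am, metric), len(aln), min_cell_size)
            )
        read_map_group = origin["transcript_id"].map(map_groups)
        for g in TERCILE_LABELS:
            ids = origin.index[read_map_group == g]
            if len(ids) == 0:
                rows.append(_report_row("alignment", "f1", g, "all", math.nan, 0, min_cell_size))
                continue
            amg = alignment_metrics(origin, aln, ids)
            for metric in ("recall", "precision", "f1"):
                rows.append(
                    _report_row("alignment", metric, g, "all", getattr(amg, metric), len(ids), min_cell_size)
                )

    # ---- quantification step (per transcript-sample pair) --------------
    pair_index = pd.MultiIndex.from_product([kept, samples], names=["transcript_id", "sample"])
    pair_est = est_log2.loc[kept, samples].to_numpy().ravel()
    pair_true = true_log2.loc[kept, samples].to_numpy().ravel()
    pair_cpm = true_cpm.loc[kept, samples].to_numpy().ravel()
    pair_df = pd.DataFrame(
        {"est": pair_est, "true": pair_true, "true_cpm": pair_cpm},
        index=pair_index,
    )
    pair_keys = pd.Series(
        pair_df["true_cpm"].to_numpy(),
        index=pd.Index([f"{t}|{s}" for t, s in pair_index], name="pair"),
    )
    pair_ab_labels, quant_ab_bounds = tercile_groups(pair_keys)
    pair_df["abundance_group"] = pair_ab_labels.to_numpy()
    pair_df["mappability_group"] = [map_groups[t] for t, _s in pair_index]

    rho_all, nrmse_all = quant_metrics(est_log2, true_log2, kept)
    rows.append(_report_row("quantification", "spearman_rho", "all", "all", rho_all, len(pair_df), min_cell_size))
    rows.append(_report_row("quantification", "nrmse", "all", "all", nrmse_all, len(pair_df), min_cell_size))
    for ab_g in TERCILE_LABELS:
        for map_g in TERCILE_LABELS:
            cell = pair_df[
                (pair_df["abundance_group"] == ab_g) & (pair_df["mappability_group"] == map_g)
            ]
            if len(cell) < 3:
                rows.append(_report_row("quantification", "spearman_rho", map_g, ab_g, math.nan, len(cell), min_cell_size))
                rows.append(_report_row("quantification", "nrmse", map_g, ab_g, math.nan, len(cell), min_cell_size))
                continue
            est_v, true_v = cell["est"].to_numpy(), cell["true"].to_numpy()
            rho = float(stats.spearmanr(est_v, true_v).statistic)
            rows.append(_report_row("quantification", "spearman_rho", map_g, ab_g, rho, len(cell), min_cell_size))
            rows.append(_report_row("quantification", "nrmse", map_g, ab_g, nrmse(est_v, true_v), len(cell), min_cell_size))

    # ---- DE step (per transcript) ---------------------------------------
    de = simple_de_test(est_counts.loc[[t for t in est_counts.index if t in set(kept)]], true_counts.groups, prior_cpm=prior_cpm)
    overall = de_metrics(de, true_counts.truth, kept)
    for metric in ("auc", "spearman_rho_lfc", "nrmse_lfc", "tp", "fp", "tn", "fn"):
        rows.append(_report_row("de", metric, "all", "all", overall[metric], overall["n"], min_cell_size))
    for ab_g in TERCILE_LABELS:
        for map_g in TERCILE_LABELS:
            cell_ids = [
                t for t in kept if map_groups[t] == map_g and de_ab_groups[t] == ab_g
            ]
            if len(cell_ids) == 0:
                rows.append(_report_row("de", "auc", map_g, ab_g, math.nan, 0, min_cell_size))
                continue
            cm = de_metrics(de, true_counts.truth, cell_ids)
            for metric in ("auc", "spearman_rho_lfc", "nrmse_lfc"):
                rows.append(_report_row("de", metric, map_g, ab_g, cm[metric], cm["n"], min_cell_size))

    return MetricsReport(
        table=pd.DataFrame(rows),
        mappability_bounds=map_bounds,
        abundance_bounds={"de": de_ab_bounds, "quantification": quant_ab_bounds},
    )
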