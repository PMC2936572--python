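"""Scoring selections against the injected truth.

Confusion accounting follows the spike-in convention: true positives are
selections made among the modified (AP) genes, false positives selections
among the unmodified (AN) genes.  Because AN-genes outnumber AP-genes
several-fold, Specificity is nearly blind to realistic numbers of false
positives; Precision = TP / (TP + FP) is therefore reported alongside
Sensitivity as the headline pair.

Metrics are computed overall and within equal consecutive blocks of the
mean-sorted gene order (20 blocks of 5% by default), so that the
performance of a normalization + DE chain can be read as a function of
expression level.  Repeated random splits of the sample group give
mean +- SD for every figure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkDataset, make_benchmark
from .data import (
    AnalysisRestrictions,
    ExpressionMatrix,
    InjectionDesign,
    TruthTable,
    ValidationError,
)
from . import de as de_mod
from . import normalization as norm_mod

__all__ = [
    "ConfusionCounts",
    "MetricSeries",
    "PowerCurve",
    "confusion",
    "metrics",
    "blockwise_metrics",
    "evaluate_repeats",
    "power_analysis",
    "plot_metric_series",
    "plot_power_curve",
]


@dataclass
class ConfusionCounts:
    """Confusion counts of one selection against the truth.

    A selected modified gene with the wrong direction is recorded in
    ``direction_errors`` and, under direction-strict scoring, counted as
    both a false negative (its change was missed) and a false positive (a
    spurious selection was produced).  Genes excluded from the analysis are
    removed from all four categories and counted in ``n_excluded``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    direction_errors: int = 0
    n_excluded: int = 0


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and precision (NaN on 0/0)."""

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "precision": ratio(counts.tp, counts.tp + counts.fp),
    }


def _aligned_arrays(result: pd.DataFrame, truth: TruthTable):
    gene_ids = result["gene_id"].to_numpy(dtype=object)
    if len(gene_ids) != len(truth.gene_ids) or not np.array_equal(gene_ids, truth.gene_ids):
        raise ValidationError("result and truth gene IDs disagree")
    selected = result["selected"].to_numpy(dtype=bool)
    direction = result["direction"].to_numpy(dtype=object)
    excluded = (
        result["excluded"].to_numpy(dtype=bool)
        if "excluded" in result.columns
        else np.zeros(len(gene_ids), dtype=bool)
    )
    return selected, direction, excluded


def confusion(
    result: pd.DataFrame,
    truth: TruthTable,
    direction_strict: bool = True,
) -> ConfusionCounts:
    """Count TP/FP/TN/FN of a DE result table against the truth.

    Alignment is checked by gene_id equality, not position alone.  With
    ``direction_strict`` (the default) a selection of a modified gene only
    counts as a true positive when its reported direction matches the
    injected one; the lenient mode accepts any selection of a modified gene,
    for comparability with direction-blind external methods.
    """
    selected, direction, excluded = _aligned_arrays(result, truth)
    keep = ~excluded
    modified = (truth.label != "unchanged") & keep
    sel = selected & keep

    right_dir = sel & modified & (direction == truth.label)
    wrong_dir = sel & modified & (direction != truth.label)
    if direction_strict:
        tp = int(right_dir.sum())
        dir_err = int(wrong_dir.sum())
        fp = int((sel & ~modified).sum()) + dir_err
    else:
        tp = int((sel & modified).sum())
        dir_err = 0
        fp = int((sel & ~modified).sum())
    fn = int(modified.sum()) - tp if not direction_strict else int(modified.sum()) - tp
    tn = int((~sel & ~modified & keep).sum())
    return ConfusionCounts(tp, fp, tn, fn, dir_err, int(excluded.sum()))


def _block_spans(n_genes: int, n_blocks: int) -> list[tuple[int, int]]:
    """Equal consecutive blocks; the last block absorbs the remainder."""
    base = n_genes // n_blocks
    if base == 0:
        raise ValidationError(f"{n_genes} genes cannot form {n_blocks} blocks")
    spans = [(i * base, (i + 1) * base) for i in range(n_blocks)]
    spans[-1] = (spans[-1][0], n_genes)
    return spans


def _block_label(i: int, n_blocks: int) -> str:
    """Percentile interval along the decreasing sort (block 0 = top)."""
    step = 100.0 / n_blocks
    hi = 100.0 - i * step
    return f"{hi - step:g}-{hi:g}"


def blockwise_metrics(
    result: pd.DataFrame,
    truth: TruthTable,
    matrix: ExpressionMatrix,
    n_blocks: int = 20,
    direction_strict: bool = True,
) -> pd.DataFrame:
    """Per-block confusion and metrics along the mean-sorted gene order.

    Returns one row per block (labelled by its percentile interval, the
    highest-expression block first) plus an ``overall`` row; per-block
    counts sum exactly to the overall counts.
    """
    if not matrix.sorted_by_mean:
        raise ValidationError("blockwise metrics need a mean-sorted matrix")
    truth.check_alignment(matrix)
    rows = []
    for i, (lo, hi) in enumerate(_block_spans(matrix.n_genes, n_blocks)):
        sub_truth = TruthTable(truth.gene_ids[lo:hi], truth.label[lo:hi], truth.fold[lo:hi])
        counts = confusion(result.iloc[lo:hi], sub_truth, direction_strict)
        rows.append(
            {"block": _block_label(i, n_blocks), "n_genes": hi - lo,
             **dataclasses.asdict(counts), **metrics(counts)}
        )
    overall = confusion(result, truth, direction_strict)
    rows.append(
        {"block": "overall", "n_genes": matrix.n_genes,
         **dataclasses.asdict(overall), **metrics(overall)}
    )
    return pd.DataFrame(rows)


@dataclass
class MetricSeries:
    """Block-wise and overall metrics, mean +- SD over permutation repeats."""

    per_block: pd.DataFrame
    overall: dict[str, dict[str, float]]
    n_repeats: int
    n_blocks: int
    runs: list[pd.DataFrame] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "n_blocks": self.n_blocks,
            "overall": self.overall,
            "per_block": self.per_block.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path, metadata: dict | None = None) -> None:
        payload = self.to_dict()
        if metadata:
            payload["metadata"] = metadata
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        self.per_block.to_csv(path, sep="\t", index=False)


def _resolve_normalizer(normalizer) -> Callable:
    return norm_mod.get_normalizer(normalizer) if isinstance(normalizer, str) else normalizer


def _resolve_de(method) -> Callable:
    return de_mod.get_de_method(method) if isinstance(method, str) else method


def _joint_normalize_and_split(
    bench: BenchmarkDataset, normalizer: Callable
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Normalize control and experimental arrays jointly, then split back.

    Real analyses normalize all arrays of an experiment together, so the
    benchmark does the same; this is also what exposes the failure modes of
    rank- and trend-based normalizers under asymmetric changes.
    """
    joint = ExpressionMatrix(
        bench.control.gene_ids.copy(),
        np.concatenate([bench.control.sample_ids, bench.experimental.sample_ids]),
        np.hstack([bench.control.values, bench.experimental.values]),
    )
    normed = normalizer(joint)
    half = bench.control.n_samples
    ctrl = normed.select_samples(range(half))
    expm = normed.select_samples(range(half, normed.n_samples))
    ctrl.sorted_by_mean = bench.control.sorted_by_mean
    return ctrl, expm


def _run_chain(
    bench: BenchmarkDataset,
    normalizer: Callable,
    de_method: Callable,
    restrictions: AnalysisRestrictions,
) -> pd.DataFrame:
    ctrl, expm = _joint_normalize_and_split(bench, normalizer)
    return de_method(ctrl, expm, restrictions)


def evaluate_repeats(
    matrix: ExpressionMatrix,
    design: InjectionDesign,
    normalizer: str | Callable = "two_step",
    de_method: str | Callable = "associative",
    restrictions: AnalysisRestrictions | None = None,
    n_repeats: int = 3,
    base_seed: int = 0,
    n_blocks: int = 20,
    direction_strict: bool = True,
) -> MetricSeries:
    """Benchmark one normalizer + DE chain over repeated random splits.

    Each repeat re-splits the samples with permutation seed
    ``base_seed + i``, injects the design into the experimental half,
    normalizes both subgroups jointly, runs the DE method and scores it.
    Reported figures are mean +- SD across the repeats (SD 0 when a single
    repeat is requested).
    """
    if restrictions is None:
        restrictions = AnalysisRestrictions()
    normalizer = _resolve_normalizer(normalizer)
    de_method = _resolve_de(de_method)
    runs: list[pd.DataFrame] = []
    for i in range(n_repeats):
        bench = make_benchmark(matrix, design, base_seed + i)
        result = _run_chain(bench, normalizer, de_method, restrictions)
        runs.append(
            blockwise_metrics(result, bench.truth, bench.control, n_blocks, direction_strict)
        )
    return _aggregate_runs(runs, n_blocks)


def _aggregate_runs(runs: list[pd.DataFrame], n_blocks: int) -> MetricSeries:
    import warnings

    metric_names = ("sensitivity", "specificity", "precision")
    stacked = {m: np.stack([r[m].to_numpy() for r in runs]) for m in metric_names}
    per_block = runs[0][["block", "n_genes"]].copy()
    for m in metric_names:
        with warnings.catch_warnings():
            # blocks where the metric is NA (0/0) in every repeat stay NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            per_block[f"{m}_mean"] = np.nanmean(stacked[m], axis=0)
            per_block[f"{m}_sd"] = (
                np.nanstd(stacked[m], axis=0, ddof=1) if len(runs) > 1
                else np.zeros(stacked[m].shape[1])
            )
    overall_row = per_block.index[-1]
    overall = {
        m: {
            "mean": float(per_block.loc[overall_row, f"{m}_mean"]),
            "sd": float(per_block.loc[overall_row, f"{m}_sd"]),
        }
        for m in metric_names
    }
    return MetricSeries(per_block, overall, len(runs), n_blocks, runs)


@dataclass
class PowerCurve:
    """Sensitivity/precision as a function of replicates per group."""

    table: pd.DataFrame
    n_boot: int
    design: InjectionDesign
    restrictions: AnalysisRestrictions

    def to_json(self, path: str | Path, metadata: dict | None = None) -> None:
        payload = {
            "n_boot": self.n_boot,
            "curve": self.table.to_dict(orient="records"),
        }
        if metadata:
            payload["metadata"] = metadata
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def power_analysis(
    matrix: ExpressionMatrix,
    design: InjectionDesign,
    normalizer: str | Callable = "two_step",
    de_method: str | Callable = "associative",
    restrictions: AnalysisRestrictions | None = None,
    n_list: Sequence[int] = (2, 3, 4, 5, 6, 7, 8, 9, 10),
    n_boot: int = 3,
    base_seed: int = 0,
    direction_strict: bool = True,
) -> PowerCurve:
    """Map the number of replicates per group to achieved quality.

    For each requested ``n``, every bootstrap repeat re-splits the samples,
    draws ``n`` replicates per subgroup without replacement, runs the chain
    and records overall sensitivity and precision; the curve reports
    mean +- SD over the repeats.  ``n = S/2`` uses every replicate and
    reproduces the corresponding full-design evaluation.
    """
    if restrictions is None:
        restrictions = AnalysisRestrictions()
    normalizer = _resolve_normalizer(normalizer)
    de_method = _resolve_de(de_method)
    half = matrix.n_samples // 2
    rows = []
    for n in n_list:
        if n < 2:
            raise ValidationError("need at least 2 replicates per group")
        if n > half:
            raise ValidationError(f"n={n} exceeds the {half} replicates per subgroup")
        sens, prec = [], []
        for b in range(n_boot):
            bench = make_benchmark(matrix, design, base_seed + b)
            rng = np.random.default_rng(base_seed + 100_000 * n + b)
            idx_c = np.sort(rng.choice(half, size=n, replace=False))
            idx_e = np.sort(rng.choice(half, size=n, replace=False))
            sub = BenchmarkDataset(
                bench.control.select_samples(idx_c),
                bench.experimental.select_samples(idx_e),
                bench.truth,
                bench.design,
                bench.permutation_seed,
            )
            result = _run_chain(sub, normalizer, de_method, restrictions)
            m = metrics(confusion(result, bench.truth, direction_strict))
            sens.append(m["sensitivity"])
            prec.append(m["precision"])
        rows.append(
            {
                "n_replicates": int(n),
                "sensitivity_mean": float(np.nanmean(sens)),
                "sensitivity_sd": float(np.nanstd(sens, ddof=1)) if n_boot > 1 else 0.0,
                "precision_mean": float(np.nanmean(prec)),
                "precision_sd": float(np.nanstd(prec, ddof=1)) if n_boot > 1 else 0.0,
            }
        )
    return PowerCurve(pd.DataFrame(rows), n_boot, design, restrictions)


# ---------------------------------------------------------------------------
# plots (optional, mirror the block-profile and power-curve figures)
# ---------------------------------------------------------------------------

def plot_metric_series(series: MetricSeries, path: str | Path, title: str = "") -> None:
    """Bar profile of sensitivity/precision per expression block."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    blocks = series.per_block.iloc[:-1]
    x = np.arange(len(blocks))
    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    for ax, m, color in zip(axes, ("sensitivity", "precision"), ("firebrick", "steelblue")):
        ax.bar(x, blocks[f"{m}_mean"], yerr=blocks[f"{m}_sd"], color=color, capsize=2)
        ax.set_ylabel(m)
        ax.set_ylim(0, 1.05)
    axes[1].set_xticks(x)
    axes[1].set_xticklabels(blocks["block"], rotation=90)
    axes[1].set_xlabel("expression percentile block (decreasing sort)")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_power_curve(curve: PowerCurve, path: str | Path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = curve.table
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.errorbar(t["n_replicates"], t["sensitivity_mean"], yerr=t["sensitivity_sd"],
                label="sensitivity", marker="o", color="firebrick")
    ax.errorbar(t["n_replicates"], t["precision_mean"], yerr=t["precision_sd"],
                label="precision", marker="s", color="steelblue")
    ax.set_xlabel("replicates per group")
    ax.set_ylabel("metric")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
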