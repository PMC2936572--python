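"""Benchmark construction: sort, split, and inject controlled fold changes.

A homogeneous group of arrays is sorted by average expression, split into
equal "control" and "experimental" subgroups, and block-wise controlled
fold changes are multiplied into the experimental subgroup.  The modified
genes (labelled up/down) and the untouched remainder form an exact ground
truth against which any normalization + DE chain can be scored.

Because the injected changes are plain multiplications of raw intensities,
the benchmark retains the full microstructure of the input data — expression
profile, variance patterns and outliers included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    ExpressionMatrix,
    InjectionDesign,
    TruthTable,
    ValidationError,
)

__all__ = [
    "BenchmarkDataset",
    "sort_by_mean",
    "split_group",
    "inject_changes",
    "make_benchmark",
    "replicate_benchmarks",
]


@dataclass
class BenchmarkDataset:
    """One control/experimental pair with its ground truth."""

    control: ExpressionMatrix
    experimental: ExpressionMatrix
    truth: TruthTable
    design: InjectionDesign
    permutation_seed: int | None

    def __post_init__(self) -> None:
        if not np.array_equal(self.control.gene_ids, self.experimental.gene_ids):
            raise ValidationError("control and experimental gene IDs disagree")
        self.truth.check_alignment(self.control)


def sort_by_mean(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder rows by non-increasing mean expression (stable on ties)."""
    means = matrix.row_means()
    order = np.argsort(-means, kind="stable")
    return ExpressionMatrix(
        matrix.gene_ids[order], matrix.sample_ids.copy(), matrix.values[order],
        sorted_by_mean=True,
    )


def split_group(
    matrix: ExpressionMatrix, permutation_seed: int | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split the samples into equal control/experimental halves.

    With a seed the sample order is randomly permuted first; with
    ``None`` the original column order is used.  Gene order is untouched.
    """
    s = matrix.n_samples
    if s % 2:
        raise ValidationError(
            f"cannot split {s} samples into equal halves; drop one sample first"
        )
    idx = np.arange(s)
    if permutation_seed is not None:
        idx = np.random.default_rng(permutation_seed).permutation(s)
    half = s // 2
    return matrix.select_samples(idx[:half]), matrix.select_samples(idx[half:])


def _block_counts(design: InjectionDesign, size: int, full_size: int) -> tuple[int, int]:
    """Numbers of up/down genes for a (sub-)block of ``size`` genes.

    ``full_size`` is the nominal size; a trailing partial block gets
    proportionally scaled counts rounded down.
    """
    if design.mode == "balanced":
        per_dir = design.fraction * full_size / 2.0
        if abs(per_dir * 2 - round(per_dir * 2)) > 1e-9 or abs(per_dir - round(per_dir)) > 1e-9:
            raise ValidationError(
                f"balanced mode needs fraction*block_size ({design.fraction}*{full_size}) "
                "to be an even integer"
            )
        n_up = n_down = int(round(per_dir))
    elif design.mode == "asymmetric_up":
        n_up, n_down = int(round(design.fraction * full_size)), 0
    else:  # custom
        n_up = int(round(design.up_fraction * full_size))
        n_down = int(round(design.down_fraction * full_size))
    if size < full_size:  # trailing partial block: floor-scale
        n_up = int(n_up * size / full_size)
        n_down = int(n_down * size / full_size)
    if n_up + n_down > size:
        raise ValidationError("block too small for the requested counts")
    return n_up, n_down


def inject_changes(
    experimental: ExpressionMatrix, design: InjectionDesign
) -> tuple[ExpressionMatrix, TruthTable]:
    """Multiply controlled fold changes into a mean-sorted matrix.

    Genes are partitioned into consecutive blocks of ``design.block_size``
    in sort order; the top block is sub-partitioned into
    ``block_size / top_block_split`` sub-blocks.  Within every (sub-)block
    the up-genes are multiplied by the fold factor and the down-genes
    divided by it, across all experimental samples; every other value is
    bit-identical to the input.
    """
    if not experimental.sorted_by_mean:
        raise ValidationError("inject_changes requires a mean-sorted matrix")
    g = experimental.n_genes
    if g < design.block_size:
        raise ValidationError(
            f"matrix has {g} genes, fewer than one block of {design.block_size}"
        )
    fold_up = design.fold_up if design.mode == "custom" else design.Fd
    fold_down = design.fold_down if design.mode == "custom" else design.Fd

    rng = (
        np.random.default_rng(design.placement_seed)
        if design.placement == "random"
        else None
    )

    values = experimental.values.copy()
    label = np.full(g, "unchanged", dtype=object)
    fold = np.ones(g)

    # (start, size, nominal size) for every (sub-)block: the top block is
    # probed at finer resolution, the remainder in full blocks
    spans: list[tuple[int, int, int]] = []
    sub = design.top_block_split
    for start in range(0, design.block_size, sub):
        spans.append((start, sub, sub))
    start = design.block_size
    while start < g:
        size = min(design.block_size, g - start)
        spans.append((start, size, design.block_size))
        start += size

    for start, size, full in spans:
        n_up, n_down = _block_counts(design, size, full)
        if n_up + n_down == 0:
            continue
        if rng is None:
            pos = np.arange(start, start + n_up + n_down)
        else:
            pos = start + rng.choice(size, size=n_up + n_down, replace=False)
        up_pos, down_pos = pos[:n_up], pos[n_up:]
        values[up_pos] *= fold_up
        label[up_pos] = "up"
        fold[up_pos] = fold_up
        values[down_pos] /= fold_down
        label[down_pos] = "down"
        fold[down_pos] = fold_down

    modified = ExpressionMatrix(
        experimental.gene_ids.copy(), experimental.sample_ids.copy(), values,
        sorted_by_mean=False,  # injection can break the mean ordering
    )
    truth = TruthTable(experimental.gene_ids.copy(), label, fold)
    return modified, truth


def make_benchmark(
    matrix: ExpressionMatrix,
    design: InjectionDesign,
    permutation_seed: int | None = None,
) -> BenchmarkDataset:
    """sort_by_mean -> split_group -> inject_changes (control untouched)."""
    sorted_matrix = sort_by_mean(matrix)
    control, experimental = split_group(sorted_matrix, permutation_seed)
    modified, truth = inject_changes(experimental, design)
    return BenchmarkDataset(control, modified, truth, design, permutation_seed)


def replicate_benchmarks(
    matrix: ExpressionMatrix,
    design: InjectionDesign,
    n_repeats: int,
    base_seed: int = 0,
) -> list[BenchmarkDataset]:
    """n_repeats benchmarks with sample permutation seeds base_seed+i."""
    if n_repeats < 1:
        raise ValidationError("n_repeats must be at least 1")
    return [make_benchmark(matrix, design, base_seed + i) for i in range(n_repeats)]
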