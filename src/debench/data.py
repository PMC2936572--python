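"""Core data types and plain-text readers/writers.

The universal currency of the pipeline is a gene x sample matrix of
non-negative intensities.  Matrices, ground-truth tables and result tables
travel as UTF-8 TSV files so that spreadsheets exported from public
repositories load directly after conversion to tab-delimited text.

Gene order is the master alignment key: every module that combines a matrix
with a truth table re-validates gene_id agreement rather than trusting
positional order, because sorting steps reorder rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "TruthTable",
    "AnalysisRestrictions",
    "InjectionDesign",
    "read_matrix",
    "write_matrix",
    "read_truth",
    "write_truth",
]

LABELS = ("unchanged", "up", "down")
#: integer codes used in truth-table files (the convention of published
#: supplementary spike-in tables): 0 unchanged, 1 up, 2 down
LABEL_CODES = {"unchanged": 0, "up": 1, "down": 2}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """An in-memory object violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A gene x sample table of expression intensities.

    Parameters
    ----------
    gene_ids :
        Ordered, unique row identifiers.
    sample_ids :
        Ordered, unique column identifiers.
    values :
        ``(G, S)`` float array.  Raw intensities are in arbitrary
        fluorescence units; after step-one normalization the unit is one
        standard deviation of the array's background distribution.
    sorted_by_mean :
        True once rows are in benchmark sort order: non-increasing mean
        expression of the matrix in which the sort was performed.  Column
        subsets and per-array transforms inherit the flag (their own row
        means need not be exactly monotone); reordering rows clears it.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    sorted_by_mean: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        g, s = self.values.shape
        # single-sample matrices arise as halves of a 2-sample split; files
        # and analyses still require >= 2 samples
        if g < 2 or s < 1:
            raise ValidationError(f"need at least 2 genes and 1 sample, got {g}x{s}")
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValidationError("ID vectors do not match the shape of `values`")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    # -- convenience ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.gene_ids.copy(), self.sample_ids.copy(), self.values.copy(),
            self.sorted_by_mean,
        )

    def select_samples(self, index: Sequence[int]) -> "ExpressionMatrix":
        """Column subset (gene order untouched)."""
        idx = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            self.gene_ids.copy(), self.sample_ids[idx], self.values[:, idx],
            self.sorted_by_mean,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same shape/IDs, new values (used by normalizers)."""
        return ExpressionMatrix(
            self.gene_ids.copy(), self.sample_ids.copy(), np.asarray(values, float),
            self.sorted_by_mean,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sorted_by_mean: bool = False) -> "ExpressionMatrix":
        return cls(
            frame.index.to_numpy(dtype=object),
            frame.columns.to_numpy(dtype=object),
            frame.to_numpy(dtype=float),
            sorted_by_mean,
        )


@dataclass
class TruthTable:
    """Per-gene ground truth of the injected changes.

    ``label`` is one of ``up``/``down``/``unchanged``; ``fold`` is the
    magnitude of the injected fold change (1.0 for unchanged genes, the
    direction is carried by the label).
    """

    gene_ids: np.ndarray
    label: np.ndarray
    fold: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        self.fold = np.asarray(self.fold, dtype=float)
        if not (len(self.gene_ids) == len(self.label) == len(self.fold)):
            raise ValidationError("truth-table columns have unequal lengths")
        _check_unique(self.gene_ids, "gene")
        bad = set(np.unique(self.label)) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")
        if np.any(self.fold <= 0):
            raise ValidationError("fold factors must be positive")
        unchanged = self.label == "unchanged"
        if not np.all(self.fold[unchanged] == 1.0):
            raise ValidationError("unchanged genes must have fold == 1.0")
        if np.any(self.fold[~unchanged] == 1.0):
            raise ValidationError("modified genes must have fold != 1.0")

    @property
    def n_modified(self) -> int:
        return int(np.sum(self.label != "unchanged"))

    def check_alignment(self, matrix: ExpressionMatrix) -> None:
        """Raise unless gene IDs agree elementwise with ``matrix``."""
        if len(self.gene_ids) != matrix.n_genes or not np.array_equal(
            self.gene_ids, matrix.gene_ids
        ):
            raise ValidationError("truth table and matrix gene IDs disagree")


@dataclass
class AnalysisRestrictions:
    """Selection restrictions applied after the statistical tests.

    Fa
        Minimal fold-change restriction (dimensionless, > 1).
    Em
        Minimal expression level in background-SD units; a gene passes when
        the larger of its two group means reaches Em.
    alpha_student
        Per-gene significance level of the Student filter.
    alpha_assoc
        Family-wise level of the associative test (Bonferroni-corrected by
        the number of genes tested).
    """

    Fa: float = 1.5
    Em: float = 20.0
    alpha_student: float = 0.05
    alpha_assoc: float = 0.05

    def __post_init__(self) -> None:
        if not self.Fa > 1:
            raise ValidationError("Fa must exceed 1")
        if self.Em < 0:
            raise ValidationError("Em must be non-negative")
        if not 0 < self.alpha_student < 1:
            raise ValidationError("alpha_student must lie in (0, 1)")
        if not 0 < self.alpha_assoc < 1:
            raise ValidationError("alpha_assoc must lie in (0, 1)")


@dataclass
class InjectionDesign:
    """Layout of the controlled fold-change injection.

    The benchmark partitions the mean-sorted matrix into consecutive blocks
    of ``block_size`` genes; the top block is sub-partitioned into
    ``block_size / top_block_split`` sub-blocks so that the wide dynamic
    range at the highest expression levels is probed at finer resolution.

    mode
        ``balanced``       -- fraction/2 of each block multiplied by Fd (up)
                              and a disjoint fraction/2 divided by Fd (down);
        ``asymmetric_up``  -- the whole fraction multiplied by Fd;
        ``custom``         -- ``up_fraction``/``down_fraction`` with separate
                              ``fold_up``/``fold_down`` factors.
    placement
        ``top_of_block`` assigns the highest-mean genes of each block first
        to up then to down (deterministic); ``random`` draws positions with
        ``placement_seed``.
    """

    Fd: float = 2.0
    fraction: float = 0.20
    mode: str = "balanced"
    block_size: int = 1000
    top_block_split: int = 200
    placement: str = "top_of_block"
    placement_seed: int | None = None
    up_fraction: float | None = None
    down_fraction: float | None = None
    fold_up: float | None = None
    fold_down: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("balanced", "asymmetric_up", "custom"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.placement not in ("top_of_block", "random"):
            raise ValidationError(f"unknown placement {self.placement!r}")
        if not 0 < self.fraction < 1:
            raise ValidationError("fraction must lie in (0, 1)")
        if self.block_size <= 0 or self.top_block_split <= 0:
            raise ValidationError("block sizes must be positive")
        if self.block_size % self.top_block_split:
            raise ValidationError("block_size must be divisible by top_block_split")
        if self.mode in ("balanced", "asymmetric_up"):
            if not self.Fd > 1:
                raise ValidationError("Fd must exceed 1")
        if self.mode == "custom":
            for name in ("up_fraction", "down_fraction", "fold_up", "fold_down"):
                if getattr(self, name) is None:
                    raise ValidationError(f"custom mode requires {name}")
            if self.fold_up <= 1 or self.fold_down <= 1:
                raise ValidationError("custom fold factors must exceed 1")
            if not 0 <= self.up_fraction + self.down_fraction < 1:
                raise ValidationError("custom fractions must sum to less than 1")


# ---------------------------------------------------------------------------
# TSV input / output
# ---------------------------------------------------------------------------

#: float format guaranteeing a lossless float64 round-trip (>= 12 significant
#: digits as required for interchange)
_FLOAT_FMT = "%.17g"


def read_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read an expression matrix from delimited text.

    The first row is a header (``gene_id`` followed by sample IDs); the
    first column holds gene IDs; every remaining cell must parse as a
    finite number.  Errors carry the offending row/column coordinates.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split(delimiter)
    if len(header) < 3:
        raise FormatError(f"{path}: need a gene_id column plus >= 2 samples")
    sample_ids = header[1:]
    n_cols = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split(delimiter)
        if len(cells) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {n_cols})"
            )
        gene_ids.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {j} "
                    f"(sample {sample_ids[j - 2]!r})"
                ) from None
        rows.append(row)
    try:
        return ExpressionMatrix(
            np.asarray(gene_ids, dtype=object),
            np.asarray(sample_ids, dtype=object),
            np.asarray(rows, dtype=float),
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix as TSV with a ``gene_id`` header column."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(delimiter.join(["gene_id", *map(str, matrix.sample_ids)]) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(str(gid))
            for v in row:
                fh.write(delimiter + _FLOAT_FMT % v)
            fh.write("\n")


def read_truth(path: str | Path, delimiter: str = "\t") -> TruthTable:
    """Read a truth table (columns ``gene_id``, ``code``, ``fold``).

    Codes follow the supplementary-table convention: 0 unchanged, 1 up
    (multiplied by the fold factor), 2 down (divided by the fold factor).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    gene_ids: list[str] = []
    labels: list[str] = []
    folds: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split(delimiter)
        if len(cells) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        gid, code_s, fold_s = cells
        try:
            code = int(code_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer code {code_s!r}") from None
        if code not in CODE_LABELS:
            raise FormatError(f"{path}:{lineno}: code {code} outside {{0, 1, 2}}")
        try:
            fold = float(fold_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric fold {fold_s!r}") from None
        if fold <= 0:
            raise FormatError(f"{path}:{lineno}: fold must be positive, got {fold}")
        gene_ids.append(gid)
        labels.append(CODE_LABELS[code])
        folds.append(fold)
    try:
        return TruthTable(
            np.asarray(gene_ids, dtype=object),
            np.asarray(labels, dtype=object),
            np.asarray(folds, dtype=float),
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_truth(truth: TruthTable, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(delimiter.join(["gene_id", "code", "fold"]) + "\n")
        for gid, label, fold in zip(truth.gene_ids, truth.label, truth.fold):
            fh.write(
                delimiter.join([str(gid), str(LABEL_CODES[label]), _FLOAT_FMT % fold]) + "\n"
            )
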