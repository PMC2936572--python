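"""Internal-standard normalization plus comparator methods.

The two-step procedure uses two internal standards:

1. **Background cohort** (step one).  The non-expressed genes of an array
   form an approximately normal noise distribution.  Its mean ``Av`` and
   standard deviation ``SD`` are fitted by an iterative trimmed-normal
   procedure and the array is transformed to ``(x - Av) / SD`` so that all
   expression values are in background-SD units and the 3-SD point is the
   threshold separating expressed from non-expressed genes.

2. **Equally expressed cohort** (step two).  Arrays are adjusted to a common
   reference profile by robust linear regression over the expressed genes;
   genes with residuals beyond 3 residual-SD are iteratively discarded so
   that the final fit rests on a homogeneous family of equally expressed
   genes with normally distributed residuals.

Quantile and lowess (MA-trend) normalization are provided as comparators,
and a registry lets external methods participate in evaluations by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .data import ExpressionMatrix, ValidationError

__all__ = [
    "BackgroundModel",
    "RegressionAdjustment",
    "DegenerateBackgroundError",
    "fit_background",
    "standardize",
    "expressed_mask",
    "robust_regression_adjust",
    "two_step_normalize",
    "quantile_normalize",
    "lowess_normalize",
    "register_normalizer",
    "get_normalizer",
    "list_normalizers",
]

#: trimming constant shared by the background fit and the residual trimming
TRIM_SD = 3.0

# Sample SD of a normal truncated at +-c standard deviations is biased low by
# sqrt(1 - 2*c*phi(c) / (2*Phi(c) - 1)); for c = 3 this is ~0.9866.  The
# fitted SD is divided by this factor so the admission window stays at a true
# +-3 SD at the fixed point.
_TRUNC_SD_FACTOR = float(
    np.sqrt(1.0 - 2.0 * TRIM_SD * stats.norm.pdf(TRIM_SD)
            / (2.0 * stats.norm.cdf(TRIM_SD) - 1.0))
)


class DegenerateBackgroundError(ValidationError):
    """The background cohort collapsed (zero spread or too few members)."""


@dataclass
class BackgroundModel:
    """Fitted parameters of an array's background cohort."""

    av: float
    sd: float
    member_mask: np.ndarray
    n_iterations: int
    converged: bool


@dataclass
class RegressionAdjustment:
    """Per-array linear map onto the reference profile."""

    slope: float
    intercept: float
    ee_mask: np.ndarray
    resid_sd: float
    n_iterations: int
    converged: bool


def _half_sample_mode(values: np.ndarray) -> float:
    """Robust mode estimate (half-sample mode).

    Recursively selects the shortest interval containing half of the
    current points.  Finds the background peak even when the background
    cohort is a minority of the array, because the expressed cohort is
    spread thinly over a much wider intensity range.
    """
    x = np.sort(np.asarray(values, float))
    while x.size > 3:
        k = (x.size + 1) // 2
        widths = x[k - 1:] - x[: x.size - k + 1]
        i = int(np.argmin(widths))
        x = x[i:i + k]
    return float(x.mean())


def fit_background(
    values: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    min_members: int = 50,
) -> BackgroundModel:
    """Iterative trimmed-normal fit of one array's background cohort.

    Starting from the neighbourhood of the intensity mode, the member set
    is repeatedly recomputed as every value within ``Av +- 3*SD`` of the
    current estimates until ``(Av, SD)`` stabilise to relative ``tol`` or
    ``max_iter`` iterations.  The reported SD is corrected for the +-3 SD
    truncation bias so that a pure normal sample is recovered unbiasedly.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 200:
        raise ValidationError(f"need at least 200 values to fit a background, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in background fit input")

    mode = _half_sample_mode(x)
    below = np.abs(x[x <= mode] - mode)
    s0 = 1.4826 * float(np.median(below)) if below.size else 0.0
    if s0 <= 0:
        raise DegenerateBackgroundError("background distribution has zero spread")

    av, sd = mode, s0 / _TRUNC_SD_FACTOR
    member = np.zeros(x.size, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        member = np.abs(x - av) <= TRIM_SD * sd
        n = int(member.sum())
        if n < min_members:
            raise DegenerateBackgroundError(
                f"background cohort degenerated to {n} members (< {min_members})"
            )
        new_av = float(x[member].mean())
        raw_sd = float(x[member].std(ddof=1))
        if raw_sd == 0.0:
            raise DegenerateBackgroundError("background cohort has zero variance")
        new_sd = raw_sd / _TRUNC_SD_FACTOR
        dav = abs(new_av - av) / max(abs(av), new_sd)
        dsd = abs(new_sd - sd) / new_sd
        av, sd = new_av, new_sd
        if dav < tol and dsd < tol:
            converged = True
            break
    return BackgroundModel(av, sd, member, it, converged)


def standardize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[BackgroundModel]]:
    """Step one: per array, transform ``x -> (x - Av) / SD``.

    After the transform the background distribution of every array has
    mean ~0 and SD ~1, so intensities are in background-SD units.
    """
    models = [fit_background(matrix.values[:, j]) for j in range(matrix.n_samples)]
    av = np.array([m.av for m in models])
    sd = np.array([m.sd for m in models])
    out = (matrix.values - av[None, :]) / sd[None, :]
    return matrix.with_values(out), models


def expressed_mask(matrix: ExpressionMatrix, threshold: float = 3.0) -> np.ndarray:
    """Genes whose mean standardized expression exceeds ``threshold``.

    3 background-SD above the background mean is the preliminary criterion
    separating expressed from non-expressed genes.
    """
    return matrix.row_means() > threshold


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    if denom == 0.0:
        raise ValidationError("reference profile is constant over the fitting set")
    slope = float(dx @ (y - ym)) / denom
    return slope, ym - slope * xm


def robust_regression_adjust(
    matrix: ExpressionMatrix,
    reference: int | str = "median",
    expression_threshold: float = 3.0,
    trim: float = TRIM_SD,
    max_iter: int = 100,
    min_ee: int = 30,
) -> tuple[ExpressionMatrix, list[RegressionAdjustment]]:
    """Step two: adjust standardized arrays onto a common reference profile.

    ``reference`` is either ``"median"`` (per-gene median across arrays) or
    an array index.  For each array an ordinary least-squares line against
    the reference is fitted over the current equally-expressed set
    (initialised to all expressed genes); genes whose residual exceeds
    ``trim`` residual-SD are dropped and the fit repeated until membership
    stabilises.  The final map is applied to all genes of the array as
    ``x -> (x - intercept) / slope`` so every array lands on the reference
    scale.
    """
    if matrix.n_samples < 2:
        raise ValidationError("need at least 2 arrays to adjust")
    expressed = expressed_mask(matrix, expression_threshold)
    if int(expressed.sum()) < min_ee:
        raise ValidationError(
            f"only {int(expressed.sum())} genes above the expression threshold "
            f"(need >= {min_ee})"
        )
    if reference == "median":
        ref = np.median(matrix.values, axis=1)
    else:
        ref = matrix.values[:, int(reference)]
    ref_e = ref[expressed]

    adjusted = np.empty_like(matrix.values)
    reports: list[RegressionAdjustment] = []
    for j in range(matrix.n_samples):
        y_e = matrix.values[expressed, j]
        member = np.ones(ref_e.size, dtype=bool)
        slope = intercept = resid_sd = 0.0
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            slope, intercept = _ols(ref_e[member], y_e[member])
            if slope <= 0:
                raise ValidationError(
                    f"array {matrix.sample_ids[j]!r} is anti-correlated with the "
                    f"reference (slope {slope:.3g})"
                )
            resid = y_e - (slope * ref_e + intercept)
            resid_sd = float(resid[member].std(ddof=2))
            if resid_sd == 0.0:  # exact linear relation
                converged = True
                break
            new_member = np.abs(resid) <= trim * resid_sd
            if int(new_member.sum()) < min_ee:
                raise ValidationError(
                    f"fewer than {min_ee} equally expressed genes left for array "
                    f"{matrix.sample_ids[j]!r}"
                )
            if np.array_equal(new_member, member):
                converged = True
                break
            member = new_member
        ee_mask = np.zeros(matrix.n_genes, dtype=bool)
        ee_mask[np.flatnonzero(expressed)[member]] = True
        adjusted[:, j] = (matrix.values[:, j] - intercept) / slope
        reports.append(RegressionAdjustment(slope, intercept, ee_mask, resid_sd, it, converged))
    return matrix.with_values(adjusted), reports


def two_step_normalize(
    matrix: ExpressionMatrix,
    expression_threshold: float = 3.0,
    return_details: bool = False,
):
    """Background standardization followed by robust regression adjustment.

    Returns the normalized matrix (background-SD units, arrays on the scale
    of the median profile of the standardized arrays); with
    ``return_details`` also the per-array background models and regression
    adjustments.
    """
    std, bg_models = standardize(matrix)
    adjusted, reports = robust_regression_adjust(
        std, reference="median", expression_threshold=expression_threshold
    )
    if return_details:
        return adjusted, bg_models, reports
    return adjusted


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-mean quantile normalization.

    Every array's sorted values are replaced by the across-array mean of
    sorted values; ties receive the average of the values they span.
    """
    v = matrix.values
    mean_sorted = np.sort(v, axis=0).mean(axis=1)
    ranks = stats.rankdata(v, axis=0, method="average")  # 1-based, .5 on ties
    out = np.interp(ranks, np.arange(1, v.shape[0] + 1), mean_sorted)
    return matrix.with_values(out)


def lowess_normalize(matrix: ExpressionMatrix, span: float = 0.3) -> ExpressionMatrix:
    """MA-trend removal against the median profile.

    Per array, the locally weighted regression of
    ``M = log(array) - log(reference)`` on ``A = (log(array) + log(reference)) / 2``
    is subtracted on the log scale and the result exponentiated back.
    An offset of 1 is added before the log to accommodate zeros.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

    shifted = matrix.values + 1.0
    if np.any(shifted <= 0):
        bad = matrix.gene_ids[np.any(shifted <= 0, axis=1)]
        raise ValidationError(
            "values below -1 make the log transform undefined for genes: "
            + ", ".join(map(str, bad[:10]))
        )
    logv = np.log2(shifted)
    ref = np.median(logv, axis=1)
    out = np.empty_like(logv)
    for j in range(matrix.n_samples):
        m = logv[:, j] - ref
        a = 0.5 * (logv[:, j] + ref)
        delta = 0.01 * (float(a.max()) - float(a.min()))
        trend = sm_lowess(m, a, frac=span, delta=delta, return_sorted=False)
        out[:, j] = logv[:, j] - trend
    back = np.clip(np.exp2(out) - 1.0, 0.0, None)
    return matrix.with_values(back)


# ---------------------------------------------------------------------------
# normalizer registry
# ---------------------------------------------------------------------------

Normalizer = Callable[[ExpressionMatrix], ExpressionMatrix]

_REGISTRY: dict[str, Normalizer] = {}


def register_normalizer(name: str, fn: Normalizer) -> None:
    """Make a matrix -> matrix callable available by name (names are unique)."""
    if name in _REGISTRY:
        raise ValidationError(f"normalizer {name!r} is already registered")
    _REGISTRY[name] = fn


def get_normalizer(name: str) -> Normalizer:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown normalizer {name!r}; available: {', '.join(list_normalizers())}"
        ) from None


def list_normalizers() -> list[str]:
    return sorted(_REGISTRY)


register_normalizer("two_step", two_step_normalize)
register_normalizer("quantile", quantile_normalize)
register_normalizer("lowess", lowess_normalize)
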