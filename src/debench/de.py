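"""Associative differential-expression analysis and a plain-t baseline.

The associative procedure tests whether a gene's replicated residuals
(deviations of the experimental replicates from the averaged control
profile) *associate* with the residual distribution of a reference group —
several hundred expressed genes with inherently low, technical-level
variability selected by an F-test.  A gene is reported as differentially
expressed only when it passes

1. a Student t-test between the two groups (p < alpha_student),
2. the associative t-test of its residuals against the pooled reference
   residuals at a Bonferroni-corrected threshold (family-wise alpha_assoc),
3. a minimal fold-change restriction Fa, and
4. a minimal expression-level restriction Em (background-SD units).

Variance comparisons across genes (reference selection, hypervariable
flagging) and the t statistics are computed on log2-transformed
standardized intensities, floored at one background-SD unit: on that scale
the technical-plus-biological noise of quantifiable genes is approximately
homoscedastic, which is what makes a single technological-variance anchor
and a pooled residual standard meaningful across a 1000-fold dynamic
range.  Fold changes and the Em restriction are evaluated on the linear
background-SD scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data import AnalysisRestrictions, ExpressionMatrix, ValidationError
from .normalization import expressed_mask

__all__ = [
    "ReferenceGroup",
    "select_reference_group",
    "student_filter",
    "associative_test",
    "apply_restrictions",
    "associative_analysis",
    "exclude_hypervariable",
    "ttest_bh_baseline",
    "register_de_method",
    "get_de_method",
    "list_de_methods",
    "de_method_from_file",
]

#: log2 floor: values below one background-SD unit carry no usable signal
LOG_FLOOR = 1.0

RESULT_COLUMNS = [
    "gene_id", "mean_control", "mean_experimental", "fold", "direction",
    "p_student", "p_assoc", "selected", "reasons", "excluded",
]


def _log_scale(values: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(values, LOG_FLOOR))


def _pooled_t_rows(
    m1: np.ndarray, v1: np.ndarray, n1: int,
    m2: float | np.ndarray, v2: float | np.ndarray, n2: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-variance two-sample t with the zero-variance conventions.

    Zero pooled variance with equal means gives p = 1; with unequal means
    p = 0 (a deterministic separation).
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = np.asarray(m1 - m2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero = np.asarray(se == 0.0)
    deterministic = np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0))
    t = np.where(zero, deterministic, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def student_filter(
    control_row: np.ndarray, experimental_row: np.ndarray, alpha_student: float = 0.05
) -> tuple[float, bool]:
    """Two-sample equal-variance Student t-test for one gene.

    Returns ``(p_value, passed)`` with ``passed`` iff p < alpha_student.
    """
    a = np.asarray(control_row, dtype=float)
    b = np.asarray(experimental_row, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("student_filter needs >= 2 replicates per group")
    _, p = _pooled_t_rows(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    p = float(p)
    return p, p < alpha_student


@dataclass
class ReferenceGroup:
    """The internal standard of equal expression.

    ``pooled_residuals`` concatenates every member gene's control-group
    residuals (deviations from its own control mean), giving a highly
    representative (several hundred plus) normally distributed pool whose
    spread reflects technical variation alone.
    """

    gene_ids: np.ndarray
    member_mask: np.ndarray
    pooled_residuals: np.ndarray
    resid_sd: float
    tech_variance: float

    @property
    def size(self) -> int:
        return int(self.member_mask.sum())


def _debiased_low_quantile_variance(variances: np.ndarray, df: int) -> float:
    """Technological-variance anchor.

    The 12.5th percentile (median of the lowest-variance quartile) of the
    per-gene sample variances, divided by the corresponding chi-square
    quantile of a chi2_df/df law so that the anchor is unbiased for the
    common variance when all genes share it.
    """
    q = float(np.quantile(variances, 0.125))
    return q / (stats.chi2.ppf(0.125, df) / df)


def select_reference_group(
    control: ExpressionMatrix,
    expressed: np.ndarray,
    alpha_F: float = 0.05,
    min_size: int = 100,
) -> ReferenceGroup:
    """Select expressed genes with inherently low variability by F-test.

    Per-gene residual variances (log2 scale, control group) are compared
    with a technological-variance anchor estimated from the lowest-variance
    quartile; genes below the F critical value at ``alpha_F`` are admitted
    and their residuals pooled.
    """
    n = control.n_samples
    if n < 2:
        raise ValidationError("need >= 2 control samples")
    expressed = np.asarray(expressed, dtype=bool)
    logv = _log_scale(control.values)
    variances = logv.var(axis=1, ddof=1)
    df = n - 1
    expr_vars = variances[expressed]
    if expr_vars.size < min_size:
        raise ValidationError(
            f"only {expr_vars.size} expressed genes; cannot build a reference group"
        )
    tech_var = _debiased_low_quantile_variance(expr_vars, df)
    n_quartile = max(int(expr_vars.size // 4), 1)
    crit = stats.f.ppf(1.0 - alpha_F, df, df * n_quartile)
    member = expressed & (variances <= tech_var * crit)
    size = int(member.sum())
    if size < min_size:
        raise ValidationError(
            f"reference group has {size} members (< {min_size}); "
            "adjust alpha_F (a smaller value admits more genes) or lower the floor"
        )
    resid = logv[member] - logv[member].mean(axis=1, keepdims=True)
    pool = resid.ravel()
    return ReferenceGroup(
        control.gene_ids[member], member, pool, float(pool.std(ddof=1)), float(tech_var)
    )


def associative_test(residuals: np.ndarray, reference: ReferenceGroup) -> float:
    """p-value of the associative t-test for one gene.

    The gene's n experimental residuals are compared with the entire pooled
    reference residual set by a standard pooled-variance two-sample t-test
    with unequal sample sizes.  Small p rejects the hypothesis that the
    gene's residuals associate with the reference distribution.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValidationError("associative_test needs >= 2 residuals")
    pool = reference.pooled_residuals
    _, p = _pooled_t_rows(
        r.mean(), r.var(ddof=1), r.size, pool.mean(), pool.var(ddof=1), pool.size
    )
    return float(p)


def exclude_hypervariable(
    control: ExpressionMatrix,
    experimental: ExpressionMatrix,
    alpha_F: float = 0.01,
    expression_threshold: float = 3.0,
) -> np.ndarray:
    """Flag genes whose within-group variability is hyper-technological.

    The pooled within-group variance (log2 scale, both groups; a genuine
    expression change shifts the mean but not the within-group variance) is
    compared against the technological-variance anchor; expressed genes
    exceeding the upper-tail F critical value at ``alpha_F`` are flagged
    (variability below the background threshold is detector noise, not
    hypervariability, so non-expressed genes are never flagged).  The mask
    can be passed to :func:`associative_analysis` to drop the flagged genes
    from both the selection and the evaluation denominator.
    """
    n1, n2 = control.n_samples, experimental.n_samples
    lc = _log_scale(control.values)
    le = _log_scale(experimental.values)
    v1 = lc.var(axis=1, ddof=1)
    v2 = le.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    expressed = expressed_mask(control, expression_threshold)
    if int(expressed.sum()) < 50:
        return np.zeros(control.n_genes, dtype=bool)
    anchor = _debiased_low_quantile_variance(vp[expressed], df)
    n_quartile = max(int(expressed.sum() // 4), 1)
    crit = stats.f.ppf(1.0 - alpha_F, df, df * n_quartile)
    return expressed & (vp > anchor * crit)


def _fold_and_direction(
    mean_control: np.ndarray, mean_experimental: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Direction-signed fold on the background-SD scale.

    Fold = larger mean / smaller mean, with the denominator floored at one
    background-SD unit (ratios of near-background means are meaningless)
    and the fold itself floored at 1.
    """
    hi = np.maximum(mean_control, mean_experimental)
    lo = np.maximum(np.minimum(mean_control, mean_experimental), 1.0)
    fold = np.maximum(hi / lo, 1.0)
    direction = np.where(
        mean_experimental > mean_control, "up",
        np.where(mean_experimental < mean_control, "down", "none"),
    ).astype(object)
    return fold, direction


def apply_restrictions(
    result: pd.DataFrame,
    restrictions: AnalysisRestrictions,
    n_genes_tested: int,
) -> pd.DataFrame:
    """Final selection: both tests plus the fold and expression restrictions.

    selected iff p_student < alpha_student, p_assoc < alpha_assoc /
    n_genes_tested (Bonferroni), fold >= Fa and max(mean) >= Em.  The
    ``reasons`` column records every failed criterion (comma-separated,
    subset of ``student,assoc,fold,expression,excluded``); ``direction`` is
    reported for selected genes only.
    """
    out = result.copy()
    thr_assoc = restrictions.alpha_assoc / max(int(n_genes_tested), 1)
    fail_student = ~(out["p_student"] < restrictions.alpha_student)
    fail_assoc = ~(out["p_assoc"] < thr_assoc)
    fail_fold = ~(out["fold"] >= restrictions.Fa)
    fail_expr = ~(
        np.maximum(out["mean_control"], out["mean_experimental"]) >= restrictions.Em
    )
    excluded = out["excluded"].to_numpy(dtype=bool) if "excluded" in out else np.zeros(len(out), bool)

    reasons = []
    for st, asc, fo, ex, drop in zip(fail_student, fail_assoc, fail_fold, fail_expr, excluded):
        r = []
        if drop:
            r.append("excluded")
        else:
            if st:
                r.append("student")
            if asc:
                r.append("assoc")
            if fo:
                r.append("fold")
            if ex:
                r.append("expression")
        reasons.append(",".join(r))
    out["reasons"] = reasons
    out["selected"] = [not r for r in reasons]
    out.loc[~out["selected"], "direction"] = "none"
    return out


def associative_analysis(
    control: ExpressionMatrix,
    experimental: ExpressionMatrix,
    restrictions: AnalysisRestrictions | None = None,
    alpha_F: float = 0.05,
    expression_threshold: float = 3.0,
    reference_floor: int = 100,
    exclude: np.ndarray | str | None = "auto",
) -> pd.DataFrame:
    """Full associative pipeline on normalized control/experimental matrices.

    ``exclude`` is ``"auto"`` (flag hypervariable genes internally — the
    recommended treatment, since genes with inherently extreme variability
    cannot be selected by any realistic replicate-based test and only
    corrupt both selection and scoring), ``None`` (analyse every gene) or a
    boolean mask.  Excluded genes are never selected, are dropped from the
    Bonferroni denominator, and carry ``excluded=True`` in the result so
    that evaluation can remove them from its denominators as well.
    """
    if restrictions is None:
        restrictions = AnalysisRestrictions()
    if not np.array_equal(control.gene_ids, experimental.gene_ids):
        raise ValidationError("control and experimental gene IDs disagree")
    if control.n_samples < 2 or experimental.n_samples < 2:
        raise ValidationError("need >= 2 replicates per group")

    if isinstance(exclude, str):
        if exclude != "auto":
            raise ValidationError(f"unknown exclude option {exclude!r}")
        excluded = exclude_hypervariable(
            control, experimental, expression_threshold=expression_threshold
        )
    elif exclude is None:
        excluded = np.zeros(control.n_genes, dtype=bool)
    else:
        excluded = np.asarray(exclude, dtype=bool)

    expressed = expressed_mask(control, expression_threshold)
    reference = select_reference_group(
        control, expressed & ~excluded, alpha_F=alpha_F, min_size=reference_floor
    )

    lc = _log_scale(control.values)
    le = _log_scale(experimental.values)
    n1, n2 = control.n_samples, experimental.n_samples

    _, p_student = _pooled_t_rows(
        lc.mean(axis=1), lc.var(axis=1, ddof=1), n1,
        le.mean(axis=1), le.var(axis=1, ddof=1), n2,
    )

    resid = le - lc.mean(axis=1, keepdims=True)
    pool = reference.pooled_residuals
    _, p_assoc = _pooled_t_rows(
        resid.mean(axis=1), resid.var(axis=1, ddof=1), n2,
        float(pool.mean()), float(pool.var(ddof=1)), pool.size,
    )

    mean_control = control.row_means()
    mean_experimental = experimental.row_means()
    fold, direction = _fold_and_direction(mean_control, mean_experimental)

    result = pd.DataFrame(
        {
            "gene_id": control.gene_ids,
            "mean_control": mean_control,
            "mean_experimental": mean_experimental,
            "fold": fold,
            "direction": direction,
            "p_student": p_student,
            "p_assoc": p_assoc,
            "selected": False,
            "reasons": "",
            "excluded": excluded,
        }
    )
    return apply_restrictions(result, restrictions, int((~excluded).sum()))


def ttest_bh_baseline(
    control: ExpressionMatrix,
    experimental: ExpressionMatrix,
    alpha: float = 0.05,
    fold_min: float = 1.5,
) -> pd.DataFrame:
    """Welch t-test + Benjamini-Hochberg + fold filter (comparator).

    The t-test runs on the log2 scale; the fold filter uses the same
    floored ratio of linear means as the associative pipeline.
    """
    from statsmodels.stats.multitest import multipletests

    if not np.array_equal(control.gene_ids, experimental.gene_ids):
        raise ValidationError("control and experimental gene IDs disagree")
    lc = _log_scale(control.values)
    le = _log_scale(experimental.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(lc, le, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    mean_control = control.row_means()
    mean_experimental = experimental.row_means()
    fold, direction = _fold_and_direction(mean_control, mean_experimental)
    selected = (q < alpha) & (fold >= fold_min)
    result = pd.DataFrame(
        {
            "gene_id": control.gene_ids,
            "mean_control": mean_control,
            "mean_experimental": mean_experimental,
            "fold": fold,
            "direction": np.where(selected, direction, "none"),
            "p_student": p,
            "p_assoc": q,
            "selected": selected,
            "reasons": np.where(selected, "", "baseline"),
            "excluded": False,
        }
    )
    return result


# ---------------------------------------------------------------------------
# DE-method registry (hosts external gene lists as methods)
# ---------------------------------------------------------------------------

DEMethod = Callable[[ExpressionMatrix, ExpressionMatrix, AnalysisRestrictions], pd.DataFrame]

_REGISTRY: dict[str, DEMethod] = {}


def register_de_method(name: str, fn: DEMethod) -> None:
    if name in _REGISTRY:
        raise ValidationError(f"DE method {name!r} is already registered")
    _REGISTRY[name] = fn


def get_de_method(name: str) -> DEMethod:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown DE method {name!r}; available: {', '.join(list_de_methods())}"
        ) from None


def list_de_methods() -> list[str]:
    return sorted(_REGISTRY)


def de_method_from_file(path: str | Path) -> DEMethod:
    """Wrap an external gene list (TSV: gene_id, optional direction) as a method.

    Lets selections produced by tools not re-implemented here (e.g. SAM or
    moderated-t pipelines run elsewhere) enter the same evaluation harness.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in table.columns:
        raise ValidationError(f"{path}: need a 'gene_id' column")
    directions = (
        dict(zip(table["gene_id"], table["direction"]))
        if "direction" in table.columns
        else {g: "none" for g in table["gene_id"]}
    )

    def method(control, experimental, restrictions):
        mean_control = control.row_means()
        mean_experimental = experimental.row_means()
        fold, _ = _fold_and_direction(mean_control, mean_experimental)
        selected = np.array([g in directions for g in control.gene_ids])
        direction = np.array(
            [directions.get(g, "none") for g in control.gene_ids], dtype=object
        )
        return pd.DataFrame(
            {
                "gene_id": control.gene_ids,
                "mean_control": mean_control,
                "mean_experimental": mean_experimental,
                "fold": fold,
                "direction": direction,
                "p_student": np.nan,
                "p_assoc": np.nan,
                "selected": selected,
                "reasons": np.where(selected, "", "external"),
                "excluded": False,
            }
        )

    return method


register_de_method(
    "associative",
    lambda control, experimental, restrictions: associative_analysis(
        control, experimental, restrictions
    ),
)
register_de_method(
    "ttest_bh",
    lambda control, experimental, restrictions: ttest_bh_baseline(
        control, experimental,
        alpha=restrictions.alpha_student, fold_min=restrictions.Fa,
    ),
)
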