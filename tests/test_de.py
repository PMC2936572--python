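"""Associative analysis: reference group, tests, restrictions, baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from debench import (
    AnalysisRestrictions,
    ReferenceGroup,
    SimulationConfig,
    ValidationError,
    apply_restrictions,
    associative_analysis,
    associative_test,
    de_method_from_file,
    exclude_hypervariable,
    get_de_method,
    list_de_methods,
    register_de_method,
    select_reference_group,
    simulate_homogeneous_group,
    sort_by_mean,
    split_group,
    student_filter,
    ttest_bh_baseline,
    two_step_normalize,
)

from conftest import make_matrix


def reference_from_pool(pool):
    pool = np.asarray(pool, dtype=float)
    return ReferenceGroup(
        gene_ids=np.array(["r"], dtype=object),
        member_mask=np.array([True]),
        pooled_residuals=pool,
        resid_sd=float(pool.std(ddof=1)),
        tech_variance=float(pool.var(ddof=1)),
    )


class TestStudentFilter:
    def test_matches_closed_form(self):
        ctrl = [10, 12, 11, 13, 9]
        exp = [20, 22, 21, 23, 19]
        p, passed = student_filter(ctrl, exp)
        oracle = stats.ttest_ind(ctrl, exp, equal_var=True).pvalue
        assert p == pytest.approx(oracle, abs=1e-10)
        assert passed

    def test_identical_groups_fail(self):
        p, passed = student_filter([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-12)
        assert not passed

    def test_zero_variance_conventions(self):
        p_sep, passed = student_filter([0, 0, 0, 0, 0], [5, 5, 5, 5, 5])
        assert p_sep == 0.0 and passed
        p_eq, passed = student_filter([2, 2, 2], [2, 2, 2])
        assert p_eq == 1.0 and not passed

    def test_needs_two_replicates(self):
        with pytest.raises(ValidationError):
            student_filter([1.0], [2.0, 3.0])


class TestAssociativeTest:
    def test_zero_residuals_symmetric_pool(self, rng):
        pool = rng.normal(0, 1, 10_000)
        pool = np.concatenate([pool, -pool])  # exactly symmetric around 0
        p = associative_test(np.zeros(5), reference_from_pool(pool))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_strong_deviation_vanishing_p(self, rng):
        pool = rng.normal(0, 1, 1000)
        ref = reference_from_pool(pool)
        p = associative_test(np.full(10, 10 * ref.resid_sd), ref)
        assert p < 1e-15

    def test_equals_two_sample_t_oracle(self, rng):
        pool = rng.normal(0, 1, 500)
        resid = rng.normal(0.5, 1, 5)
        p = associative_test(resid, reference_from_pool(pool))
        oracle = stats.ttest_ind(resid, pool, equal_var=True).pvalue
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_needs_two_residuals(self):
        with pytest.raises(ValidationError):
            associative_test([0.1], reference_from_pool(np.arange(10.0)))


class TestReferenceGroup:
    def test_null_calibration(self, rng):
        """All genes i.i.d. equal-variance noise: ~(1 - alpha_F) admitted."""
        values = 100 + rng.normal(0, 3, (3000, 10))
        m = make_matrix(values)
        ref = select_reference_group(m, np.ones(3000, bool), alpha_F=0.05)
        frac = ref.size / 3000
        assert 0.90 < frac < 0.985

    def test_high_variance_gene_excluded(self, rng):
        values = 100 + rng.normal(0, 3, (1000, 10))
        values[0] = 100 + rng.normal(0, 30, 10)
        m = make_matrix(values)
        ref = select_reference_group(m, np.ones(1000, bool))
        assert not ref.member_mask[0]

    def test_pool_size_bookkeeping(self, rng):
        values = 100 + rng.normal(0, 3, (500, 8))
        m = make_matrix(values)
        ref = select_reference_group(m, np.ones(500, bool))
        assert ref.pooled_residuals.size == ref.size * 8

    def test_floor_error_advises_alpha(self, rng):
        values = 100 + rng.normal(0, 3, (300, 6))
        m = make_matrix(values)
        with pytest.raises(ValidationError, match="alpha_F"):
            select_reference_group(m, np.ones(300, bool), alpha_F=0.999999, min_size=100)


class TestApplyRestrictions:
    def make_row(self, **kw):
        base = dict(
            gene_id="g", mean_control=30.0, mean_experimental=60.0, fold=2.0,
            direction="up", p_student=1e-4, p_assoc=1e-9, selected=False,
            reasons="", excluded=False,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_fold_restriction(self):
        out = apply_restrictions(self.make_row(fold=1.4), AnalysisRestrictions(Fa=1.5), 100)
        assert not out.selected[0] and out.reasons[0] == "fold"

    def test_expression_restriction(self):
        out = apply_restrictions(
            self.make_row(mean_control=19.9, mean_experimental=19.9, fold=2.0),
            AnalysisRestrictions(Em=20.0), 100,
        )
        assert "expression" in out.reasons[0]

    def test_bonferroni_threshold(self):
        row = self.make_row(p_assoc=1e-4)
        assert apply_restrictions(row, AnalysisRestrictions(), 10).selected[0]
        out = apply_restrictions(row, AnalysisRestrictions(), 10_000)
        assert not out.selected[0] and out.reasons[0] == "assoc"

    def test_all_pass_selected_with_direction(self):
        out = apply_restrictions(self.make_row(), AnalysisRestrictions(), 100)
        assert out.selected[0] and out.direction[0] == "up" and out.reasons[0] == ""


class TestExcludeHypervariable:
    def make_pair(self, rng, n=2000, cv=0.1, n_hyper=0, cv_hyper=1.0):
        abundance = rng.lognormal(7.5, 1.0, n)
        cvs = np.full(n, cv)
        cvs[:n_hyper] = cv_hyper
        vals = abundance[:, None] * (1 + rng.normal(0, 1, (n, 20)) * cvs[:, None]) / 4
        c = make_matrix(np.clip(vals[:, :10], 0, None))
        e = make_matrix(np.clip(vals[:, 10:], 0, None))
        return c, e

    def test_flags_extreme_cv(self, rng):
        c, e = self.make_pair(rng, n_hyper=20, cv_hyper=1.0)
        mask = exclude_hypervariable(c, e)
        assert mask[:20].mean() > 0.9
        assert mask[20:].mean() < 0.1

    def test_null_calibration(self, rng):
        c, e = self.make_pair(rng)
        frac = exclude_hypervariable(c, e, alpha_F=0.05).mean()
        assert 0.005 < frac < 0.15


def normalized_null_pair(seed, n_genes=4000):
    m = simulate_homogeneous_group(
        SimulationConfig(n_genes=n_genes, n_samples=20, seed=seed)
    )
    normed = two_step_normalize(sort_by_mean(m))
    return split_group(normed, permutation_seed=seed)


class TestAssociativeAnalysis:
    def test_null_split_selects_almost_nothing(self):
        ctrl, exp = normalized_null_pair(seed=21)
        res = associative_analysis(ctrl, exp)
        assert int(res.selected.sum()) <= 5

    def test_selected_genes_satisfy_restrictions_exhaustively(self, benchmark_matrix):
        from debench import InjectionDesign, make_benchmark
        from debench.evaluation import _joint_normalize_and_split
        bench = make_benchmark(benchmark_matrix, InjectionDesign(), 1)
        ctrl, exp = _joint_normalize_and_split(bench, two_step_normalize)
        restrictions = AnalysisRestrictions()
        res = associative_analysis(ctrl, exp, restrictions)
        sel = res[res.selected]
        assert len(sel) > 2000
        assert (sel.fold >= restrictions.Fa).all()
        assert (np.maximum(sel.mean_control, sel.mean_experimental) >= restrictions.Em).all()
        assert (sel.p_student < restrictions.alpha_student).all()
        n_tested = int((~res.excluded).sum())
        assert (sel.p_assoc < restrictions.alpha_assoc / n_tested).all()
        assert set(sel.direction) <= {"up", "down"}

    def test_misaligned_matrices_rejected(self, rng):
        a = make_matrix(rng.normal(100, 5, (300, 4)), gene_ids=[f"a{i}" for i in range(300)])
        b = make_matrix(rng.normal(100, 5, (300, 4)), gene_ids=[f"b{i}" for i in range(300)])
        with pytest.raises(ValidationError, match="gene IDs"):
            associative_analysis(a, b)


class TestTTestBHBaseline:
    def test_null_selects_nothing(self):
        ctrl, exp = normalized_null_pair(seed=33)
        res = ttest_bh_baseline(ctrl, exp)
        assert int(res.selected.sum()) <= 2

    def test_planted_separation_found(self, rng):
        vals = 100 + rng.normal(0, 1, (500, 8))
        exp_vals = vals[:, 4:].copy()
        exp_vals[:10] *= 3.0
        c = make_matrix(vals[:, :4])
        e = make_matrix(exp_vals)
        res = ttest_bh_baseline(c, e)
        assert res.selected[:10].all()
        assert int(res.selected[10:].sum()) == 0

    def test_raw_p_matches_welch(self, rng):
        c = make_matrix(rng.normal(100, 5, (50, 6)))
        e = make_matrix(rng.normal(100, 5, (50, 6)))
        res = ttest_bh_baseline(c, e)
        lc = np.log2(np.maximum(c.values, 1.0))
        le = np.log2(np.maximum(e.values, 1.0))
        oracle = stats.ttest_ind(lc[7], le[7], equal_var=False).pvalue
        assert res.p_student[7] == pytest.approx(oracle, abs=1e-10)


class TestDERegistry:
    def test_builtins(self):
        assert {"associative", "ttest_bh"} <= set(list_de_methods())

    def test_duplicate_rejected(self):
        with pytest.raises(ValidationError, match="already registered"):
            register_de_method("associative", lambda c, e, r: None)

    def test_external_gene_list_as_method(self, tmp_path, rng):
        path = tmp_path / "list.tsv"
        path.write_text("gene_id\tdirection\ng1\tup\ng3\tdown\n")
        method = de_method_from_file(path)
        c = make_matrix(rng.normal(100, 5, (5, 3)), gene_ids=[f"g{i}" for i in range(5)])
        e = make_matrix(rng.normal(100, 5, (5, 3)), gene_ids=[f"g{i}" for i in range(5)])
        res = method(c, e, AnalysisRestrictions())
        assert list(res.selected) == [False, True, False, True, False]
        assert res.direction[1] == "up" and res.direction[3] == "down"


class TestQualitativeProperties:
    def test_exclusion_raises_sensitivity_on_remaining_genes(self):
        """On data salted with genes too variable for any replicate-based
        test to select, dropping them from both selection and denominator
        improves the sensitivity computed on what remains."""
        from debench import (
            InjectionDesign, SimulationConfig, confusion, make_benchmark,
            metrics, simulate_matrix,
        )
        from debench.evaluation import _joint_normalize_and_split

        matrix, _ = simulate_matrix(SimulationConfig.benchmark_default(
            n_genes=5000, n_samples=8, frac_hypervariable=0.08, cv_hyper=2.0, seed=19,
        ))
        design = InjectionDesign(block_size=500, top_block_split=100)
        bench = make_benchmark(matrix, design, 2)
        ctrl, exp = _joint_normalize_and_split(bench, two_step_normalize)
        with_excl = associative_analysis(ctrl, exp, exclude="auto")
        without = associative_analysis(ctrl, exp, exclude=None)
        sens_with = metrics(confusion(with_excl, bench.truth))["sensitivity"]
        sens_without = metrics(confusion(without, bench.truth))["sensitivity"]
        assert sens_with > sens_without

    def test_sensitivity_monotone_in_fd(self):
        """Larger injected folds are easier to recover (3-seed average)."""
        from debench import InjectionDesign, SimulationConfig, evaluate_repeats, simulate_matrix

        matrix, _ = simulate_matrix(
            SimulationConfig.benchmark_default(n_genes=4000, n_samples=12, seed=6)
        )
        sens = []
        for fd in (1.6, 3.0):
            s = evaluate_repeats(
                matrix, InjectionDesign(Fd=fd, block_size=500, top_block_split=100),
                n_repeats=3, base_seed=31, n_blocks=10,
            )
            sens.append(s.overall["sensitivity"]["mean"])
        assert sens[0] <= sens[1]
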