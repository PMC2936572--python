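# Methods

This note records the statistical model behind `debench`, the parameters
that matter, and the design choices made where the procedure left room for
them. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The benchmark construction

A homogeneous group of `S` arrays (no systematic between-sample structure)
is sorted by average gene expression and split into equal control and
experimental halves; the split order is a seeded random permutation of the
samples, so repeating the procedure with different seeds yields mean ± SD
for every reported figure. Controlled fold changes are then multiplied
into the experimental half:

* genes are partitioned into consecutive blocks of 1000 along the sort;
* in the balanced design, `fraction/2` of each block is multiplied by `Fd`
  (labelled *up*) and a disjoint `fraction/2` divided by `Fd` (*down*);
* the top 1000 genes are treated at finer resolution — five 200-gene
  sub-blocks, each receiving its own up/down quota — because the dynamic
  range at the highest expression levels is widest there;
* the asymmetric design multiplies only (the case that breaks rank- and
  trend-based normalizers); a custom design takes separate up/down
  fractions and fold factors.

Within each block the default placement gives the highest-mean genes the
up labels and the next tier the down labels; a seeded random placement is
available. Ties in the mean sort are resolved by a stable sort on input
order. A trailing partial block receives floor-scaled quotas; with
20,000 genes and 1000-gene blocks this case does not arise. Injection
operates on raw intensities, before any normalization, and every
unmodified value is bit-identical to the input — un-injecting (divide the
up genes, multiply the down genes) restores the input to the last ulp.

Assumption to keep in mind: the scoring treats every post-split difference
as caused by the injection. Genuinely hypervariable genes violate this
(they differ between arbitrary halves of even the most homogeneous group),
which is why the analysis can flag and exclude them (§3).

## 2. Two-step internal-standard normalization

**Step one — background standardization.** The non-expressed genes of an
array form a background cohort that is approximately normal. Its
parameters are fitted by an iterative trimmed fit: starting from the
intensity mode (half-sample mode estimator) and the left-half MAD as the
initial spread, membership is recomputed as all values within
`Av ± 3·SD` of the current estimates until `(Av, SD)` change by less than
1e-6 relatively (at most 100 iterations; fewer than 50 members or zero
spread raises a degenerate-background error). Because a ±3 SD window
truncates the tails, the raw member SD underestimates the true SD by the
truncated-normal factor `sqrt(1 − 6·phi(3)/(2·Phi(3) − 1)) ≈ 0.9866`; the
fitted SD is divided by this factor inside the iteration so the admission
window is a true ±3 SD at the fixed point and a pure normal sample is
recovered without bias. The mode-anchored initialization (rather than,
say, the lower half of the sorted values) keeps the fit locked on the
background peak even when the background cohort is a minority of the
array — the regime of curated matrices where most retained probes carry
signal; it is validated down to ~10% background fraction.

The array is then transformed as `x → (x − Av)/SD`, putting all values in
background-SD units with the background at (0, 1). A gene is called
*expressed* when its mean standardized value exceeds 3 (three background
SDs above the background mean).

**Step two — robust regression adjustment.** Each standardized array is
regressed (ordinary least squares) on a reference profile over the
expressed genes, initialised to all of them; genes whose residual exceeds
3 residual-SD are dropped and the fit repeated until membership stabilises
— the same trimming logic as the background fit, now isolating a
homogeneous family of *equally expressed* genes with normally distributed
residuals. The final map `x → (x − intercept)/slope` is applied to every
gene of the array. The reference is the per-gene **median profile** of the
standardized arrays: symmetric in the arrays and robust to the injected
changes themselves (with 10 control + 10 experimental arrays, the median
of a modified gene is still anchored by the unmodified half). A
non-positive slope (anti-correlated array) or fewer than 30 surviving
genes aborts with an error. Adjusted values may be negative; no flooring
is applied — the expression restrictions downstream handle low values.
Both steps are strictly monotone per array, so within-array gene ranking
is preserved.

**Comparators.** Quantile normalization is the standard rank-mean method
(ties averaged). Lowess normalization removes the locally weighted trend
of `M = log2(array) − log2(reference)` against `A` (mean log intensity)
per array against the median profile, with span 0.3 and an offset of 1
before the log; both are deliberately conventional implementations of the
methods they stand for, and the registry accepts externally computed
matrices for anything else (e.g. a variance-stabilizing normalization run
in R).

## 3. Associative analysis

All variance machinery runs on `log2(max(x, 1))` of the standardized
values — the log scale with a floor of one background-SD unit. On this
scale the spread of a quantifiable gene's replicates is approximately its
coefficient of variation (plus an additive-noise term that fades above
~15 SD units), so variances are comparable across the full dynamic range;
on the linear scale a single "technological variance" anchor would be
meaningless, as multiplicative noise makes absolute residual variance grow
with the square of expression. Fold changes and the expression
restriction stay on the linear background-SD scale.

1. **Reference group.** Among expressed genes, per-gene control-group
   variances are compared against a technological-variance anchor — the
   12.5th percentile (the median of the lowest-variance quartile) of those
   variances, divided by `chi2.ppf(0.125, n−1)/(n−1)` so the anchor is
   unbiased for the common variance when genes share one. Genes whose
   variance ratio stays below the upper F critical value at `alpha_F`
   (default 0.05) are admitted; their residuals (deviations from their own
   control means) are pooled. With i.i.d. equal-variance data this admits
   ≈ 95% of genes; on realistic data it lands in the hundreds-to-thousands
   range. A floor (default 100 members) guards against a degenerate pool.
2. **Student filter.** Per gene, an equal-variance two-sample t-test
   between the groups at `alpha_student = 0.05` — the conventional
   sensitivity level, known to pass many false positives on its own.
   Zero pooled variance is a deterministic outcome: p = 1 for equal
   means, p = 0 otherwise.
3. **Associative t-test.** The gene's n experimental residuals from the
   control mean profile are t-tested (pooled variance, unequal sizes)
   against the entire reference pool (thousands of residuals). The
   threshold is Bonferroni-corrected, `alpha_assoc / n_tested`, rendering
   family-wise false positives improbable — the simplest correction
   consistent with that goal.
4. **Restrictions.** A gene is selected only if it also has
   `fold ≥ Fa` and `max(mean_ctrl, mean_exp) ≥ Em`. Fold is the ratio of
   the larger to the smaller group mean with the denominator floored at
   1 background-SD unit (ratios of near-background means carry no
   information); `Em` applies to the larger of the two means, so a gene
   whose experimental level rises out of the background can qualify.
   Every failed criterion is recorded per gene in `reasons`.

**Hypervariable exclusion.** Genes whose pooled within-group variance
(both groups; an expression *shift* does not inflate within-group
variance) exceeds the anchor's upper F critical value at `alpha_F = 0.01`
are flagged. Only expressed genes can be flagged — variability below the
background threshold is detector noise. By default
`associative_analysis` excludes flagged genes from testing, from the
Bonferroni denominator, and (via the `excluded` column) from the
evaluation denominators, reporting their count: a gene with inherently
extreme variability cannot be selected by any realistic replicate-based
test, and keeping such genes in the null would admit a handful of false
selections per split. Passing `exclude=None` analyses every gene.

**Baseline.** A Welch t-test + Benjamini–Hochberg + fold-filter pipeline
is included so evaluations always have a second, method-independent chain;
external gene lists (e.g. permutation-statistic or moderated-t selections
produced elsewhere) can be registered as DE methods from a two-column
file.

## 4. Evaluation conventions

True positives are selections among modified genes **with the matching
direction** (direction-strict, the default); a selected modified gene with
the wrong direction counts as a missed change (FN) *and* a spurious
selection (FP), and is reported separately as a direction error. A
lenient mode accepts any selection of a modified gene, for direction-blind
external methods. Metrics are exact integer-count ratios with NaN on 0/0.
Block profiles use 20 equal consecutive blocks of the sort order (the last
absorbs any remainder); per-block counts sum to the overall counts by
construction. Joint normalization of control + experimental arrays
precedes the DE step, as in real analyses.

The power analysis draws `n` replicates per subgroup **without
replacement** within each repeat (fresh split and fresh draw across
repeats): subsampling real replicates, not resampling them, is what the
question "how many arrays do I need?" asks. `n = S/2` reproduces the
full-design evaluation exactly.

## 5. The synthetic generator

Per gene `g` and array `s`:

    value = scale_s · abundance_g · (1 + delta_gs) + offset_s + eps_gs

with `eps ~ N(bg_mean, bg_sd²)` the additive background floor on *all*
genes, `abundance = 0` for background genes and lognormal
(`expr_log_mean`, `expr_log_sd`) for expressed genes,
`delta ~ N(0, cv²)` multiplicative biological noise, and per-array
distortions `scale ~ lognormal(0, array_scale_sd)`,
`offset ~ N(0, array_offset_sd²)`. Negative values are clipped at zero
(scanner behaviour; the clipped fraction is logged). Hypervariable genes
are an expressed subset with `cv_hyper` in place of `cv_bio` — the
simplest heavy-variance mechanism, symmetric by construction.

Defaults (chosen once, as a realistic bead-summarized array): 20,000
genes × 20 samples; background mean 100, SD 4 intensity units (a tight
floor, mean/SD = 25); expressed abundances lognormal with log-mean 7.5 and
log-SD 1.2 (median ≈ 1800, upper range ≈ 60,000 — a 16-bit scanner's
ceiling); `cv_bio = 0.1`; 1% hypervariable genes at CV 0.6; array gain SD
0.08 and offset SD 2. `frac_expressed` is 0.5 by default;
`SimulationConfig.benchmark_default()` raises it to 0.75, emulating a
curated benchmark matrix in which the clear majority of retained,
mean-sorted probes are quantifiable — the regime in which spike-in style
method comparisons are run — while keeping a genuine background floor in
the bottom blocks. Down-changes injected into pure-background genes are
undetectable in principle (halving noise leaves both group means below any
meaningful `Em`), so the background fraction directly caps overall
sensitivity; the block profile makes that cap visible instead of hiding
it.

What the generator does **not** emulate: probe-level bead structure,
spatial artifacts, batch effects beyond per-array linear distortion,
heavy-tailed or skewed biological noise, and correlated gene modules.
Passing tests on synthetic data therefore demonstrate correctness of the
machinery and calibration under the stated model, not performance on any
particular real platform — which is exactly why the benchmark accepts
real matrices as input.

## 6. Numerical choices and degenerate inputs

* Matrix I/O renders floats with 17 significant digits (lossless float64
  round-trip); truth tables use the 0/1/2 code convention (unchanged, up,
  down) so published supplementary tables converted to TSV load directly.
* Missing values are rejected, not imputed; the procedures assume complete
  matrices. Duplicate IDs, ragged rows and non-numeric cells are reported
  with coordinates.
* Gene order is the master alignment key; matrix/truth/result combinations
  re-validate gene-ID equality, never position alone.
* Convergence tolerances: 1e-6 relative for the background fit; exact
  membership stability for the regression trimming; both capped at 100
  iterations with the convergence flag exposed.
* Problem sizes in the test suite: full-scale checks (20,000 × 20, three
  repeats) for the headline chain; smaller matrices (2,000–5,000 genes)
  where only calibration or plumbing is exercised.

## 7. Known limitations

* The F-based reference selection assumes approximate homoscedasticity on
  the log scale; data with strong mean–variance trends beyond that (e.g.
  raw counts) should be transformed accordingly before entering the DE
  step.
* Bonferroni is deliberately conservative; the associative test's pooled
  reference makes per-gene tests dependent, so FDR-style corrections would
  need care.
* The lowess comparator uses one span (0.3) against the median profile; it
  is a representative implementation, not a re-creation of any specific
  published pipeline's settings.
* Balanced sample splits only (S even, equal halves); unbalanced designs
  are out of scope.
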