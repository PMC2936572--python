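# debench

Benchmark any normalization + differential-expression (DE) pipeline against
an exact, injected ground truth.

## The problem

Dozens of methods exist for pre-processing and analysing expression-array
data, and they routinely return different gene lists from the same matrix.
Comparing them objectively requires knowing, per gene, whether a reported
change is real — knowledge that real experiments do not provide and that
purely simulated data only provide at the cost of unrealistic structure.

`debench` implements the middle road: take a **homogeneous group of
samples** (real arrays, or the bundled realistic generator), sort the genes
by average expression, split the samples into equal *control* and
*experimental* halves, and multiply **controlled fold changes** into a known
fraction of the experimental half. The modified genes (AP-genes) and the
untouched remainder (AN-genes) form a complete ground truth while all the
microstructure of the data — expression profile, variance patterns,
outliers — is retained. Any chain of normalization and DE analysis can then
be scored exactly:

    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)

Because unmodified genes outnumber modified ones several-fold, Specificity
barely moves when false positives appear; Precision is reported alongside
Sensitivity as the symmetric headline pair. Metrics are computed overall,
within 20 equal blocks of the expression sort (performance as a function of
expression level), and as a function of replicate number (power analysis).

## What is included

* **Injection benchmark** — blocks of 1000 genes (the top block probed in
  five 200-gene sub-blocks); balanced (up + down), asymmetric (up only) and
  custom designs; repeated random sample splits for mean ± SD.
* **Two-step internal-standard normalization** — (1) iterative
  trimmed-normal fit of each array's background cohort, transforming the
  array to background-SD units with expression threshold at 3 SD; (2)
  robust linear regression of each array onto the median profile over an
  iteratively trimmed set of equally expressed genes.
* **Associative DE analysis** — a reference group of expressed,
  low-variability genes selected by F-test supplies a pooled residual
  standard of technical variation; each gene's experimental residuals are
  t-tested against that pool (Bonferroni-corrected), combined with a
  Student filter (p < 0.05) and minimal fold-change (`Fa`) and expression
  (`Em`) restrictions. Hypervariable genes can be flagged and excluded.
* **Comparators and plugins** — quantile and lowess (MA-trend)
  normalization, a Welch + Benjamini–Hochberg DE baseline, and registries
  that accept any external normalizer or gene list.
* **Synthetic data generator** — normal background cohort, lognormal
  expressed cohort spanning a wide dynamic range, per-array linear
  distortions, and a small hypervariable fraction; every module is testable
  without downloads.

## Worked example

```python
import debench as db

# a 20,000-gene, 20-sample homogeneous matrix (most probes quantifiable)
matrix, _ = db.simulate_matrix(db.SimulationConfig.benchmark_default(seed=1))

# 2-fold balanced changes in 20% of genes; three random splits;
# two-step normalization + associative analysis with Fa=1.5, Em=20
series = db.evaluate_repeats(
    matrix, db.InjectionDesign(Fd=2.0, fraction=0.20),
    normalizer="two_step", de_method="associative",
    restrictions=db.AnalysisRestrictions(Fa=1.5, Em=20.0),
    n_repeats=3, base_seed=7,
)
o = series.overall
print(f"sensitivity {o['sensitivity']['mean']:.3f} +- {o['sensitivity']['sd']:.3f}")
print(f"precision   {o['precision']['mean']:.3f} +- {o['precision']['sd']:.3f}")
```

prints

```
sensitivity 0.869 +- 0.000
precision   1.000 +- 0.000
```

Read: with 2-fold changes, 10 replicates per group and the default
restrictions, the chain recovers ~87% of the injected changes with
essentially no false selections. The per-block table
(`series.per_block`) shows Sensitivity 1.0 throughout the quantifiable
range; what is missed sits in the background blocks, where halved
intensities cannot clear the minimal-expression restriction — exactly the
kind of expression-level dependence the block profile exists to reveal.

The same chain is available from the shell:

```bash
debench simulate --out matrix.tsv --seed 1
debench evaluate --matrix matrix.tsv --normalizer two_step --de associative \
    --fd 2 --fraction 0.2 --fa 1.5 --em 20 --repeats 3 --seed 7 --out report.json
debench power --matrix matrix.tsv --n 2:10 --boot 3 --seed 7 --out power.json
```

`debench inject`, `normalize`, `analyze` and `compare` expose the
intermediate steps and side-by-side method comparisons; all file formats
are plain TSV/JSON.

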