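# Methods

## The analysis model

The pipeline implements a threshold-driven screen for epigenetic gene
silencing in tumor/normal cohorts. It makes no distributional assumptions
about the data beyond what the thresholds encode: methylation is summarized
per CpG by group statistics of the beta value (mean, maximum, linearly
interpolated 95th percentile), expression enters only through
log₂(x + 1)-transformed values in a Pearson correlation, and significance
is a fixed cut on the correlation (r < −0.2) and its two-sided t-test
p-value (p < 0.05, t = r·√((n−2)/(1−r²)) on n−2 df). There is no
per-site statistical test for differential methylation: a site is
hypermethylated iff mean β_normal ≤ 0.2 and mean β_tumor > 0.2, and
hypomethylated in the mirrored case. The 0.2 boundary is assigned exactly
as stated: β ≤ 0.2 counts as unmethylated, β > 0.2 as methylated.

A gene is *epigenetically silenced* in a cohort when at least one CpG
(configurable via `min_supporting_cpgs`) both survives the correlation
screen and satisfies P95(β_normal) < 0.2, P95(β_tumor) > 0.2 ∧
max(β_tumor) > 0.5, and mean(β_tumor) > 0.2 — the screen and the beta
criteria must hold on the *same* CpG, the stricter of the two readings the
gene-level rule admits. *Activated* is the mirror image. All criterion
inequalities are strict. Within a gene, a silencing call takes precedence
over an activation call; such conflicts are logged. Cross-cohort
aggregation is a plain count: genes with verdict `silenced` in at least
`min_cohorts` cohorts, sorted by descending count then gene id.

Enrichment is the exact hypergeometric upper tail
P(X ≥ k | N, K, n), accumulated from the log-pmf
(via log-gamma) with `logsumexp` for stability; `mode="ease"` substitutes
max(k−1, 0) for k, the conservative variant popularized by the DAVID
service. The default background is the union of the collection's members
intersected with the genes measured in the cohort; an explicit background
can be supplied. Significance is strict raw p < 0.05; Benjamini–Hochberg
adjusted values are reported alongside but do not drive the flag, because
the screening rules of this analysis are defined on raw p throughout.
(Enrichment screens of this kind are often run through the external DAVID
web service; this package implements the test itself so results need no
network and are exactly reproducible. Since DAVID's precise statistic and
background are service-internal, both standard and EASE modes are exposed
rather than asserting one.)

## Preprocessing conventions

* **Missingness filter**: a row is dropped when its missing fraction
  strictly exceeds 5% ("over 5%" read as > 0.05). Dropping is reported; an
  all-rows-dropped outcome raises a distinct `EmptyResultError`.
* **Imputation**: k-nearest-rows (k = 10, the convention of the standard
  array-imputation tooling), distance = nan-Euclidean over co-observed
  columns; the filled value is the mean of the k nearest rows' values in
  that column (distance ties broken by row order). With fewer than k
  eligible neighbors the row's own observed mean is used. k is exposed.
* **Quantile normalization**: classic reference = element-wise mean of the
  per-sample sorted values; entries tied within a sample receive the mean
  of the reference values at their tied ranks (deterministic, limma-style).
  Note the tie rule intentionally trades two textbook properties —
  "all columns share one multiset" and idempotence — which hold exactly
  only for tie-free columns; the test suite asserts them on continuous
  data. Beta values are clipped back to [0, 1] after normalization (they
  can exit the interval only by floating rounding). A single-column matrix
  is a no-op.
* **Stage order** is fixed: filter → impute → normalize (→ log₂(x+1) for
  expression). Imputation needs bounded missingness; normalization needs
  completeness. Each cohort is processed independently; matrices are never
  pooled across cancer types.
* **Correlation samples**: tumor + normal pooled by default (the beta-value
  range of published methylation–expression scatterplots spans both
  groups); a tumor-only mode is available (`correlation_samples: tumor`).
  No multiple-testing correction is applied by default in the screen; a BH
  option exists.

## The synthetic-cohort generator

The generator emulates the data regime the analysis assumes, with planted
ground truth:

* **Methylation**: each CpG/sample beta value is drawn from a Beta
  distribution parameterized by (mean m, concentration c), i.e.
  Beta(mc, (1−m)c), so values live in [0, 1] like array beta values.
  Defaults: unmethylated state m = 0.10, methylated state m = 0.45 — the
  two states straddle the 0.2 call threshold, and the methylated state
  puts the tumor maximum above 0.5 — and c = 100, giving the unmethylated
  state an sd of ≈ 0.03, typical per-probe noise for a 450K array.
* **Planted effects**: promoter (TSS200/TSS1500) CpGs of silenced genes are
  unmethylated in normals and methylated in tumors; reversed for activated
  genes; every other CpG sits at the unmethylated state in both groups.
  Every gene gets at least one promoter CpG.
* **Expression**: generated on the log₂ scale and mapped through
  max(2^y − 1, 0), so values are non-negative and right-skewed like RSEM
  estimates and the downstream log₂(x+1) transform is natural. For planted
  genes the per-sample log-expression is base − coupling · β_promoter +
  noise (defaults: base 8, coupling 4 log₂-units per beta unit, noise sd
  0.5); the link is per sample, not per group, so correlation screening
  has within-cohort signal. Neutral genes get uncoupled noise.
* **Missingness**: each matrix entry is masked with probability 0.01,
  uniformly at random.
* **Determinism**: one master seed; annotation, beta, expression and
  missingness draw from sub-streams derived via `numpy.random.SeedSequence`,
  so any matrix can be regenerated independently and results are identical
  across platforms.
* **Default cohort size**: 50 tumors, 20 normals, 200 genes × 3 CpGs, 30
  silenced + 10 activated. These sizes keep a full multi-cohort study in
  seconds on one CPU while leaving ≥ 1000 draws per methylation state for
  moment checks.

What the generator does **not** emulate: copy-number and purity effects,
batch effects, Infinium I/II probe-type chemistry, CpG-island structure,
correlated probes within a region, or realistic expression dispersion.
Passing recovery tests therefore demonstrates that the implementation
applies the criteria correctly under the assumed regime — not that the
thresholds are well-calibrated for real tumor data.

### A scale artifact worth knowing about

Quantile normalization assumes samples differ only technically. In a
simulated cohort of 600 CpGs where ~12% of sites are genuinely
differential between groups, forcing all samples onto one pooled
distribution measurably erodes the planted signal (silenced-call
sensitivity drops from ≈ 1.0 to ≈ 0.77). On a real 485k-site array the
differential fraction is negligible and the distortion vanishes. The
recovery benchmarks (tests and `scripts/acceptance.py`) therefore run the
calling chain on filtered + imputed but unnormalized matrices
(`Thresholds(normalize=False)`), while the pipeline default keeps
normalization on, matching the published procedure for real data.

Similarly, with the default 1% missing rate the strict >5% row filter
occasionally (P ≈ 0.006 per row at 70 samples) removes a planted gene's
entire expression row — harmless at transcriptome scale, but fatal to an
*exact*-recovery oracle over 5 × 30 gene-cohorts. Exact-recovery checks
therefore use `simulate.strong_effects`: state means 0.08 / 0.60, coupling
6, noise sd 0.3, no missingness. (Raising the beta concentration instead is
counterproductive: tighter tumor noise makes max(β_tumor) > 0.5 fail at
small n; the correct strong-effect axis is widening the state means.)
Sensitivity / false-positive benchmarks use the unmodified defaults.

## Numerical choices

* Percentiles use the linear-interpolation order statistic
  h = (n−1)q/100 + 1, v(⌊h⌋) + (h−⌊h⌋)(v(⌊h⌋+1) − v(⌊h⌋)) — the common
  statistical default — documented because percentile conventions change
  boundary calls at these sample sizes.
* Pearson |r| within 1e−14 of 1 is treated as the degenerate exact linear
  case (r = ±1, p = 0). Zero-variance vectors raise a distinct
  `ConstantInputError`; affected pairs are skipped and logged, never
  silently given r = 0. Minimum n is 3 (the p-value is undefined below).
* Hypergeometric tails: k at or below the support minimum returns exactly
  1.0; otherwise exp(logsumexp(log-pmf)) clipped to [0, 1].
* TSVs serialize missing values as `NA` and floats at full repr precision,
  so write → read round trips are lossless and reruns are byte-identical.

## Known limitations

* Thresholds are constants of the method, not estimated; no uncertainty is
  attached to gene verdicts.
* The correlation screen is linear and unregularized; heteroscedastic or
  nonlinear methylation–expression relationships are out of scope.
* Survival/prognosis association of silenced genes and protein-interaction
  network analysis are out of scope; figure rendering is not provided —
  the pipeline emits the underlying matrices as TSV only.
* Per-cohort runtimes scale as O(#annotation records × #samples) in the
  screen; the implementation loops per pair and targets cohort sizes of
  10³–10⁴ CpGs, not full-array scale.
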