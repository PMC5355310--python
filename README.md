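# methsilence

A tested, reusable pipeline for pan-cancer DNA-methylation / gene-expression
analysis on Illumina 450K-style beta values and RSEM-style expression
estimates. Given per-cohort (per cancer type) CpG-by-sample beta matrices,
gene-by-sample expression matrices, tumor/normal labels and a CpG-to-gene
annotation, it:

1. **Preprocesses** each cohort: drops rows with more than 5% missing
   entries, fills the rest by k-nearest-row imputation (k = 10), and
   quantile-normalizes samples.
2. **Calls differentially methylated CpG sites** from group means: a site is
   *hypermethylated* when mean β ≤ 0.2 in normals and mean β > 0.2 in
   tumors, *hypomethylated* in the mirrored case; calls are summarized by
   genomic region (TSS200, TSS1500, 5′UTR, 1st exon, gene body, 3′UTR).
3. **Screens CpG–gene correlations**: Pearson r between β and
   log₂(expression + 1) per annotated pair; pairs with r < −0.2 and
   p < 0.05 are significant negative associations.
4. **Classifies epigenetically silenced genes**: a gene is silenced in a
   cohort when at least one of its significantly anticorrelated CpGs
   satisfies all of
   * P95(β_normal) < 0.2,
   * P95(β_tumor) > 0.2 **and** max(β_tumor) > 0.5,
   * mean(β_tumor) > 0.2,

   where P95 is the linearly interpolated 95th percentile. *Epigenetically
   activated* genes are the mirror image (methylated in normal, unmethylated
   in tumor, expression up).
5. **Aggregates across cohorts**: genes silenced in ≥ *m* cancer types.
6. **Tests gene-set enrichment** of silenced-gene lists with an exact
   hypergeometric upper tail P(X ≥ k), computed in log space, with an
   optional EASE-style conservative variant (k → k−1), reading standard GMT
   collections.

Because consortium-scale tumor data cannot ship with a package, a
first-class **synthetic-cohort generator** produces fully labeled cohorts
with the statistical structure the analysis assumes — beta-distributed
methylation with distinct tumor/normal state means, expression negatively
coupled to promoter methylation for planted silenced/activated genes,
region-annotated CpGs, and missing values — so every stage is testable
end-to-end with known ground truth.

Intended users: computational epigenomics researchers who want a
reproducible, threshold-driven silencing screen, or a labeled benchmark
regime for one.

## Worked example

```python
from methsilence import (SimulationConfig, generate_cohort, filter_missing,
                         impute_knn, log_transform_expression, group_means,
                         call_sites, correlate_cpg_expression,
                         significant_negative, call_genes)
from methsilence.containers import BetaMatrix

cohort = generate_cohort(SimulationConfig(seed=1))   # 200 genes, 30 silenced, 10 activated
beta_vals = impute_knn(filter_missing(cohort.beta.values)[0])
expr = impute_knn(filter_missing(cohort.expression)[0])
expr_log = log_transform_expression(expr.clip(lower=0))
beta = BetaMatrix(beta_vals, cohort.beta.groups)

calls = call_sites(group_means(beta))
print(calls["status"].value_counts().to_dict())

sig = significant_negative(correlate_cpg_expression(beta, expr_log, cohort.annotation))
print(f"{len(sig)} significant negative CpG-gene pairs")

gene_calls = call_genes(beta, sig, cohort.annotation, "demo")
verdicts = [c.verdict for c in gene_calls]
print(f"silenced: {verdicts.count('silenced')}, activated: {verdicts.count('activated')}")
```

prints

```
{'none': 530, 'hyper': 49, 'hypo': 18}
75 significant negative CpG-gene pairs
silenced: 30, activated: 9
```

The 49 hypermethylated sites are (mostly) the promoter CpGs of the 30
planted silenced genes (some genes carry more than one promoter CpG); all
30 planted silenced genes are recovered, with no false positives among the
170 non-silenced genes, and 9 of the 10 planted activated genes are
recovered. Each verdict carries its CpG evidence, e.g. for `GENE0001`:

```
cg00000002  r=-0.785  p=8.62e-16  p95_normal=0.150  max_tumor=0.593  mean_tumor=0.464
```

## Command line

```bash
methsilence simulate --out sim/ --seed 4          # write a labeled synthetic cohort
methsilence run --config study.yaml               # full multi-cohort study
methsilence preprocess|call-sites|associate|call-genes|aggregate|enrich ...
```

`run` takes a YAML config listing cohorts (beta/expression/groups/annotation
paths) and thresholds, and writes per-cohort stage TSVs (`calls.tsv`,
`distribution.tsv`, `associations.tsv`, `gene_calls.tsv`, `summary.tsv`)
plus study-level `study_summary.tsv`, `shared_genes.tsv` and, when a GMT is
configured, enrichment tables. Outputs are deterministic: identical config
and inputs give byte-identical files.

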