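"""Synthetic multi-omic cohort generator with planted epigenetic effects.

Emulates the statistical regime the downstream analysis assumes: array-style
methylation beta values in [0, 1] drawn from a beta distribution with distinct
tumor/normal state means, RSEM-like non-negative expression generated on a
log2 scale, promoter methylation negatively coupled to expression for planted
silenced/activated genes, region-annotated CpGs, and missing entries. Every
gene carries a ground-truth label, so recall/precision of the full pipeline
is measurable without any external data.

Randomness: one master seed; each matrix (annotation, beta, expression,
missing masks) draws from its own stream derived via ``numpy.random.SeedSequence``
so partial regeneration is reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import io
from .containers import PROMOTER_REGIONS, REGIONS, BetaMatrix, CpGAnnotation

# stream indices for per-matrix substreams
_STREAM_ANNOTATION = 0
_STREAM_BETA = 1
_STREAM_EXPRESSION = 2
_STREAM_MISSING = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    The two state means straddle the 0.2 beta-value threshold used by the
    site caller, and ``meth_mean`` with realistic array noise puts the tumor
    maximum above the 0.5 silencing cutoff; ``beta_concentration`` is the
    precision of the beta distribution (variance = m(1-m)/(c+1)), set so the
    unmethylated state has sd ~0.03, typical of a 450K probe.
    ``coupling_strength`` is the log2-expression drop per unit of promoter
    beta for planted genes.
    """

    n_tumor: int = 50
    n_normal: int = 20
    n_genes: int = 200
    cpgs_per_gene: int = 3
    n_silenced: int = 30
    n_activated: int = 10
    unmeth_mean: float = 0.10
    meth_mean: float = 0.45
    beta_concentration: float = 100.0
    coupling_strength: float = 4.0
    base_log_expression: float = 8.0
    expression_noise_sd: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes", "n_silenced", "n_activated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cpgs_per_gene < 1:
            raise ValueError(f"cpgs_per_gene must be >= 1, got {self.cpgs_per_gene}")
        if self.n_silenced + self.n_activated > self.n_genes:
            raise ValueError(
                "n_silenced + n_activated exceeds n_genes "
                f"({self.n_silenced} + {self.n_activated} > {self.n_genes})"
            )
        for name in ("unmeth_mean", "meth_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.beta_concentration <= 0:
            raise ValueError(f"beta_concentration must be > 0, got {self.beta_concentration}")
        if self.expression_noise_sd < 0:
            raise ValueError(f"expression_noise_sd must be >= 0, got {self.expression_noise_sd}")


@dataclass
class SyntheticCohort:
    """A fully labeled cohort: matrices, annotation, and per-gene truth."""

    beta: BetaMatrix
    expression: pd.DataFrame
    annotation: CpGAnnotation
    truth: pd.Series  # gene -> {silenced, activated, neutral}
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _gene_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"GENE{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _truth_labels(config: SimulationConfig) -> pd.Series:
    genes = _gene_ids(config)
    labels = (
        ["silenced"] * config.n_silenced
        + ["activated"] * config.n_activated
        + ["neutral"] * (config.n_genes - config.n_silenced - config.n_activated)
    )
    return pd.Series(labels, index=genes, name="label")


def generate_annotation(config: SimulationConfig) -> CpGAnnotation:
    """Assign each of n_genes * cpgs_per_gene CpGs one gene and one region.

    Each gene gets at least one promoter-region (TSS200/TSS1500) CpG; the
    remaining CpGs draw a region uniformly from all six categories.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config, _STREAM_ANNOTATION)
    genes = _gene_ids(config)
    rows = []
    cpg_index = 0
    for gene in genes:
        promoter_slot = int(rng.integers(config.cpgs_per_gene))
        for j in range(config.cpgs_per_gene):
            cpg_index += 1
            if j == promoter_slot:
                region = str(rng.choice(PROMOTER_REGIONS))
            else:
                region = str(rng.choice(REGIONS))
            rows.append((f"cg{cpg_index:08d}", gene, region))
    return CpGAnnotation(pd.DataFrame(rows, columns=["cpg_id", "gene", "region"]))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate one tumor/normal cohort with planted silenced/activated genes.

    Promoter CpGs of planted silenced genes are unmethylated in normals and
    methylated in tumors (reversed for activated genes); every other CpG sits
    at the unmethylated state in both groups. Expression of planted genes
    follows a per-sample negative linear link between promoter beta and
    log2 expression with slope ``-coupling_strength``; neutral genes get
    uncoupled noise. ``missing_rate`` of the entries of each matrix are then
    masked to NaN uniformly at random.
    """
    annotation = generate_annotation(config)
    truth = _truth_labels(config)
    genes = list(truth.index)
    samples = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)] + [
        f"N{i:04d}" for i in range(1, config.n_normal + 1)
    ]
    groups = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal, index=samples, name="group"
    )
    is_tumor = np.array([g == "tumor" for g in groups.values])

    records = annotation.records
    cpg_ids = list(records["cpg_id"])
    n_cpgs = len(cpg_ids)
    n_samples = len(samples)

    # per-entry target mean: unmethylated everywhere except planted promoter CpGs
    mean = np.full((n_cpgs, n_samples), config.unmeth_mean)
    is_promoter = records["region"].isin(PROMOTER_REGIONS).to_numpy()
    gene_label = truth.loc[records["gene"]].to_numpy()
    sil_rows = is_promoter & (gene_label == "silenced")
    act_rows = is_promoter & (gene_label == "activated")
    mean[np.ix_(sil_rows, is_tumor)] = config.meth_mean
    mean[np.ix_(act_rows, ~is_tumor)] = config.meth_mean

    c = config.beta_concentration
    rng_beta = _rng(config, _STREAM_BETA)
    beta_vals = rng_beta.beta(mean * c, (1.0 - mean) * c)
    beta_df = pd.DataFrame(beta_vals, index=cpg_ids, columns=samples)

    # expression: planted genes coupled to their mean promoter beta per sample
    rng_expr = _rng(config, _STREAM_EXPRESSION)
    noise = rng_expr.normal(0.0, config.expression_noise_sd, size=(config.n_genes, n_samples))
    log_expr = np.full((config.n_genes, n_samples), config.base_log_expression) + noise
    for gi, gene in enumerate(genes):
        if truth[gene] == "neutral":
            continue
        promoter = annotation.promoter_cpgs_for_gene(gene)
        prom_beta = beta_df.loc[promoter].to_numpy().mean(axis=0)
        log_expr[gi] += -config.coupling_strength * prom_beta
    expr_vals = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
    expr_df = pd.DataFrame(expr_vals, index=genes, columns=samples)

    if config.missing_rate > 0:
        rng_miss = _rng(config, _STREAM_MISSING)
        beta_df = beta_df.mask(rng_miss.random(beta_df.shape) < config.missing_rate)
        expr_df = expr_df.mask(rng_miss.random(expr_df.shape) < config.missing_rate)

    return SyntheticCohort(
        beta=BetaMatrix(beta_df, groups),
        expression=expr_df,
        annotation=annotation,
        truth=truth,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> dict[str, str]:
    """Write beta/expression/annotation/groups/truth TSVs; returns the paths."""
    d = io.ensure_dir(directory)
    paths = {
        "beta": str(d / "beta.tsv"),
        "expression": str(d / "expression.tsv"),
        "annotation": str(d / "annotation.tsv"),
        "groups": str(d / "groups.tsv"),
        "truth": str(d / "truth.tsv"),
    }
    io.write_matrix(cohort.beta.values, paths["beta"], "cpg_id")
    io.write_matrix(cohort.expression, paths["expression"], "gene")
    io.write_annotation(cohort.annotation, paths["annotation"])
    io.write_groups(cohort.beta.groups, paths["groups"])
    io.write_truth(cohort.truth, paths["truth"])
    return paths


def replicate_configs(config: SimulationConfig, n_cohorts: int) -> list[SimulationConfig]:
    """Configs for n cohorts sharing the same planted genes but fresh noise."""
    return [replace(config, seed=config.seed + i) for i in range(n_cohorts)]


def strong_effects(config: SimulationConfig) -> SimulationConfig:
    """A strong-effect variant of a config, for exact-recovery oracles.

    Widens the tumor/normal contrast (0.08 vs 0.60 state means), strengthens
    the expression coupling, and removes missingness so no planted gene can
    be lost to row filtering or a chance criterion failure.
    """
    return replace(
        config,
        unmeth_mean=0.08,
        meth_mean=0.60,
        coupling_strength=6.0,
        expression_noise_sd=0.3,
        missing_rate=0.0,
    )
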