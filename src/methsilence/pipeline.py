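"""Per-cohort and cross-cohort orchestration.

``run_cohort`` sequences preprocess -> site calls -> association -> gene
classification for one cohort and persists every stage table as TSV plus a
machine-readable summary. ``run_study`` runs all cohorts (a failing cohort
aborts with a stage-tagged diagnostic without stopping the others),
aggregates silenced calls across cohorts, and tests enrichment per cohort
and on the shared-gene list. All thresholds live in one config with the
analysis' standard values as defaults; outputs are deterministic functions
of config + inputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, enrichment, gene_classifier, io, preprocess, site_calls
from .containers import BetaMatrix, GeneEpigeneticCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortPaths:
    """Input file locations for one cohort."""

    cohort_id: str
    beta: str
    expression: str
    groups: str
    annotation: str


@dataclass
class Thresholds:
    max_missing: float = 0.05
    knn_k: int = 10
    beta_threshold: float = 0.2
    r_cut: float = -0.2
    p_cut: float = 0.05
    silencing_low: float = 0.2
    silencing_high: float = 0.5
    min_supporting_cpgs: int = 1
    min_cohorts: int = 5
    enrichment_p_cut: float = 0.05
    enrichment_mode: str = "standard"
    correlation_samples: str = "pooled"
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing < 1:
            raise ValueError(f"max_missing must lie in [0, 1), got {self.max_missing}")
        if self.knn_k <= 0:
            raise ValueError(f"knn_k must be positive, got {self.knn_k}")
        if not 0 <= self.beta_threshold <= 1:
            raise ValueError(f"beta_threshold must lie in [0, 1], got {self.beta_threshold}")
        if not -1 <= self.r_cut <= 1:
            raise ValueError(f"r_cut must lie in [-1, 1], got {self.r_cut}")
        for name in ("p_cut", "enrichment_p_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_cohorts < 1:
            raise ValueError(f"min_cohorts must be >= 1, got {self.min_cohorts}")


@dataclass
class PipelineConfig:
    cohorts: list[CohortPaths]
    output_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    gmt: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("config must list at least one cohort")
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ValueError("cohort ids must be unique")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        cohorts = [
            CohortPaths(
                cohort_id=str(c["id"]),
                beta=c["beta"],
                expression=c["expression"],
                groups=c["groups"],
                annotation=c["annotation"],
            )
            for c in raw["cohorts"]
        ]
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            cohorts=cohorts,
            output_dir=raw["output_dir"],
            thresholds=thresholds,
            gmt=raw.get("gmt"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class CohortResult:
    cohort_id: str
    calls: pd.DataFrame
    distribution: pd.DataFrame
    associations: pd.DataFrame
    significant: pd.DataFrame
    gene_calls: list[GeneEpigeneticCall]
    summary: dict
    out_dir: Path


class StageError(RuntimeError):
    """A cohort stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cohort_id: str, cause: Exception):
        super().__init__(f"cohort {cohort_id}: stage {stage} failed: {cause}")
        self.stage = stage
        self.cohort_id = cohort_id
        self.cause = cause


def run_cohort(config: PipelineConfig, cohort: CohortPaths) -> CohortResult:
    """Execute all per-cohort stages and write their TSV artifacts."""
    t = config.thresholds
    out_dir = io.ensure_dir(Path(config.output_dir) / cohort.cohort_id)
    stage = "read-inputs"
    try:
        beta_raw = io.read_beta_values(cohort.beta)
        expr_raw = io.read_expression(cohort.expression)
        groups = io.read_groups(cohort.groups)
        annotation = io.read_annotation(cohort.annotation)

        stage = "preprocess"
        beta_vals, beta_dropped = preprocess.preprocess_beta(
            beta_raw, t.max_missing, t.knn_k, normalize=t.normalize
        )
        expr_log, expr_dropped = preprocess.preprocess_expression(
            expr_raw, t.max_missing, t.knn_k, normalize=t.normalize
        )
        beta = BetaMatrix(beta_vals, groups)
        logger.info(
            "cohort %s: preprocess kept %d/%d CpGs, %d/%d genes",
            cohort.cohort_id, beta_vals.shape[0], beta_raw.shape[0],
            expr_log.shape[0], expr_raw.shape[0],
        )

        stage = "site-calls"
        means = site_calls.group_means(beta)
        calls = site_calls.call_sites(means, t.beta_threshold)
        distribution = site_calls.region_distribution(calls, annotation)

        stage = "association"
        assoc = association.correlate_cpg_expression(
            beta, expr_log, annotation, samples=t.correlation_samples
        )
        significant = association.significant_negative(assoc, t.r_cut, t.p_cut)

        stage = "gene-classifier"
        gene_calls = gene_classifier.call_genes(
            beta, significant, annotation, cohort.cohort_id,
            t.silencing_low, t.silencing_high, t.min_supporting_cpgs,
        )
    except Exception as exc:  # noqa: BLE001 - re-tagged with the failing stage
        raise StageError(stage, cohort.cohort_id, exc) from exc

    verdicts = pd.Series([c.verdict for c in gene_calls])
    summary = {
        "cohort": cohort.cohort_id,
        "n_cpgs": int(calls.shape[0]),
        "n_hyper": int((calls["status"] == "hyper").sum()),
        "n_hypo": int((calls["status"] == "hypo").sum()),
        "n_associations": int(assoc.shape[0]),
        "n_significant_negative": int(significant.shape[0]),
        "n_genes": int(len(gene_calls)),
        "n_silenced": int((verdicts == "silenced").sum()),
        "n_activated": int((verdicts == "activated").sum()),
        "n_cpgs_dropped": len(beta_dropped),
        "n_genes_dropped": len(expr_dropped),
    }

    calls.to_csv(out_dir / "calls.tsv", sep="\t")
    distribution.to_csv(out_dir / "distribution.tsv", sep="\t", index=False)
    assoc_out = assoc.copy()
    sig_keys = set(map(tuple, significant[["cpg_id", "gene"]].itertuples(index=False)))
    assoc_out["significant"] = [
        int((c, g) in sig_keys) for c, g in assoc_out[["cpg_id", "gene"]].itertuples(index=False)
    ]
    assoc_out.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    gene_classifier.calls_to_frame(gene_calls).to_csv(
        out_dir / "gene_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(summary.items()), columns=["metric", "value"]).to_csv(
        out_dir / "summary.tsv", sep="\t", index=False
    )

    return CohortResult(
        cohort_id=cohort.cohort_id,
        calls=calls,
        distribution=distribution,
        associations=assoc_out,
        significant=significant,
        gene_calls=gene_calls,
        summary=summary,
        out_dir=out_dir,
    )


@dataclass
class StudyResult:
    cohort_results: dict[str, CohortResult]
    failures: dict[str, str]
    shared: pd.DataFrame
    study_summary: pd.DataFrame
    enrichment_tables: dict[str, pd.DataFrame]


def run_study(config: PipelineConfig) -> StudyResult:
    """Run every cohort, aggregate silenced genes, and test enrichment."""
    out_root = io.ensure_dir(config.output_dir)
    results: dict[str, CohortResult] = {}
    failures: dict[str, str] = {}
    for cohort in config.cohorts:
        try:
            results[cohort.cohort_id] = run_cohort(config, cohort)
        except StageError as exc:
            logger.error("%s", exc)
            failures[cohort.cohort_id] = str(exc)
    if not results:
        raise RuntimeError("all cohorts failed; study aborted")

    t = config.thresholds
    calls_by_cohort = {cid: r.gene_calls for cid, r in results.items()}
    summaries = gene_classifier.aggregate_across_cohorts(calls_by_cohort, t.min_cohorts)
    shared = gene_classifier.summaries_to_frame(summaries)
    shared.to_csv(out_root / "shared_genes.tsv", sep="\t", index=False)

    study_summary = pd.DataFrame(
        [
            (cid, r.summary["n_silenced"], r.summary["n_activated"])
            for cid, r in results.items()
        ],
        columns=["cohort", "n_silenced", "n_activated"],
    )
    study_summary.to_csv(out_root / "study_summary.tsv", sep="\t", index=False)

    enrichment_tables: dict[str, pd.DataFrame] = {}
    if config.gmt:
        collection = enrichment.read_gmt(config.gmt)
        for cid, r in results.items():
            silenced = sorted(c.gene for c in r.gene_calls if c.verdict == "silenced")
            measured = {c.gene for c in r.gene_calls}
            if not silenced:
                logger.info("cohort %s: no silenced genes; enrichment skipped", cid)
                continue
            try:
                table = enrichment.enrich(
                    silenced, collection, t.enrichment_p_cut, t.enrichment_mode,
                    measured=measured,
                )
            except ValueError as exc:
                logger.warning("cohort %s: enrichment skipped: %s", cid, exc)
                continue
            table.to_csv(r.out_dir / "enrichment.tsv", sep="\t", index=False)
            enrichment_tables[cid] = table
        if len(shared):
            measured = set().union(*({c.gene for c in r.gene_calls} for r in results.values()))
            try:
                table = enrichment.enrich(
                    list(shared["gene"]), collection, t.enrichment_p_cut,
                    t.enrichment_mode, measured=measured,
                )
                table.to_csv(out_root / "shared_enrichment.tsv", sep="\t", index=False)
                enrichment_tables["shared"] = table
            except ValueError as exc:
                logger.warning("shared-gene enrichment skipped: %s", exc)

    with open(out_root / "study_summary.json", "w") as handle:
        json.dump(
            {
                "cohorts": {cid: r.summary for cid, r in results.items()},
                "failures": failures,
                "n_shared_genes": int(len(shared)),
                "min_cohorts": t.min_cohorts,
            },
            handle,
            indent=2,
            sort_keys=True,
        )
    return StudyResult(
        cohort_results=results,
        failures=failures,
        shared=shared,
        study_summary=study_summary,
        enrichment_tables=enrichment_tables,
    )
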