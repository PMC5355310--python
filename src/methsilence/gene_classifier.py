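"""Percentile-based classification of epigenetically silenced/activated genes.

A gene is epigenetically silenced in a cohort when at least one of its CpGs
both survives the negative-correlation screen and satisfies, on its per-group
beta vectors, all three of:

  (a) 95th percentile of normal-tissue betas < 0.2
  (b) 95th percentile of tumor betas > 0.2 AND maximum tumor beta > 0.5
  (c) mean tumor beta > 0.2

Epigenetic activation is the mirror image with the group roles swapped. The
screen and the beta criteria must hold on the same CpG. All inequalities are
strict. Within a gene, silencing takes precedence over activation; conflicts
are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CpGAnnotation, CrossCohortSummary, GeneEpigeneticCall, SupportingCpG

logger = logging.getLogger(__name__)


def percentile(values, q: float) -> float:
    """Linear-interpolation order statistic.

    With sorted values v(1..n) and h = (n-1) * q/100 + 1, returns
    v(floor(h)) + (h - floor(h)) * (v(floor(h)+1) - v(floor(h))).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty vector")
    if not 0 <= q <= 100:
        raise ValueError(f"q must lie in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))


@dataclass(frozen=True)
class CriterionBreakdown:
    """Outcome of one silencing/activation evaluation with per-criterion detail."""

    passed: bool
    a: bool  # low-group 95th percentile < low cutoff
    b: bool  # high-group 95th percentile > low cutoff and max > high cutoff
    c: bool  # high-group mean > low cutoff
    p95_normal: float
    p95_tumor: float
    max_normal: float
    max_tumor: float
    mean_normal: float
    mean_tumor: float


def _beta_summaries(betas_normal, betas_tumor) -> dict[str, float]:
    bn = np.asarray(betas_normal, dtype=float)
    bt = np.asarray(betas_tumor, dtype=float)
    if bn.size == 0 or bt.size == 0:
        raise ValueError("both group beta vectors must be non-empty")
    return dict(
        p95_normal=percentile(bn, 95),
        p95_tumor=percentile(bt, 95),
        max_normal=float(bn.max()),
        max_tumor=float(bt.max()),
        mean_normal=float(bn.mean()),
        mean_tumor=float(bt.mean()),
    )


def silencing_criteria(
    betas_normal, betas_tumor, low_cut: float = 0.2, high_cut: float = 0.5
) -> CriterionBreakdown:
    """Unmethylated in normals, methylated in tumors (silencing direction)."""
    s = _beta_summaries(betas_normal, betas_tumor)
    a = s["p95_normal"] < low_cut
    b = s["p95_tumor"] > low_cut and s["max_tumor"] > high_cut
    c = s["mean_tumor"] > low_cut
    return CriterionBreakdown(passed=a and b and c, a=a, b=b, c=c, **s)


def activation_criteria(
    betas_normal, betas_tumor, low_cut: float = 0.2, high_cut: float = 0.5
) -> CriterionBreakdown:
    """Mirror image: methylated in normals, unmethylated in tumors."""
    s = _beta_summaries(betas_normal, betas_tumor)
    a = s["p95_tumor"] < low_cut
    b = s["p95_normal"] > low_cut and s["max_normal"] > high_cut
    c = s["mean_normal"] > low_cut
    return CriterionBreakdown(passed=a and b and c, a=a, b=b, c=c, **s)


def call_genes(
    beta: BetaMatrix,
    associations: pd.DataFrame,
    annotation: CpGAnnotation,
    cohort: str,
    low_cut: float = 0.2,
    high_cut: float = 0.5,
    min_supporting_cpgs: int = 1,
) -> list[GeneEpigeneticCall]:
    """Verdict per annotated gene from its significantly anticorrelated CpGs.

    ``associations`` must already be filtered by
    :func:`methsilence.association.significant_negative`; only those CpGs are
    tested against the beta criteria (screen and criteria on the same CpG).
    A gene is silenced with >= ``min_supporting_cpgs`` CpGs passing the
    silencing criteria; activated with that many passing activation and none
    passing silencing; otherwise none. Genes without annotated CpGs in the
    beta matrix get verdict none (logged, not an error).
    """
    if min_supporting_cpgs < 1:
        raise ValueError("min_supporting_cpgs must be >= 1")
    normal_samples = beta.samples_in_group("normal")
    tumor_samples = beta.samples_in_group("tumor")
    if not normal_samples or not tumor_samples:
        raise ValueError("both tumor and normal groups must be non-empty")

    assoc_by_gene: dict[str, pd.DataFrame] = (
        {g: sub for g, sub in associations.groupby("gene")} if len(associations) else {}
    )
    cpg_present = set(beta.values.index)

    calls: list[GeneEpigeneticCall] = []
    for gene in annotation.genes:
        if not set(annotation.cpgs_for_gene(gene)) & cpg_present:
            logger.info("gene %s has no annotated CpGs in the beta matrix", gene)
            calls.append(GeneEpigeneticCall(gene=gene, cohort=cohort, verdict="none"))
            continue
        silencing_support: list[SupportingCpG] = []
        activation_support: list[SupportingCpG] = []
        for row in assoc_by_gene.get(gene, pd.DataFrame()).itertuples(index=False):
            if row.cpg_id not in cpg_present:
                continue
            bn = beta.values.loc[row.cpg_id, normal_samples]
            bt = beta.values.loc[row.cpg_id, tumor_samples]
            sil = silencing_criteria(bn, bt, low_cut, high_cut)
            act = activation_criteria(bn, bt, low_cut, high_cut)
            evidence = SupportingCpG(
                cpg_id=row.cpg_id,
                r=float(row.r),
                p=float(row.p),
                p95_normal=sil.p95_normal,
                p95_tumor=sil.p95_tumor,
                max_tumor=sil.max_tumor,
                max_normal=sil.max_normal,
                mean_tumor=sil.mean_tumor,
                mean_normal=sil.mean_normal,
            )
            if sil.passed:
                silencing_support.append(evidence)
            if act.passed:
                activation_support.append(evidence)
        if len(silencing_support) >= min_supporting_cpgs:
            verdict, support = "silenced", silencing_support
            if activation_support:
                logger.warning(
                    "gene %s has CpGs passing both directions in cohort %s; "
                    "silenced takes precedence",
                    gene,
                    cohort,
                )
        elif len(activation_support) >= min_supporting_cpgs and not silencing_support:
            verdict, support = "activated", activation_support
        else:
            verdict, support = "none", []
        calls.append(
            GeneEpigeneticCall(gene=gene, cohort=cohort, verdict=verdict, supporting_cpgs=support)
        )
    return calls


def calls_to_frame(calls: list[GeneEpigeneticCall]) -> pd.DataFrame:
    """Flatten calls to a table: gene, cohort, verdict, best CpG and its stats."""
    rows = []
    for call in calls:
        if call.supporting_cpgs:
            best = min(call.supporting_cpgs, key=lambda s: (s.r, s.cpg_id))
            rows.append((call.gene, call.cohort, call.verdict, best.cpg_id, best.r, best.p))
        else:
            rows.append((call.gene, call.cohort, call.verdict, "", np.nan, np.nan))
    return pd.DataFrame(rows, columns=["gene", "cohort", "verdict", "best_cpg", "r", "p"])


def aggregate_across_cohorts(
    calls_by_cohort: dict[str, list[GeneEpigeneticCall]],
    min_cohorts: int = 5,
) -> list[CrossCohortSummary]:
    """Genes silenced in at least ``min_cohorts`` cohorts.

    Returns one summary per qualifying gene (its silenced and activated
    cohort sets), sorted by descending silenced-cohort count, then gene id.
    """
    if not calls_by_cohort:
        raise ValueError("at least one cohort required")
    if min_cohorts > len(calls_by_cohort):
        logger.warning(
            "min_cohorts=%d exceeds the %d available cohorts; result is empty",
            min_cohorts,
            len(calls_by_cohort),
        )
    silenced: dict[str, set[str]] = {}
    activated: dict[str, set[str]] = {}
    for cohort, calls in calls_by_cohort.items():
        for call in calls:
            if call.verdict == "silenced":
                silenced.setdefault(call.gene, set()).add(cohort)
            elif call.verdict == "activated":
                activated.setdefault(call.gene, set()).add(cohort)
    summaries = [
        CrossCohortSummary(
            gene=gene,
            cohorts_silenced=frozenset(cohorts),
            cohorts_activated=frozenset(activated.get(gene, set())),
        )
        for gene, cohorts in silenced.items()
        if len(cohorts) >= min_cohorts
    ]
    summaries.sort(key=lambda s: (-s.n_silenced, s.gene))
    return summaries


def summaries_to_frame(summaries: list[CrossCohortSummary]) -> pd.DataFrame:
    rows = [
        (s.gene, s.n_silenced, ",".join(sorted(s.cohorts_silenced))) for s in summaries
    ]
    return pd.DataFrame(rows, columns=["gene", "n_cohorts_silenced", "cohorts"])
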