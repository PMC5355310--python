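"""Per-CpG differential methylation calls from tumor/normal group means.

A site is hypermethylated when it is unmethylated in normal tissue (group
mean beta <= threshold) and methylated in tumor tissue (group mean beta >
threshold), and hypomethylated in the mirrored case. The default threshold
is a beta value of 0.2. No statistical test is involved; the calls are
purely threshold-based.
"""

from __future__ import annotations

import pandas as pd

from .containers import REGIONS, BetaMatrix, CpGAnnotation

STATUSES = ("hyper", "hypo", "none")
UNANNOTATED = "unannotated"


def group_means(beta: BetaMatrix) -> pd.DataFrame:
    """Arithmetic mean beta per CpG within each sample group.

    Returns a DataFrame indexed by cpg_id with columns
    ``mean_beta_normal`` and ``mean_beta_tumor``.
    """
    out = {}
    for group, col in (("normal", "mean_beta_normal"), ("tumor", "mean_beta_tumor")):
        samples = beta.samples_in_group(group)
        if not samples:
            raise ValueError(f"group {group!r} has zero samples")
        out[col] = beta.values[samples].mean(axis=1)
    return pd.DataFrame(out, index=beta.values.index)[["mean_beta_normal", "mean_beta_tumor"]]


def call_sites(means: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Assign each CpG a status in {hyper, hypo, none}.

    hyper  iff normal mean <= threshold and tumor mean > threshold;
    hypo   iff normal mean >  threshold and tumor mean <= threshold;
    none   otherwise. The boundary sits exactly at the threshold: <= is
    unmethylated, > is methylated.
    """
    normal = means["mean_beta_normal"]
    tumor = means["mean_beta_tumor"]
    status = pd.Series("none", index=means.index, name="status")
    status[(normal <= threshold) & (tumor > threshold)] = "hyper"
    status[(normal > threshold) & (tumor <= threshold)] = "hypo"
    calls = means.copy()
    calls["status"] = status
    calls.index.name = "cpg_id"
    return calls


def region_distribution(calls: pd.DataFrame, annotation: CpGAnnotation) -> pd.DataFrame:
    """Count annotation records per region among hyper- and hypomethylated CpGs.

    A CpG annotated to multiple (gene, region) records contributes one count
    per record; called CpGs absent from the annotation are tallied under
    ``unannotated``. Returns a tidy table (status, region, count) covering
    every (status in {hyper, hypo}) x (region + unannotated) cell, zeros
    included.
    """
    records = annotation.records
    rows = []
    for status in ("hyper", "hypo"):
        called = calls.index[calls["status"] == status]
        sub = records[records["cpg_id"].isin(called)]
        counts = sub["region"].value_counts()
        for region in REGIONS:
            rows.append((status, region, int(counts.get(region, 0))))
        n_unannotated = int((~called.isin(set(records["cpg_id"]))).sum())
        rows.append((status, UNANNOTATED, n_unannotated))
    return pd.DataFrame(rows, columns=["status", "region", "count"])
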