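"""CpG-gene correlation screening.

For every annotated (CpG, gene) pair present in both matrices, the Pearson
correlation between the CpG's beta values and the gene's log2(x+1)
expression is computed over samples matched by id (tumor and normal pooled
by default). Pairs with r < -0.2 and p < 0.05 (both strict) are the
significant negative associations fed to the gene classifier.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, ConstantInputError, CpGAnnotation

logger = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = ["cpg_id", "gene", "r", "p", "n"]


def pearson(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with a two-sided t-test p-value.

    p is derived from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; a degenerate |r| = 1 yields p = 0.

    Raises
    ------
    ConstantInputError
        If either vector has zero variance (correlation undefined).
    ValueError
        On unequal lengths or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if 1.0 - abs(r) < 1e-14:  # exact linear relation up to rounding
        return (1.0 if r > 0 else -1.0), 0.0, n
    return r, float(res.pvalue), n


def correlate_cpg_expression(
    beta: BetaMatrix,
    expr_log: pd.DataFrame,
    annotation: CpGAnnotation,
    samples: str = "pooled",
) -> pd.DataFrame:
    """One association record per annotated (CpG, gene) pair.

    Parameters
    ----------
    beta
        Complete beta matrix.
    expr_log
        Expression matrix already log2(x+1) transformed.
    samples
        ``"pooled"`` uses the tumor+normal sample intersection of the two
        matrices; ``"tumor"`` restricts to tumor samples.

    Pairs whose gene is absent from the expression matrix are skipped and
    logged, as are pairs with zero variance in either vector.
    """
    if samples not in ("pooled", "tumor"):
        raise ValueError(f"samples must be 'pooled' or 'tumor', got {samples!r}")
    shared = [s for s in beta.values.columns if s in set(expr_log.columns)]
    if not shared:
        raise ValueError("beta and expression matrices share no sample ids")
    if len(shared) < beta.values.shape[1] or len(shared) < expr_log.shape[1]:
        logger.warning(
            "sample sets differ; using intersection of %d samples", len(shared)
        )
    if samples == "tumor":
        shared = [s for s in shared if beta.groups[s] == "tumor"]
        if not shared:
            raise ValueError("no tumor samples in the shared sample set")

    beta_vals = beta.values[shared]
    expr_vals = expr_log[shared]
    expr_genes = set(expr_log.index)
    cpg_present = set(beta.values.index)

    rows = []
    for cpg_id, gene in annotation.records[["cpg_id", "gene"]].itertuples(index=False):
        if gene not in expr_genes:
            logger.info("gene %s absent from expression matrix; pair skipped", gene)
            continue
        if cpg_id not in cpg_present:
            logger.info("CpG %s absent from beta matrix; pair skipped", cpg_id)
            continue
        try:
            r, p, n = pearson(beta_vals.loc[cpg_id], expr_vals.loc[gene])
        except ConstantInputError:
            logger.info("constant vector for (%s, %s); pair skipped", cpg_id, gene)
            continue
        rows.append((cpg_id, gene, r, p, n))
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def significant_negative(
    records: pd.DataFrame,
    r_cut: float = -0.2,
    p_cut: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Retain records with r < r_cut and p < p_cut (strict inequalities).

    With ``bh=True`` the p rule is applied to Benjamini-Hochberg adjusted
    p-values instead of raw ones (off by default; the screening thresholds
    are stated on raw p).
    """
    if records.empty:
        return records.copy()
    p = records["p"].to_numpy()
    if bh:
        p = multipletests(p, method="fdr_bh")[1]
    keep = (records["r"].to_numpy() < r_cut) & (p < p_cut)
    return records.loc[keep].reset_index(drop=True)
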