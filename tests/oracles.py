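"""Independent brute-force re-implementations used as oracles.

Everything here is written from the definitions with plain Python loops and
deliberately shares no code path with the package: means via statistics.mean,
correlation via the two-pass covariance formula, percentiles via the explicit
linear-interpolation order-statistic formula, gene verdicts by enumerating
every (gene, CpG) pair and re-checking every criterion from scratch.
"""

from __future__ import annotations

import math
from fractions import Fraction
from statistics import mean

from scipy import stats


def oracle_group_means(beta_rows: dict[str, dict[str, float]], groups: dict[str, str]):
    """beta_rows: cpg -> {sample: beta}; returns cpg -> (mean_normal, mean_tumor)."""
    out = {}
    for cpg, row in beta_rows.items():
        normal = [v for s, v in row.items() if groups[s] == "normal"]
        tumor = [v for s, v in row.items() if groups[s] == "tumor"]
        out[cpg] = (mean(normal), mean(tumor))
    return out


def oracle_site_status(mean_normal: float, mean_tumor: float, threshold: float = 0.2) -> str:
    if mean_normal <= threshold and mean_tumor > threshold:
        return "hyper"
    if mean_normal > threshold and mean_tumor <= threshold:
        return "hypo"
    return "none"


def oracle_pearson(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-pass covariance formula; p from the t distribution."""
    n = len(x)
    mx, my = mean(x), mean(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / math.sqrt(vx * vy)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def oracle_percentile(values: list[float], q: float) -> float:
    """v(floor(h)) + (h - floor(h)) * (v(floor(h)+1) - v(floor(h))), h = (n-1)q/100 + 1."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * q / 100.0 + 1.0
    lo = math.floor(h)
    if lo >= n:
        return v[-1]
    return v[lo - 1] + (h - lo) * (v[lo] - v[lo - 1])


def oracle_silencing(normal: list[float], tumor: list[float]) -> bool:
    return (
        oracle_percentile(normal, 95) < 0.2
        and oracle_percentile(tumor, 95) > 0.2
        and max(tumor) > 0.5
        and mean(tumor) > 0.2
    )


def oracle_activation(normal: list[float], tumor: list[float]) -> bool:
    return (
        oracle_percentile(tumor, 95) < 0.2
        and oracle_percentile(normal, 95) > 0.2
        and max(normal) > 0.5
        and mean(normal) > 0.2
    )


def oracle_gene_verdicts(
    beta_rows: dict[str, dict[str, float]],
    groups: dict[str, str],
    expr_rows: dict[str, dict[str, float]],
    annotation_records: list[tuple[str, str, str]],
    r_cut: float = -0.2,
    p_cut: float = 0.05,
) -> dict[str, str]:
    """Re-derive every gene verdict from raw matrices, one pair at a time.

    Expression is assumed already log-transformed. Every (cpg, gene)
    annotation record is screened by Pearson correlation over the shared
    samples, then the qualifying CpG's per-group betas are tested against
    the silencing and activation criteria.
    """
    genes = sorted({g for _, g, _ in annotation_records})
    verdicts = {}
    for gene in genes:
        cpgs = [c for c, g, _ in annotation_records if g == gene]
        any_sil = False
        any_act = False
        for cpg in dict.fromkeys(cpgs):
            if cpg not in beta_rows or gene not in expr_rows:
                continue
            shared = [s for s in beta_rows[cpg] if s in expr_rows[gene]]
            x = [beta_rows[cpg][s] for s in shared]
            y = [expr_rows[gene][s] for s in shared]
            if len(shared) < 3 or max(x) == min(x) or max(y) == min(y):
                continue
            r, p = oracle_pearson(x, y)
            if not (r < r_cut and p < p_cut):
                continue
            normal = [v for s, v in beta_rows[cpg].items() if groups[s] == "normal"]
            tumor = [v for s, v in beta_rows[cpg].items() if groups[s] == "tumor"]
            if oracle_silencing(normal, tumor):
                any_sil = True
            if oracle_activation(normal, tumor):
                any_act = True
        if any_sil:
            verdicts[gene] = "silenced"
        elif any_act:
            verdicts[gene] = "activated"
        else:
            verdicts[gene] = "none"
    return verdicts


def oracle_hypergeom_upper(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact upper tail as a rational number via direct binomial enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc
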