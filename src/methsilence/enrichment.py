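"""Gene-set over-representation by the exact hypergeometric upper tail.

Given a query gene list (e.g. the silenced genes of one cohort) and a GMT
collection, each set is scored with P(X >= k) where X ~ Hypergeometric(
N = background size, K = set size in background, n = query size in
background). The tail is accumulated in log space for numerical stability.
An EASE-style variant (the conservative modification used by the DAVID
service: remove one overlapping gene before taking the tail) is available
via ``mode="ease"``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe used for testing."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    background: frozenset[str] | None = None

    def effective_background(self, measured: set[str] | None = None) -> frozenset[str]:
        """Explicit background if given, else the union of all set members;
        intersected with the measured-gene universe when one is supplied."""
        bg = self.background
        if bg is None:
            bg = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        if measured is not None:
            bg = frozenset(bg) & frozenset(measured)
        return frozenset(bg)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, tab-separated members.

    Duplicate members are de-duplicated with a warning; sets left empty are
    dropped with a warning; a line with fewer than 3 fields is rejected with
    its line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m.strip()]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("set %s: %d duplicate members removed", name, len(members) - len(unique))
            if not unique:
                logger.warning("set %s is empty and was dropped", name)
                continue
            sets[name] = frozenset(unique)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _log_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact, in log space.

    N is the background size, K the set size, n the draw (query) size,
    k the observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N, got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    support_lo = max(0, n + K - N)
    if k <= support_lo:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    if i.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(_log_pmf(i, K, n, N)))))


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    members: tuple[str, ...]


def enrich(
    query,
    collection: GeneSetCollection,
    p_cut: float = 0.05,
    mode: str = "standard",
    background=None,
    measured=None,
) -> pd.DataFrame:
    """Score every set of the collection against a query gene list.

    Parameters
    ----------
    query
        Gene symbols to test (e.g. silenced genes of a cohort).
    mode
        ``"standard"`` uses the observed overlap k; ``"ease"`` substitutes
        max(k-1, 0), the conservative DAVID-style variant.
    background
        Optional explicit background universe; defaults to the collection's
        (union of set members), intersected with ``measured`` if given.
    measured
        Optional universe of genes actually measured in the cohort.

    Returns a DataFrame sorted by ascending p (ties by set id) with columns
    set_id, k, K, n, N, p, p_bh, significant, members. Significance is
    strict raw p < p_cut; the BH-adjusted p is reported alongside but does
    not drive the flag.
    """
    if mode not in ("standard", "ease"):
        raise ValueError(f"mode must be 'standard' or 'ease', got {mode!r}")
    if background is not None:
        bg = frozenset(background)
        if measured is not None:
            bg &= frozenset(measured)
    else:
        bg = collection.effective_background(set(measured) if measured is not None else None)
    query_bg = frozenset(query) & bg
    if not query_bg:
        raise ValueError(
            f"query ({len(set(query))} genes) has empty intersection with the "
            f"background ({len(bg)} genes)"
        )
    N = len(bg)
    n = len(query_bg)
    rows = []
    for set_id in sorted(collection.sets):
        members_bg = collection.sets[set_id] & bg
        K = len(members_bg)
        overlap = sorted(query_bg & members_bg)
        k = len(overlap)
        k_eff = max(k - 1, 0) if mode == "ease" else k
        p = hypergeometric_upper(k_eff, K, n, N)
        rows.append((set_id, k, K, n, N, p, ",".join(overlap)))
    out = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p", "members"])
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["significant"] = (out["p"] < p_cut).astype(int)
    out = out.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    return out[["set_id", "k", "K", "n", "N", "p", "p_bh", "significant", "members"]]
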