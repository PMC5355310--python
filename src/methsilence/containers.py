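"""Core in-memory containers shared across pipeline stages.

Matrices are pandas DataFrames: rows are features (CpG sites or genes),
columns are samples. Methylation values are Illumina 450K-style beta values
in [0, 1]; expression values are non-negative abundance estimates (RSEM-like).
Missing entries are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

GROUPS = ("tumor", "normal")

REGIONS = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR")
#: regions counted as promoter-proximal (within 1500 bp of the TSS)
PROMOTER_REGIONS = ("TSS200", "TSS1500")


class MethsilenceError(Exception):
    """Base class for pipeline errors."""


class EmptyResultError(MethsilenceError):
    """An operation removed every row/record; distinct from ordinary success."""


class ConstantInputError(MethsilenceError):
    """Correlation undefined because one vector has zero variance."""


@dataclass
class BetaMatrix:
    """CpG-by-sample beta-value matrix with per-sample tumor/normal labels.

    Parameters
    ----------
    values : DataFrame
        Index = CpG ids, columns = sample ids, entries in [0, 1] or NaN.
    groups : Series
        Maps each sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if not self.values.index.is_unique:
            raise ValueError("duplicate CpG ids in beta matrix")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in beta matrix")
        missing_labels = [s for s in self.values.columns if s not in self.groups.index]
        if missing_labels:
            raise ValueError(f"samples without a group label: {missing_labels[:5]}")
        bad = set(self.groups.loc[list(self.values.columns)]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        vals = self.values.to_numpy()
        finite = vals[~pd.isna(vals)]
        if len(finite) and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("beta values must lie in [0, 1]")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


# ExpressionMatrix is a plain DataFrame (index = gene symbols, columns =
# sample ids, non-negative entries or NaN); no wrapper type is needed because
# it carries no side information.


@dataclass
class CpGAnnotation:
    """Record-level CpG annotation: one row per (cpg_id, gene, region).

    A CpG may map to several genes/regions; each mapping is a separate record,
    mirroring record-level array annotation tables.
    """

    records: pd.DataFrame  # columns: cpg_id, gene, region

    def __post_init__(self) -> None:
        required = {"cpg_id", "gene", "region"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        bad = set(self.records["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region categories: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    def cpgs_for_gene(self, gene: str) -> list[str]:
        return list(self.records.loc[self.records["gene"] == gene, "cpg_id"].unique())

    def promoter_cpgs_for_gene(self, gene: str) -> list[str]:
        sub = self.records[
            (self.records["gene"] == gene) & (self.records["region"].isin(PROMOTER_REGIONS))
        ]
        return list(sub["cpg_id"].unique())


class SupportingCpG(NamedTuple):
    """Evidence attached to a gene verdict: one qualifying CpG and its stats."""

    cpg_id: str
    r: float
    p: float
    p95_normal: float
    p95_tumor: float
    max_tumor: float
    max_normal: float
    mean_tumor: float
    mean_normal: float


@dataclass
class GeneEpigeneticCall:
    """Per-gene, per-cohort verdict with the CpG evidence behind it."""

    gene: str
    cohort: str
    verdict: str  # silenced | activated | none
    supporting_cpgs: list[SupportingCpG] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict not in ("silenced", "activated", "none"):
            raise ValueError(f"invalid verdict {self.verdict!r}")


@dataclass
class CrossCohortSummary:
    """Which cohorts silenced / activated a gene."""

    gene: str
    cohorts_silenced: frozenset[str]
    cohorts_activated: frozenset[str]

    @property
    def n_silenced(self) -> int:
        return len(self.cohorts_silenced)
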