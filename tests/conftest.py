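from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from methsilence.containers import REGIONS, BetaMatrix, CpGAnnotation
from methsilence.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical synthetic cohort: 200 genes, 30 silenced, 10 activated."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort with no missing values, for stages requiring completeness."""
    return generate_cohort(
        SimulationConfig(
            n_tumor=15, n_normal=8, n_genes=40, cpgs_per_gene=2,
            n_silenced=6, n_activated=2, missing_rate=0.0, seed=7,
        )
    )


def random_small_cohort(rng: np.random.Generator):
    """A random tiny cohort (<=20 CpGs, <=12 samples) for oracle-equivalence checks.

    Half the time beta values are drawn from a coarse grid so group means can
    sit exactly on the 0.2 threshold; annotation includes multi-gene CpGs and
    genes absent from the expression matrix.
    """
    n_cpgs = int(rng.integers(2, 21))
    n_samples = int(rng.integers(6, 13))
    n_genes = int(rng.integers(1, 6))
    samples = [f"s{i}" for i in range(n_samples)]
    # at least 3 per group so correlations are defined on group subsets too
    n_tumor = int(rng.integers(3, n_samples - 2))
    groups = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor), index=samples, name="group"
    )
    if rng.random() < 0.5:
        # dyadic grid: group means are exact in floats regardless of summation
        # order, so threshold ties are reproduced identically by any oracle
        beta_vals = rng.choice(np.arange(17) / 16.0, size=(n_cpgs, n_samples))
    else:
        beta_vals = rng.random((n_cpgs, n_samples))
    cpg_ids = [f"cg{i}" for i in range(n_cpgs)]
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=cpg_ids, columns=samples), groups)

    genes = [f"g{i}" for i in range(n_genes)]
    expr_genes = [g for g in genes if rng.random() > 0.2] or genes[:1]
    expr = pd.DataFrame(
        np.round(rng.random((len(expr_genes), n_samples)) * 8, 3),
        index=expr_genes, columns=samples,
    )
    records = []
    for cpg in cpg_ids:
        n_map = int(rng.integers(1, min(2, len(genes)) + 1))
        for gene in rng.choice(genes, size=n_map, replace=False):
            records.append((cpg, str(gene), str(rng.choice(REGIONS))))
    annotation = CpGAnnotation(pd.DataFrame(records, columns=["cpg_id", "gene", "region"]))
    return beta, expr, annotation
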