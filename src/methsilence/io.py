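"""TSV readers/writers for the pipeline's exchange dialects.

All files are tab-separated with a header row. Missing values are written
as the literal string ``NA`` and parsed back to NaN. Floats are written with
full ``repr`` precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .containers import BetaMatrix, CpGAnnotation

_NA = "NA"
_READ_KW = dict(sep="\t", na_values=[_NA], keep_default_na=False)


def read_matrix(path: str | os.PathLike, index_name: str) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix; first column holds feature ids."""
    df = pd.read_csv(path, index_col=0, **_READ_KW)
    df.index.name = index_name
    df.index = df.index.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike, index_name: str) -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_beta_values(path: str | os.PathLike) -> pd.DataFrame:
    return read_matrix(path, "cpg_id")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    return read_matrix(path, "gene")


def read_groups(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, **_READ_KW)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    return pd.Series(df["group"].values, index=df["sample_id"].astype(str).values, name="group")


def write_groups(groups: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path: str | os.PathLike) -> CpGAnnotation:
    df = pd.read_csv(path, dtype=str, **_READ_KW)
    return CpGAnnotation(df[["cpg_id", "gene", "region"]])


def write_annotation(annotation: CpGAnnotation, path: str | os.PathLike) -> None:
    annotation.records.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, dtype=str, **_READ_KW)
    if list(df.columns) != ["gene", "label"]:
        raise ValueError(f"{path}: expected columns gene, label")
    return pd.Series(df["label"].values, index=df["gene"].values, name="label")


def write_truth(truth: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"gene": truth.index, "label": truth.values}).to_csv(path, sep="\t", index=False)


def read_beta_matrix(
    beta_path: str | os.PathLike, groups_path: str | os.PathLike
) -> BetaMatrix:
    return BetaMatrix(read_beta_values(beta_path), read_groups(groups_path))


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
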