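"""Tab-separated readers/writers for expression matrices and clinical tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene id).

    Rows containing any missing value are dropped with a logged count;
    duplicate gene or sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.info("%s: dropped %d genes with missing values", path, n_bad)
        df = df.dropna(axis=0)
    if df.empty:
        raise ValueError(f"{path}: no complete gene rows")
    return df.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV: sample_id, time, event, then covariate columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0/1")
    return df


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")
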