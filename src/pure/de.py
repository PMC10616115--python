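"""Differential-expression input: reading DE tables and selecting signed
DE genes with the |log(FC)| > 0.6, p < 0.05 rule (strict inequalities;
thresholds configurable)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_LOGFC_CUT = 0.6
DEFAULT_P_CUT = 0.05

RECORD_COLUMNS = ("gene_id", "log_fc", "p_value")


class DEFormatError(ValueError):
    """The DE table is missing a required column or holds invalid values."""


@dataclass(frozen=True)
class DEGene:
    """A selected DE gene; ``sign`` is the algebraic sign of log_fc."""

    gene_id: str
    sign: int
    log_fc: float
    p_value: float

    def __post_init__(self) -> None:
        if self.sign != (1 if self.log_fc > 0 else -1):
            raise ValueError("DE gene sign must equal sign(log_fc)")


@dataclass
class DEProfile:
    """Per-gene log fold-change and p-value, plus selection thresholds.

    ``records`` holds one row per gene after duplicate aggregation, columns
    gene_id / log_fc / p_value.
    """

    records: pd.DataFrame
    logfc_cut: float = DEFAULT_LOGFC_CUT
    p_cut: float = DEFAULT_P_CUT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise DEFormatError(f"DE records missing column(s): {', '.join(missing)}")
        if self.logfc_cut <= 0:
            raise ValueError("logfc_cut must be positive")
        if not (0 < self.p_cut <= 1):
            raise ValueError("p_cut must lie in (0, 1]")
        p = self.records["p_value"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1) | np.isnan(p)):
            raise DEFormatError("p_value outside [0, 1] in DE table")
        if self.records["gene_id"].duplicated().any():
            raise DEFormatError(
                "duplicate gene_id in DE records; run aggregate_duplicates first"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.records["gene_id"].astype(str).tolist()


def read_de_table(
    path: str | Path,
    rename: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Read a CSV/TSV DE table (delimiter sniffed), returning raw records.

    Required columns after optional renaming: ``gene_id`` (``gene_symbol``
    accepted as an alias), ``log_fc``, ``p_value``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"gene_id": str})
    if rename:
        df = df.rename(columns=rename)
    if "gene_id" not in df.columns and "gene_symbol" in df.columns:
        df = df.rename(columns={"gene_symbol": "gene_id"})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DEFormatError(
            f"DE table {path} is missing required column(s): {', '.join(missing)}"
        )
    df = df.loc[:, list(RECORD_COLUMNS)].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["log_fc"] = pd.to_numeric(df["log_fc"], errors="raise")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="raise")
    return df


def aggregate_duplicates(
    records: pd.DataFrame,
    logfc_cut: float = DEFAULT_LOGFC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    meta: Optional[dict] = None,
) -> DEProfile:
    """Collapse duplicated gene_ids into a DEProfile.

    Rule: keep the record with the smallest p-value; ties broken by the
    largest |log_fc|, then by input order.  This mirrors the common
    best-probe collapse for microarray tables.
    """
    df = records.copy()
    df["_abs"] = df["log_fc"].abs()
    df = df.sort_values(
        ["p_value", "_abs"], ascending=[True, False], kind="mergesort"
    ).drop_duplicates("gene_id", keep="first")
    df = df.drop(columns="_abs").sort_values("gene_id", kind="mergesort")
    df = df.reset_index(drop=True)
    return DEProfile(records=df, logfc_cut=logfc_cut, p_cut=p_cut, meta=meta or {})


def select_de_genes(profile: DEProfile) -> list[DEGene]:
    """Apply the DE selection rule: |log_fc| strictly greater than the
    fold-change cut and p strictly below the p cut; each selected gene
    carries sign(log_fc)."""
    out: list[DEGene] = []
    for row in profile.records.itertuples(index=False):
        lfc = float(row.log_fc)
        p = float(row.p_value)
        if abs(lfc) > profile.logfc_cut and p < profile.p_cut:
            out.append(
                DEGene(
                    gene_id=str(row.gene_id),
                    sign=1 if lfc > 0 else -1,
                    log_fc=lfc,
                    p_value=p,
                )
            )
    return out
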