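"""Relative qPCR quantification by the ddCt method.

Cycle-threshold (Ct) values are normalised to an endogenous reference
gene (GAPDH by default) within each condition, and fold change of a
target gene in the treated condition relative to control is

    dCt  = Ct_target - Ct_reference        (per condition)
    ddCt = dCt_treated - dCt_control
    fold change = 2 ** (-ddCt)

Replicates are averaged on the Ct scale before differencing, and the
amplification efficiency is fixed at 2 (perfect doubling per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = ["CtTable", "fold_change", "fold_change_table"]

REQUIRED_COLUMNS = ("sample", "condition", "gene", "ct")
CONDITIONS = ("control", "treated")


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: sample, condition ("control"/"treated"), gene, ct.
    Every (sample, condition) present must include a Ct for the
    reference gene; Ct values must lie in the open interval (0, 45).
    """

    data: pd.DataFrame
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"Ct table lacks columns {missing}")
        df["gene"] = df["gene"].astype(str).str.upper()
        df["condition"] = df["condition"].astype(str).str.lower()
        self.reference_gene = self.reference_gene.upper()
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise InputError(f"unknown condition labels {sorted(bad_cond)}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        if ct.isna().any() or not ((ct > 0) & (ct < 45)).all():
            raise InputError("Ct values must be numeric and in (0, 45)")
        df["ct"] = ct
        ref_by = df[df["gene"] == self.reference_gene].groupby(["sample", "condition"]).size()
        all_by = df.groupby(["sample", "condition"]).size()
        if not all_by.index.isin(ref_by.index).all():
            raise InputError(
                f"every (sample, condition) needs a {self.reference_gene} measurement"
            )
        self.data = df

    @classmethod
    def from_csv(cls, path: str, reference_gene: str = "GAPDH") -> "CtTable":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise FormatError(f"could not parse Ct table {path!r}: {exc}") from exc
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df, reference_gene=reference_gene)


def _mean_ct(df: pd.DataFrame, gene: str, condition: str) -> float:
    sel = df[(df["gene"] == gene) & (df["condition"] == condition)]
    if sel.empty:
        raise InputError(f"no Ct for gene {gene!r} in condition {condition!r}")
    return float(sel["ct"].mean())


def fold_change(table: CtTable, target: str) -> float:
    """Fold change of ``target`` in treated vs control, via 2^(-ddCt)."""
    target = target.upper()
    ref = table.reference_gene
    df = table.data
    d_ct = {}
    for cond in CONDITIONS:
        d_ct[cond] = _mean_ct(df, target, cond) - _mean_ct(df, ref, cond)
    dd_ct = d_ct["treated"] - d_ct["control"]
    return float(2.0 ** (-dd_ct))


def fold_change_table(table: CtTable) -> pd.DataFrame:
    """Fold change and log2 fold change for every non-reference gene."""
    genes = sorted(set(table.data["gene"]) - {table.reference_gene})
    rows = []
    for g in genes:
        fc = fold_change(table, g)
        rows.append({"gene": g, "fold_change": fc, "log2fc": float(np.log2(fc))})
    return pd.DataFrame(rows)
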