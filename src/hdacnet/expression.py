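"""Gene-expression matrices and gene panels.

The analysis operates on gene-level, log2-scale expression matrices
(genes in rows, samples in columns) such as the public AML (GSE14468,
N = 525) and neuroblastoma (GSE16476, N = 88) cohorts or GDSC cell-line
panels.  This module reads such matrices from delimited text (including
the GEO series-matrix dialect), validates them, and slices out the HDAC
predictor block and the RTK response block used by the regression stage.

Probe-to-gene summarisation, batch correction and normalisation are out
of scope: inputs must already be gene-level; an optional ``log2(x+1)``
transform is offered for matrices distributed on the raw scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError, MissingGeneError, InputError

__all__ = [
    "ExpressionMatrix",
    "GenePanel",
    "LoadReport",
    "PanelSubset",
    "read_expression",
    "write_expression",
    "subset_panel",
    "DEFAULT_HDAC_PREDICTORS",
    "DEFAULT_SCORE_SET",
    "DEFAULT_SCORE_I_SET",
]

#: Class I + II HDAC genes used as predictors, in canonical order.
DEFAULT_HDAC_PREDICTORS = tuple(f"HDAC{i}" for i in range(1, 9))
#: HDAC subset whose squared coefficients define the SCORE statistic.
DEFAULT_SCORE_SET = frozenset({"HDAC1", "HDAC2", "HDAC3", "HDAC6", "HDAC8"})
#: HDAC subset (class I only) defining the SCORE I statistic.
DEFAULT_SCORE_I_SET = frozenset({"HDAC1", "HDAC2", "HDAC3", "HDAC8"})


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_expression`."""

    n_rows_raw: int = 0
    n_duplicate_rows_collapsed: int = 0
    n_rows_dropped_missing: int = 0
    log2_applied: bool = False


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    Invariants enforced on construction: unique gene identifiers,
    consistent shapes, and all-finite values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    load_report: LoadReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(g.upper() for g in self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene identifiers must be unique (case-insensitive)")
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, load_report: LoadReport | None = None) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            load_report=load_report,
        )

    def row(self, gene: str) -> np.ndarray:
        """Return the expression vector of ``gene`` (case-insensitive)."""
        idx = self._gene_index(gene)
        if idx is None:
            raise MissingGeneError(f"gene {gene!r} not present in matrix")
        return self.values[idx]

    def _gene_index(self, gene: str) -> int | None:
        lut = {g.upper(): i for i, g in enumerate(self.gene_ids)}
        return lut.get(gene.upper())

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Subset to ``genes`` in the given order; all must be present."""
        rows = []
        for g in genes:
            idx = self._gene_index(g)
            if idx is None:
                raise MissingGeneError(f"gene {g!r} not present in matrix")
            rows.append(idx)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in rows],
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
        )


@dataclass
class GenePanel:
    """HDAC predictor set, SCORE subsets, and the RTK response genes.

    ``score_set`` defaults to HDAC1/2/3/6/8 and ``score_i_set`` to the
    class I enzymes HDAC1/2/3/8; both must be subsets of the predictors,
    and RTK genes must be disjoint from the predictors.
    """

    hdac_predictors: tuple[str, ...] = DEFAULT_HDAC_PREDICTORS
    score_set: frozenset[str] = DEFAULT_SCORE_SET
    score_i_set: frozenset[str] = DEFAULT_SCORE_I_SET
    rtk_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.hdac_predictors = tuple(str(g).upper() for g in self.hdac_predictors)
        self.score_set = frozenset(str(g).upper() for g in self.score_set)
        self.score_i_set = frozenset(str(g).upper() for g in self.score_i_set)
        self.rtk_genes = tuple(str(g).upper() for g in self.rtk_genes)
        preds = set(self.hdac_predictors)
        if len(preds) != len(self.hdac_predictors):
            raise InputError("hdac_predictors must be unique")
        if not self.score_set <= preds:
            raise InputError("score_set must be a subset of hdac_predictors")
        if not self.score_i_set <= preds:
            raise InputError("score_i_set must be a subset of hdac_predictors")
        if preds & set(self.rtk_genes):
            overlap = sorted(preds & set(self.rtk_genes))
            raise InputError(f"rtk_genes overlap hdac_predictors: {overlap}")

    @classmethod
    def from_yaml(cls, path: str) -> "GenePanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"panel YAML {path!r} must be a mapping")
        kwargs = {}
        for key in ("hdac_predictors", "score_set", "score_i_set", "rtk_genes"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        payload = {
            "hdac_predictors": list(self.hdac_predictors),
            "score_set": sorted(self.score_set),
            "score_i_set": sorted(self.score_i_set),
            "rtk_genes": list(self.rtk_genes),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


class PanelSubset(NamedTuple):
    hdac_block: ExpressionMatrix
    rtk_block: ExpressionMatrix
    missing_rtks: tuple[str, ...]


def _read_geo_series_matrix(path: str) -> pd.DataFrame:
    """Parse the GEO series-matrix text dialect.

    Metadata lines begin with ``!``; when the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers
    are present only the delimited block between them is read.  Values
    and identifiers may be double-quoted.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        low = line.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            begin = i + 1
        elif low.startswith("!series_matrix_table_end"):
            end = i
    if begin is not None:
        table_lines = lines[begin:end]
    else:
        table_lines = [ln for ln in lines if not ln.startswith("!")]
    table_lines = [ln for ln in table_lines if ln.strip()]
    if not table_lines:
        raise EmptyInputError(f"no table rows found in series-matrix file {path!r}")
    text = "\n".join(table_lines)
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, quotechar='"')
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"could not parse series-matrix table in {path!r}: {exc}") from exc
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    return df


def read_expression(
    path: str,
    dialect: str = "tsv",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text.

    Parameters
    ----------
    path
        File with gene identifiers in the first column and sample labels
        in the header row.
    dialect
        ``"tsv"``, ``"csv"`` or ``"geo_series_matrix"``.
    log2_transform
        Apply ``log2(x + 1)`` after loading, for matrices distributed on
        the raw intensity/count scale.  Cohort matrices from microarray
        repositories are typically already log2-scale, so the default is
        no transform.

    Duplicate gene rows are collapsed by their mean; rows containing any
    missing value are dropped.  Both counts are recorded in the returned
    matrix's ``load_report``.
    """
    if dialect == "geo_series_matrix":
        df = _read_geo_series_matrix(path)
    elif dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"could not parse {dialect} file {path!r}: {exc}") from exc
    else:
        raise InputError(f"unknown dialect {dialect!r}")

    if df.shape[1] == 0:
        raise FormatError(f"{path!r}: header row has no sample columns")
    # non-numeric columns indicate a malformed header or annotation columns
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path!r}: non-numeric expression values: {exc}") from exc

    report = LoadReport(n_rows_raw=int(df.shape[0]))

    df.index = df.index.astype(str).str.strip()
    upper = df.index.str.upper()
    if upper.duplicated().any():
        n_dup = int(upper.duplicated().sum())
        df = df.groupby(upper, sort=False).mean()
        report.n_duplicate_rows_collapsed = n_dup
    else:
        df.index = upper

    has_na = df.isna().any(axis=1)
    report.n_rows_dropped_missing = int(has_na.sum())
    df = df.loc[~has_na]
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path!r}: no data rows remain after filtering")

    if log2_transform:
        df = np.log2(df + 1.0)
        report.log2_applied = True
    return ExpressionMatrix.from_frame(df, load_report=report)


def write_expression(expr: ExpressionMatrix, path: str, dialect: str = "tsv") -> None:
    """Write a matrix as TSV/CSV with genes in rows (round-trips with
    :func:`read_expression`)."""
    sep = "\t" if dialect == "tsv" else ","
    expr.to_frame().to_csv(path, sep=sep, index_label="gene")


def subset_panel(expr: ExpressionMatrix, panel: GenePanel) -> PanelSubset:
    """Split ``expr`` into the HDAC predictor block and the RTK block.

    All HDAC predictors must be present (a missing one is a hard error
    naming the gene); RTKs absent from the matrix are tolerated and
    reported in ``missing_rtks``.  Sample order is preserved.
    """
    hdac_block = expr.subset_genes(panel.hdac_predictors)  # raises MissingGeneError
    found, missing = [], []
    for g in panel.rtk_genes:
        if expr._gene_index(g) is None:
            missing.append(g)
        else:
            found.append(g)
    if found:
        rtk_block = expr.subset_genes(found)
    else:
        rtk_block = ExpressionMatrix([], list(expr.sample_ids), np.empty((0, expr.n_samples)))
    return PanelSubset(hdac_block, rtk_block, tuple(missing))
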