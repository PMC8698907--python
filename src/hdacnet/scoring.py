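"""Per-RTK elastic-net fits and the HDAC SCORE ranking.

Each receptor tyrosine kinase (RTK) gene is regressed on the expression
of the eight class I/II histone deacetylases HDAC1-8.  Two summary
statistics rank how strongly an RTK's expression tracks HDAC
expression:

* ``SCORE``   = sum of squared coefficients over HDAC1, 2, 3, 6, 8
* ``SCORE I`` = sum of squared coefficients over HDAC1, 2, 3, 8

Coefficients entering the scores are on the standardised-predictor
scale, so squared magnitudes are comparable across HDAC genes; positive
and negative dependencies contribute identically.  Top-k lists per
cohort are intersected to find RTKs whose HDAC dependency replicates
across cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .elastic_net import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_L1_GRID,
    ElasticNetModel,
    cv_mse_grid,
    fit_elastic_net,
    make_folds,
    select_best_pair,
)
from .errors import InputError
from .expression import ExpressionMatrix, GenePanel

__all__ = [
    "CVConfig",
    "RTKScoreRecord",
    "fit_rtk_models",
    "compute_scores",
    "top_k",
    "intersect_top",
    "score_vs_expression",
    "records_to_frame",
    "records_to_long_frame",
]


@dataclass
class CVConfig:
    """Penalty-selection settings for the per-RTK fits.

    ``mode="dataset"`` selects one (alpha, l1_ratio) pair for the whole
    cohort by minimising the CV MSE averaged over all RTK responses;
    ``mode="gene"`` selects a pair per RTK.  ``penalties`` pins the pair
    explicitly and skips cross-validation entirely.
    """

    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    l1_grid: tuple[float, ...] = DEFAULT_L1_GRID
    k: int = 10
    mode: str = "dataset"
    penalties: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dataset", "gene"):
            raise InputError(f"unknown CV mode {self.mode!r}")
        if not self.alpha_grid or not self.l1_grid:
            raise InputError("penalty grids must be non-empty")


@dataclass
class RTKScoreRecord:
    """Scored regression result for one RTK gene."""

    gene: str
    coefficients: dict[str, float]  # standardised scale, keyed by HDAC gene
    score: float
    score_i: float
    mean_expression: float
    rank: int = 0


def fit_rtk_models(
    hdac_block: ExpressionMatrix,
    rtk_block: ExpressionMatrix,
    cv_config: CVConfig | None = None,
    seed: int = 0,
) -> list[tuple[str, ElasticNetModel]]:
    """Fit one elastic-net model per RTK against the HDAC block.

    Both blocks must share sample order.  Deterministic given ``seed``
    (folds are drawn once per cohort).  A constant RTK response yields a
    model with all-zero weights and a warning.
    """
    if hdac_block.sample_ids != rtk_block.sample_ids:
        raise InputError("hdac_block and rtk_block must share sample order")
    cv = cv_config or CVConfig()
    X = hdac_block.values.T  # samples x predictors
    names = tuple(hdac_block.gene_ids)
    n = X.shape[0]
    responses = rtk_block.values

    for gene, y in zip(rtk_block.gene_ids, responses):
        if np.std(y) == 0.0:
            warnings.warn(f"RTK {gene!r} has constant expression; weights will be 0", stacklevel=2)

    pairs = [(a, l) for a in cv.alpha_grid for l in cv.l1_grid]
    if cv.penalties is not None:
        per_gene_pairs = {g: cv.penalties for g in rtk_block.gene_ids}
    else:
        if cv.k > n:
            raise InputError(f"k={cv.k} folds exceed n={n} samples")
        folds = make_folds(n, cv.k, seed)
        if cv.mode == "dataset":
            pooled = np.zeros(len(pairs))
            for y in responses:
                pooled += cv_mse_grid(X, y, pairs, folds)
            pooled /= max(len(responses), 1)
            best = select_best_pair(pairs, pooled)
            per_gene_pairs = {g: best for g in rtk_block.gene_ids}
        else:
            per_gene_pairs = {}
            for gene, y in zip(rtk_block.gene_ids, responses):
                mse = cv_mse_grid(X, y, pairs, folds)
                per_gene_pairs[gene] = select_best_pair(pairs, mse)

    models = []
    for gene, y in zip(rtk_block.gene_ids, responses):
        alpha, l1_ratio = per_gene_pairs[gene]
        model = fit_elastic_net(X, y, alpha, l1_ratio, predictor_names=names)
        models.append((gene, model))
    return models


def compute_scores(
    models: Sequence[tuple[str, ElasticNetModel]],
    panel: GenePanel,
    expr: ExpressionMatrix,
) -> list[RTKScoreRecord]:
    """SCORE / SCORE I per RTK, ranked by SCORE descending.

    ``expr`` supplies the RTK rows from which each gene's cohort mean
    expression is taken.  Ties in SCORE break alphabetically by gene
    symbol; ranks are 1..N.
    """
    if expr.n_samples == 0:
        raise InputError("expression matrix has no samples")
    records = []
    for gene, model in models:
        if model.predictor_names is None:
            raise InputError(f"model for {gene!r} lacks predictor names")
        std = {n: w for n, w in zip(model.predictor_names, model.weights_std)}
        missing = panel.score_set - set(std)
        if missing:
            raise InputError(f"model for {gene!r} lacks predictors {sorted(missing)}")
        score = float(sum(std[g] ** 2 for g in panel.score_set))
        score_i = float(sum(std[g] ** 2 for g in panel.score_i_set))
        records.append(
            RTKScoreRecord(
                gene=gene,
                coefficients={n: float(w) for n, w in std.items()},
                score=score,
                score_i=score_i,
                mean_expression=float(expr.row(gene).mean()),
            )
        )
    records.sort(key=lambda r: (-r.score, r.gene))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


def top_k(records: Sequence[RTKScoreRecord], k: int = 15, by: str = "score") -> list[str]:
    """First ``k`` gene symbols of the ranking (default: by SCORE)."""
    if by not in ("score", "score_i"):
        raise InputError(f"unknown ranking key {by!r}")
    if k > len(records):
        raise InputError(f"k={k} exceeds {len(records)} records")
    if by == "score":
        ordered = sorted(records, key=lambda r: (-r.score, r.gene))
    else:
        ordered = sorted(records, key=lambda r: (-r.score_i, r.gene))
    return [r.gene for r in ordered[:k]]


def intersect_top(*lists: Sequence[str]) -> list[str]:
    """Genes shared by every list, in the order of the first list."""
    if not lists or any(len(lst) == 0 for lst in lists):
        raise InputError("intersect_top requires non-empty gene lists")
    shared = set(lists[0])
    for lst in lists[1:]:
        shared &= set(lst)
    return [g for g in lists[0] if g in shared]


def score_vs_expression(records: Sequence[RTKScoreRecord]) -> pd.DataFrame:
    """Table of (gene, mean_expression, score) for scatter plots of
    SCORE against cohort-average expression."""
    if not records:
        raise InputError("no records")
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "mean_expression": [r.mean_expression for r in records],
            "score": [r.score for r in records],
        }
    )


def records_to_frame(records: Sequence[RTKScoreRecord]) -> pd.DataFrame:
    """Wide score table: one row per RTK with per-HDAC coefficients,
    SCORE, SCORE I, rank, and mean expression."""
    if not records:
        raise InputError("no records")
    hdacs = list(records[0].coefficients)
    rows = []
    for r in records:
        row = {"gene": r.gene}
        row.update({h: r.coefficients[h] for h in hdacs})
        row.update(
            {
                "SCORE": r.score,
                "SCORE_I": r.score_i,
                "rank": r.rank,
                "mean_expression": r.mean_expression,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_long_frame(records: Sequence[RTKScoreRecord]) -> pd.DataFrame:
    """Heatmap-ready long format: (gene, hdac, coefficient)."""
    if not records:
        raise InputError("no records")
    rows = [
        {"gene": r.gene, "hdac": h, "coefficient": w}
        for r in records
        for h, w in r.coefficients.items()
    ]
    return pd.DataFrame(rows)
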