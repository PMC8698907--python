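"""Bliss-independence synergy scoring of two-drug viability matrices.

Given a dose grid of two drugs with % viability relative to untreated
control (including single-agent rows/columns at dose zero), the Bliss
independence model predicts the combined inhibition of two
non-interacting drugs as ``fA + fB - fA * fB``.  The synergy score is
100 times the mean excess of observed over expected inhibition across
all non-zero dose combinations; a score above 10 is classified as
synergistic.

No baseline or outlier correction and no surface smoothing is applied —
the score is the raw Bliss excess, a deliberate simplification relative
to full synergy-analysis suites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = [
    "DoseResponseMatrix",
    "SynergyResult",
    "normalize_viability",
    "bliss_expected",
    "bliss_synergy_score",
    "read_dose_matrix",
    "DEFAULT_SYNERGY_THRESHOLD",
]

#: Bliss score above which a combination is called synergistic.
DEFAULT_SYNERGY_THRESHOLD = 10.0


@dataclass
class DoseResponseMatrix:
    """% viability over a two-drug dose grid, with zero-dose anchors.

    ``viability[i, j]`` is the viability at ``doses_a[i]`` x
    ``doses_b[j]``; row/column 0 (dose 0 of the partner drug) hold the
    single-agent responses, and cell (0, 0) the untreated control.
    Values above 100 (stimulation) are retained.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    unit_a: str = "uM"
    unit_b: str = "uM"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise InputError(
                f"viability shape {self.viability.shape} does not match dose grid "
                f"({len(self.doses_a)} x {len(self.doses_b)})"
            )
        for name, doses in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if np.any(doses < 0):
                raise InputError(f"{name} must be nonnegative")
            if np.any(np.diff(doses) <= 0):
                raise InputError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.viability)):
            raise InputError("viability matrix must be complete and finite")

    @property
    def has_zero_anchors(self) -> bool:
        return self.doses_a[0] == 0.0 and self.doses_b[0] == 0.0

    def transpose(self) -> "DoseResponseMatrix":
        return DoseResponseMatrix(
            doses_a=self.doses_b,
            doses_b=self.doses_a,
            viability=self.viability.T,
            drug_a=self.drug_b,
            drug_b=self.drug_a,
            unit_a=self.unit_b,
            unit_b=self.unit_a,
        )


@dataclass
class SynergyResult:
    """Bliss excess surface and its summary score."""

    excess: np.ndarray  # percentage points, over nonzero dose pairs
    score: float
    label: str
    threshold: float = DEFAULT_SYNERGY_THRESHOLD
    doses_a: np.ndarray = field(default_factory=lambda: np.empty(0))
    doses_b: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self) -> str:
        payload = {
            "score": float(self.score),
            "label": self.label,
            "threshold": float(self.threshold),
            "doses_a": [float(d) for d in self.doses_a],
            "doses_b": [float(d) for d in self.doses_b],
            "excess": [[float(v) for v in row] for row in self.excess],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def normalize_viability(
    raw_counts: np.ndarray,
    control_count: float,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    **kwargs,
) -> DoseResponseMatrix:
    """Cell counts -> % viability relative to the untreated control.

    Viability is ``100 * raw / control``; values above 100 (growth
    stimulation) are kept as-is — clamping happens only on the
    inhibition scale downstream.
    """
    if control_count <= 0:
        raise InputError("control_count must be positive")
    viability = 100.0 * np.asarray(raw_counts, dtype=float) / float(control_count)
    return DoseResponseMatrix(doses_a=doses_a, doses_b=doses_b, viability=viability, **kwargs)


def bliss_expected(inh_a, inh_b):
    """Bliss-independent combined inhibition ``fA + fB - fA*fB``.

    Inputs are inhibition fractions and are clamped to [0, 1];
    broadcasting over arrays is supported.
    """
    a = np.clip(np.asarray(inh_a, dtype=float), 0.0, 1.0)
    b = np.clip(np.asarray(inh_b, dtype=float), 0.0, 1.0)
    out = a + b - a * b
    if out.ndim == 0:
        return float(out)
    return out


def bliss_synergy_score(
    m: DoseResponseMatrix,
    threshold: float = DEFAULT_SYNERGY_THRESHOLD,
) -> SynergyResult:
    """Score a combination matrix against the Bliss independence model.

    Inhibition is ``clamp((100 - viability) / 100, 0, 1)``; single-agent
    inhibitions come from the zero-dose row and column.  The excess at
    each non-zero dose pair is ``100 * (observed - expected)`` and the
    score is the unweighted mean excess.
    """
    if not m.has_zero_anchors:
        raise InputError("dose grids must include the zero-dose anchors (dose 0 first)")
    if len(m.doses_a) < 2 or len(m.doses_b) < 2:
        raise InputError("need at least one non-zero dose of each drug")
    inh = np.clip((100.0 - m.viability) / 100.0, 0.0, 1.0)
    inh_a = inh[1:, 0]  # single-agent drug A at each nonzero dose
    inh_b = inh[0, 1:]
    expected = bliss_expected(inh_a[:, None], inh_b[None, :])
    excess = 100.0 * (inh[1:, 1:] - expected)
    score = float(excess.mean())
    label = "synergistic" if score > threshold else "non-synergistic"
    return SynergyResult(
        excess=excess,
        score=score,
        label=label,
        threshold=float(threshold),
        doses_a=m.doses_a[1:],
        doses_b=m.doses_b[1:],
    )


def read_dose_matrix(path: str, **kwargs) -> DoseResponseMatrix:
    """Read a combination matrix from CSV.

    Two layouts are accepted: long format with columns
    ``dose_a, dose_b, viability``, or a wide matrix whose first column
    holds doses of drug A and whose header row holds doses of drug B.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse dose matrix {path!r}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if {"dose_a", "dose_b", "viability"} <= set(cols):
        df.columns = cols
        pivot = df.pivot_table(index="dose_a", columns="dose_b", values="viability")
        if pivot.isna().any().any():
            raise FormatError(f"{path!r}: incomplete dose grid")
        return DoseResponseMatrix(
            doses_a=pivot.index.to_numpy(dtype=float),
            doses_b=pivot.columns.to_numpy(dtype=float),
            viability=pivot.to_numpy(dtype=float),
            **kwargs,
        )
    # wide layout
    try:
        wide = pd.read_csv(path, index_col=0)
        doses_a = wide.index.to_numpy(dtype=float)
        doses_b = wide.columns.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(
            f"{path!r}: expected long columns (dose_a, dose_b, viability) "
            f"or a wide matrix with numeric dose headers"
        ) from exc
    return DoseResponseMatrix(
        doses_a=doses_a,
        doses_b=doses_b,
        viability=wide.to_numpy(dtype=float),
        **kwargs,
    )
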