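"""Synthetic cohorts and drug-response surfaces with known ground truth.

Every analysis stage in the package can be exercised against data whose
generating process is known exactly:

* ``simulate_cohort`` emulates a patient or cell-line expression cohort
  (e.g. AML N = 525, neuroblastoma N = 88): HDAC1-8 expression is drawn
  from a multivariate normal with configurable co-expression, a subset
  of RTK genes is planted as a linear function of the HDACs plus
  Gaussian noise (the regression model the scoring stage assumes), and
  the remaining RTKs are independent noise.
* ``simulate_combination`` builds a two-drug viability matrix whose
  single agents follow 4PL curves and whose combination cells deviate
  from Bliss independence by a planted excess.
* ``simulate_dose_response`` draws noisy single-agent 4PL curves for
  IC50-recovery experiments.

All randomness flows from a single seed through spawned child streams,
so each component of a simulated dataset is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import four_pl
from .errors import InputError
from .expression import DEFAULT_HDAC_PREDICTORS, ExpressionMatrix, GenePanel
from .synergy import DoseResponseMatrix, bliss_expected

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "SurfaceSpec",
    "default_cohort_spec",
    "simulate_cohort",
    "simulate_combination",
    "simulate_dose_response",
]

#: RTK symbols used for planted / null genes in default cohorts.
_PLANTED_RTKS = ("NTRK1", "FGFR3", "KIT", "FLT3", "CSF1R")
_NULL_RTKS = (
    "ALK", "AXL", "DDR1", "DDR2", "EGFR", "FGFR1", "IGF1R", "INSR",
    "MET", "NTRK2", "PDGFRA", "PDGFRB", "RET", "ROR1", "ROR2", "ROS1",
    "TEK", "TIE1", "TYRO3", "RYK",
)


@dataclass
class CohortSpec:
    """Generating process of a synthetic expression cohort.

    ``planted`` maps an RTK symbol to ``(intercept, weights)`` where
    ``weights`` is a length-8 vector over the HDAC predictors; null RTKs
    are drawn independent normal with ``null_mean`` / ``null_sd``.
    Expression is on the log2 scale throughout.
    """

    n_samples: int = 500
    hdac_means: np.ndarray = field(default_factory=lambda: np.full(8, 8.0))
    hdac_cov: np.ndarray | None = None  # default: unit variance, 0.3 correlation
    planted: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)
    n_null_rtks: int = 15
    noise_sd: float = 0.5
    null_mean: float = 8.0
    null_sd: float = 1.0
    seed: int = 0
    hdac_genes: tuple[str, ...] = DEFAULT_HDAC_PREDICTORS

    def __post_init__(self) -> None:
        p = len(self.hdac_genes)
        self.hdac_means = np.asarray(self.hdac_means, dtype=float)
        if self.hdac_means.shape != (p,):
            raise InputError(f"hdac_means must have length {p}")
        if self.hdac_cov is None:
            self.hdac_cov = np.full((p, p), 0.3) + 0.7 * np.eye(p)
        self.hdac_cov = np.asarray(self.hdac_cov, dtype=float)
        if self.hdac_cov.shape != (p, p):
            raise InputError(f"hdac_cov must be {p} x {p}")
        if not np.allclose(self.hdac_cov, self.hdac_cov.T):
            raise InputError("hdac_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(self.hdac_cov)
        if eigvals.min() < -1e-10:
            raise InputError("hdac_cov must be positive semidefinite")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        for gene, (y0, w) in list(self.planted.items()):
            w = np.asarray(w, dtype=float)
            if w.shape != (p,) or not np.all(np.isfinite(w)):
                raise InputError(f"planted weights for {gene!r} must be a finite length-{p} vector")
            self.planted[gene] = (float(y0), w)


@dataclass
class CohortTruth:
    """Ground truth accompanying a simulated cohort."""

    planted: dict[str, tuple[float, np.ndarray]]
    null_rtks: tuple[str, ...]
    seed: int

    @property
    def planted_genes(self) -> tuple[str, ...]:
        return tuple(self.planted)

    def panel(self, hdac_genes: tuple[str, ...] = DEFAULT_HDAC_PREDICTORS) -> GenePanel:
        """Gene panel covering all simulated RTKs."""
        return GenePanel(
            hdac_predictors=hdac_genes,
            rtk_genes=tuple(self.planted) + self.null_rtks,
        )


def default_cohort_spec(
    n_samples: int = 500,
    n_planted: int = 5,
    n_null_rtks: int = 15,
    noise_sd: float = 0.5,
    seed: int = 0,
    weight_low: float = 1.0,
    weight_high: float = 2.0,
) -> CohortSpec:
    """Cohort spec with dependencies planted on the class I enzymes.

    Each planted RTK loads on HDAC1, HDAC2, HDAC3 and HDAC8 with
    weights drawn uniformly in [weight_low, weight_high] (seeded), so
    SCORE and SCORE I rank the planted set identically.
    """
    if n_planted > len(_PLANTED_RTKS):
        raise InputError(f"at most {len(_PLANTED_RTKS)} planted RTKs supported by default")
    if n_null_rtks > len(_NULL_RTKS):
        raise InputError(f"at most {len(_NULL_RTKS)} null RTKs supported by default")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    loaded = [0, 1, 2, 7]  # HDAC1, HDAC2, HDAC3, HDAC8
    planted = {}
    for gene in _PLANTED_RTKS[:n_planted]:
        w = np.zeros(8)
        w[loaded] = rng.uniform(weight_low, weight_high, size=len(loaded))
        planted[gene] = (1.0, w)
    return CohortSpec(
        n_samples=n_samples,
        planted=planted,
        n_null_rtks=n_null_rtks,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw a cohort under the linear HDAC->RTK model.

    HDAC rows are multivariate normal; each planted RTK row is
    ``y0 + X w + N(0, noise_sd)``; null RTK rows are independent normal.
    Deterministic given ``spec.seed``.
    """
    p = len(spec.hdac_genes)
    ss = np.random.SeedSequence(spec.seed)
    rng_hdac, rng_noise, rng_null = (np.random.default_rng(s) for s in ss.spawn(3))

    hdac = rng_hdac.multivariate_normal(
        spec.hdac_means, spec.hdac_cov, size=spec.n_samples, method="cholesky"
    ).T  # p x n

    rows = [hdac]
    gene_ids = list(spec.hdac_genes)
    for gene, (y0, w) in spec.planted.items():
        signal = y0 + w @ hdac
        noise = rng_noise.normal(0.0, spec.noise_sd, size=spec.n_samples) if spec.noise_sd else 0.0
        rows.append((signal + noise)[None, :])
        gene_ids.append(gene)

    null_names = tuple(g for g in _NULL_RTKS if g not in spec.planted)[: spec.n_null_rtks]
    if len(null_names) < spec.n_null_rtks:
        extra = tuple(f"RTK_NULL{i}" for i in range(spec.n_null_rtks - len(null_names)))
        null_names = null_names + extra
    for gene in null_names:
        rows.append(rng_null.normal(spec.null_mean, spec.null_sd, size=spec.n_samples)[None, :])
        gene_ids.append(gene)

    values = np.vstack(rows)
    sample_ids = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    truth = CohortTruth(planted=dict(spec.planted), null_rtks=null_names, seed=spec.seed)
    return expr, truth


@dataclass
class SurfaceSpec:
    """Generating process of a two-drug combination matrix.

    Single-agent inhibition follows the 4PL parameters of each drug;
    combined inhibition is the Bliss expectation plus ``excess``
    (a scalar or a per-cell matrix over nonzero dose pairs), clamped to
    [0, 1]; Gaussian noise (in % viability) is added to every cell.
    """

    drug_a_params: dict = field(
        default_factory=lambda: {"top": 100.0, "bottom": 0.0, "hill": 1.0, "ec50": 2.0}
    )
    drug_b_params: dict = field(
        default_factory=lambda: {"top": 100.0, "bottom": 0.0, "hill": 1.0, "ec50": 2.0}
    )
    doses_a: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.25, 0.5, 1.0, 2.0]))
    doses_b: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.25, 0.5, 1.0, 2.0]))
    excess: float | np.ndarray = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        if self.doses_a[0] != 0.0 or self.doses_b[0] != 0.0:
            raise InputError("dose grids must start at 0 (untreated anchors)")
        exc = np.asarray(self.excess, dtype=float)
        if np.any(exc <= -1.0) or np.any(exc >= 1.0):
            raise InputError("excess must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


def simulate_combination(spec: SurfaceSpec) -> tuple[DoseResponseMatrix, dict]:
    """Build a combination matrix with a planted Bliss excess.

    Returns the matrix and a truth record with the realised mean planted
    excess over non-zero dose pairs (after any clamping).
    """
    na, nb = len(spec.doses_a), len(spec.doses_b)
    inh_a = 1.0 - four_pl(spec.doses_a, **spec.drug_a_params) / 100.0
    inh_b = 1.0 - four_pl(spec.doses_b, **spec.drug_b_params) / 100.0
    inh_a[0] = 0.0
    inh_b[0] = 0.0

    inhibition = np.zeros((na, nb))
    inhibition[:, 0] = inh_a
    inhibition[0, :] = inh_b
    expected = bliss_expected(inh_a[1:, None], inh_b[None, 1:])
    exc = np.broadcast_to(np.asarray(spec.excess, dtype=float), expected.shape)
    combo = np.clip(expected + exc, 0.0, 1.0)
    inhibition[1:, 1:] = combo

    viability = 100.0 * (1.0 - inhibition)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        viability = viability + rng.normal(0.0, spec.noise_sd, size=viability.shape)

    matrix = DoseResponseMatrix(doses_a=spec.doses_a, doses_b=spec.doses_b, viability=viability)
    truth = {
        "mean_planted_excess": float((combo - expected).mean()),
        "seed": spec.seed,
    }
    return matrix, truth


def simulate_dose_response(
    params: dict,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Noisy % viability at ``doses`` under a 4PL curve (seeded)."""
    doses = np.asarray(doses, dtype=float)
    v = four_pl(doses, **params)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        v = v + rng.normal(0.0, noise_sd, size=doses.shape)
    return v
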