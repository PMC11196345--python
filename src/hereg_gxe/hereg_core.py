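"""Haseman-Elston regression machinery.

Builds squared-difference responses ``Y_ij = (y_i - y_j)^2`` against a
genetic-sharing predictor and fits the ordinary-least-squares regression
``Y = mu + slope * x + e`` for the four designs:

==================  =========================================
design tag          predictor x
==================  =========================================
linkage-single      single-locus sib IBD, pi in {0, 1/2, 1}
linkage-genome      genome-wide sib IBD, pi_tilde
assoc-single        single-marker IBS score z_i * z_j
assoc-genome        relatedness score s_ij = mean_l z_il z_jl
==================  =========================================

Under the additive (or crossover-GxE) model the slope expectation is
``-2 h^2``, so every fit also reports the implied heritability
``-slope / 2`` (unclamped: sampling noise may push it negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gxe_sim import GenomeIBDPairs, SibPairSample, UnrelatedSample

LINKAGE_SINGLE = "linkage-single"
LINKAGE_GENOME = "linkage-genome"
ASSOC_SINGLE = "assoc-single"
ASSOC_GENOME = "assoc-genome"
DESIGNS = (LINKAGE_SINGLE, ASSOC_SINGLE, LINKAGE_GENOME, ASSOC_GENOME)


def squared_difference_response(y_i, y_j):
    """``Y_ij = (y_i - y_j)^2`` for paired phenotypes (scalar or array)."""
    y_i = np.asarray(y_i, dtype=float)
    y_j = np.asarray(y_j, dtype=float)
    if not (np.all(np.isfinite(y_i)) and np.all(np.isfinite(y_j))):
        raise ValueError("phenotypes must be finite")
    return (y_i - y_j) ** 2


@dataclass(frozen=True)
class PairedResponse:
    """HE regression input: response ``y`` (squared differences) against
    predictor ``x`` (pi, pi_tilde or s_ij) with a design tag."""

    y: np.ndarray
    x: np.ndarray
    design: str

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if len(self.y) != len(self.x):
            raise ValueError("response and predictor length mismatch")
        if np.any(np.asarray(self.y) < 0):
            raise ValueError("squared-difference response must be >= 0")
        if self.design.startswith("linkage"):
            x = np.asarray(self.x)
            if np.any((x < 0) | (x > 1)):
                raise ValueError("IBD predictor must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    @classmethod
    def from_sibpairs(cls, sample: SibPairSample) -> "PairedResponse":
        return cls(y=squared_difference_response(sample.y1, sample.y2),
                   x=np.asarray(sample.pi, dtype=float), design=LINKAGE_SINGLE)

    @classmethod
    def from_genome_ibd(cls, pairs: GenomeIBDPairs) -> "PairedResponse":
        return cls(y=squared_difference_response(pairs.y1, pairs.y2),
                   x=np.asarray(pairs.pi_tilde, dtype=float),
                   design=LINKAGE_GENOME)

    @classmethod
    def from_unrelated(cls, sample: UnrelatedSample,
                       standardization: str = "sample") -> "PairedResponse":
        """All n(n-1)/2 pairs of an unrelated cohort against the IBS
        relatedness score (design assoc-single when m = 1).

        ``standardization='population'`` uses the generating-frequency
        standardized genotypes, the convention under which the analytic
        sampling SEs hold exactly (sample centering introduces O(1/n)
        cross-pair dependence that deflates the slope variance).
        """
        if standardization == "sample":
            scores = relatedness_scores(sample.z)
        elif standardization == "population":
            scores = relatedness_scores(sample.z_pop, validate=False)
        else:
            raise ValueError(f"unknown standardization {standardization!r}")
        iu = np.triu_indices(sample.n, k=1)
        yy = squared_difference_response(sample.y[iu[0]], sample.y[iu[1]])
        design = ASSOC_SINGLE if sample.m == 1 else ASSOC_GENOME
        return cls(y=yy, x=scores.s, design=design)


@dataclass(frozen=True)
class HEFit:
    """Fitted HE regression."""

    design: str
    intercept: float
    slope: float
    se: float
    t: float
    df: int
    n_pairs: int

    @property
    def h2_implied(self) -> float:
        return heritability_from_slope(self.slope)

    def to_record(self) -> dict:
        return {
            "design": self.design, "slope": self.slope, "se": self.se,
            "t": self.t, "df": self.df, "n_pairs": self.n_pairs,
            "h2_implied": self.h2_implied,
        }


def _ols_from_sums(n, sx, sy, sxx, syy, sxy, df):
    """Simple-regression fit from raw sums; used by both the explicit-pair
    and the pair-moment paths so they are algebraically identical."""
    Sxx = sxx - sx * sx / n
    Sxy = sxy - sx * sy / n
    Syy = syy - sy * sy / n
    if Sxx <= 0:
        raise ValueError("degenerate design: constant predictor")
    slope = Sxy / Sxx
    intercept = (sy - slope * sx) / n
    rss = max(Syy - slope * Sxy, 0.0)
    if df <= 0:
        raise ValueError("insufficient data: need more pairs than parameters")
    sigma2 = rss / df
    se = np.sqrt(sigma2 / Sxx)
    t = slope / se if se > 0 else np.inf * np.sign(slope)
    return float(intercept), float(slope), float(se), float(t)


def he_fit(pairs: PairedResponse) -> HEFit:
    """Ordinary least squares of ``Y`` on the sharing predictor, with
    intercept; SE from the residual mean square with df = n_pairs - 2.

    For the association designs the rows already are the n(n-1)/2
    exchangeable pairs, so the same df convention applies.
    """
    n = pairs.n_pairs
    if n < 3:
        raise ValueError(f"insufficient data: need >= 3 pairs, got {n}")
    x = np.asarray(pairs.x, dtype=float)
    y = np.asarray(pairs.y, dtype=float)
    intercept, slope, se, t = _ols_from_sums(
        n, x.sum(), y.sum(), (x * x).sum(), (y * y).sum(), (x * y).sum(),
        df=n - 2)
    return HEFit(design=pairs.design, intercept=intercept, slope=slope,
                 se=se, t=t, df=n - 2, n_pairs=n)


def he_fit_assoc_single(y: np.ndarray, z: np.ndarray) -> HEFit:
    """Single-marker association HE fit over all n(n-1)/2 pairs in O(n).

    Exact pair-moment identity: every pair sum that the OLS normal
    equations need (of ``x = z_i z_j``, ``Y = (y_i - y_j)^2`` and their
    products) collapses to per-individual power sums, so this equals
    ``he_fit`` on the explicitly enumerated pairs to machine precision
    while scaling to cohorts where enumeration is infeasible.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float).reshape(-1)
    n = len(y)
    if n < 3:
        raise ValueError("insufficient data: need >= 3 individuals")
    if len(z) != n:
        raise ValueError("phenotype/genotype length mismatch")
    N = n * (n - 1) // 2
    Z1, Z2, Z4 = z.sum(), (z ** 2).sum(), (z ** 4).sum()
    M1, M2, M3, M4 = y.sum(), (y ** 2).sum(), (y ** 3).sum(), (y ** 4).sum()
    B = (y ** 2 * z).sum()
    C = (y * z).sum()
    sx = (Z1 * Z1 - Z2) / 2.0
    sxx = (Z2 * Z2 - Z4) / 2.0
    sy = n * M2 - M1 * M1
    syy = ((n - 1) * M4 - 4.0 * (M3 * M1 - M4) + 3.0 * (M2 * M2 - M4))
    sxy = B * Z1 - C * C
    intercept, slope, se, t = _ols_from_sums(N, sx, sy, sxx, syy, sxy,
                                             df=N - 2)
    return HEFit(design=ASSOC_SINGLE, intercept=intercept, slope=slope,
                 se=se, t=t, df=N - 2, n_pairs=N)


@dataclass(frozen=True)
class RelatednessScores:
    """Pairwise IBS relatedness scores and the mean squared marker
    correlation of the panel that produced them."""

    s: np.ndarray       # condensed upper-triangle, pair order (i<j)
    m: int
    rho2mm: float


def relatedness_scores(z: np.ndarray, validate: bool = True,
                       small_sample_correction: bool = False
                       ) -> RelatednessScores:
    """Relatedness scores ``s_ij = (1/m) sum_l z_il z_jl`` for all pairs.

    ``rho2mm`` is the plug-in mean squared pairwise marker correlation
    ``(1/m^2) sum sum rho^2`` (equal to 1 when m = 1).  The optional
    small-sample correction subtracts the off-diagonal noise floor
    ``(m-1)/(m n)``; it is off by default because the analytic statistics
    use population values.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, m = z.shape
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 markers")
    if validate:
        mu = z.mean(axis=0)
        var = z.var(axis=0, ddof=0)
        if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(var - 1.0) > 1e-6):
            raise ValueError(
                "genotype columns must be standardized (mean 0, variance 1); "
                "use gxe_sim.standardize_columns")
    grm = (z @ z.T) / m
    iu = np.triu_indices(n, k=1)
    s = grm[iu]
    if m == 1:
        rho2 = 1.0
    else:
        corr = (z.T @ z) / n
        rho2 = float((corr ** 2).mean())
        if small_sample_correction:
            rho2 = max(rho2 - (m - 1) / (m * n), 1.0 / m)
    return RelatednessScores(s=s, m=m, rho2mm=rho2)


@dataclass(frozen=True)
class GwasFit:
    """Single-locus GWAS marginal-effect fit ``y = mu + a z + e``."""

    slope: float
    se: float
    t: float
    r2: float
    n: int


def gwas_fit(y: np.ndarray, z: np.ndarray) -> GwasFit:
    """OLS marginal effect of a single standardized marker, with intercept.

    The t statistic is consistent with ``sqrt((n-2) R^2 / (1 - R^2))``
    where ``R^2`` is the realized variance explained.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float).reshape(-1)
    n = len(y)
    if n < 3:
        raise ValueError("insufficient data: need n >= 3")
    intercept, slope, se, t = _ols_from_sums(
        n, z.sum(), y.sum(), (z ** 2).sum(), (y ** 2).sum(), (z * y).sum(),
        df=n - 2)
    Sxx = (z ** 2).sum() - z.sum() ** 2 / n
    Syy = (y ** 2).sum() - y.sum() ** 2 / n
    Sxy = (z * y).sum() - z.sum() * y.sum() / n
    r2 = (Sxy * Sxy) / (Sxx * Syy) if Syy > 0 else 0.0
    return GwasFit(slope=slope, se=se, t=t, r2=float(r2), n=n)


def heritability_from_slope(slope: float) -> float:
    """Implied heritability ``-slope / 2`` (the HE slope expectation is
    ``-2 h^2`` once the recombination factor is dropped)."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return -float(slope) / 2.0


def fits_to_dataframe(fits: list[HEFit]) -> pd.DataFrame:
    return pd.DataFrame([f.to_record() for f in fits])
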