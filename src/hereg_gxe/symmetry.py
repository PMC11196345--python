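"""Symmetry tests: linkage vs association HE slopes from summary statistics.

Under a purely additive architecture the linkage and association HE
regressions estimate the same heritability, so their slopes agree in
expectation ("symmetry").  A crossover GxE component is captured by the
linkage slope but cancels in association, so a significant slope contrast
signals GxE.  Test I contrasts the single-locus designs, Test II the
whole-genome designs; both are Welch-style contrasts that need only
(slope, SE, sample size) from each arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import analytic_stats
from .hereg_core import (ASSOC_GENOME, ASSOC_SINGLE, DESIGNS, HEFit,
                         LINKAGE_GENOME, LINKAGE_SINGLE,
                         heritability_from_slope)

_SINGLE = {LINKAGE_SINGLE, ASSOC_SINGLE}
_GENOME = {LINKAGE_GENOME, ASSOC_GENOME}


@dataclass(frozen=True)
class SummaryStatistic:
    """One arm of a symmetry test: design tag, signed slope estimate
    (= -2 x implied heritability), its SE, and the sample size (sib pairs
    for linkage, individuals for association)."""

    design: str
    slope: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if not self.se > 0:
            raise ValueError(f"SE must be positive, got {self.se}")
        if self.n < 3:
            raise ValueError(f"sample size must be >= 3, got {self.n}")

    @property
    def h2_implied(self) -> float:
        return heritability_from_slope(self.slope)

    @classmethod
    def from_fit(cls, fit: HEFit, n: int) -> "SummaryStatistic":
        """Note: ``n`` is the design's sample size (individuals for
        association), not the pair count stored in the fit."""
        return cls(design=fit.design, slope=fit.slope, se=fit.se, n=n)

    @classmethod
    def from_h2(cls, design: str, h2: float, n: int, *,
                se: float | None = None, L: float = analytic_stats.DEFAULT_L,
                rho2mm: float = 1.0) -> "SummaryStatistic":
        """Build a summary record from an implied heritability; when no SE
        is supplied the design's analytic (sigma_B) formula imputes it."""
        if se is None:
            se = analytic_stats.slope_se(design, n, abs(h2), L=L,
                                         rho2mm=rho2mm)
        return cls(design=design, slope=-2.0 * h2, se=se, n=n)


@dataclass(frozen=True)
class SymmetryResult:
    """Outcome of a symmetry test."""

    test: str                  # "I" or "II"
    t: float
    chi2: float
    p_value: float
    h2_linkage: float
    h2_assoc: float

    @property
    def gxe_estimate(self) -> float:
        """Heritability gap: the GxE component the linkage arm captured."""
        return self.h2_linkage - self.h2_assoc


def symmetry_test(linkage: SummaryStatistic,
                  assoc: SummaryStatistic) -> SymmetryResult:
    """Welch-style contrast of the linkage and association HE slopes.

    ``t = (slope_L - slope_A) / sqrt(SE_L^2 + SE_A^2)``; ``t^2`` is
    referred to a central 1-df chi-square for the p-value (the intended
    sample sizes are large, so no Welch-Satterthwaite df is used).
    """
    if linkage.design not in (LINKAGE_SINGLE, LINKAGE_GENOME):
        raise ValueError(f"first argument must be a linkage summary, got "
                         f"{linkage.design!r}")
    if assoc.design not in (ASSOC_SINGLE, ASSOC_GENOME):
        raise ValueError(f"second argument must be an association summary, "
                         f"got {assoc.design!r}")
    both_single = {linkage.design, assoc.design} <= _SINGLE
    both_genome = {linkage.design, assoc.design} <= _GENOME
    if not (both_single or both_genome):
        raise ValueError(
            "design mismatch: single-locus and whole-genome summaries "
            f"cannot be contrasted ({linkage.design} vs {assoc.design})")
    t = (linkage.slope - assoc.slope) / np.sqrt(linkage.se ** 2
                                                + assoc.se ** 2)
    chi2 = t * t
    p = float(stats.chi2.sf(chi2, df=1))
    return SymmetryResult(
        test="I" if both_single else "II", t=float(t), chi2=float(chi2),
        p_value=p, h2_linkage=linkage.h2_implied, h2_assoc=assoc.h2_implied)


def ncp_symmetry_I(h2_LS: float, h2_AS: float, n_LS: int, n_AS: int) -> float:
    """Noncentrality of Symmetry Test I.

    ``(2 h2_LS - 2 h2_AS)^2`` over the sum of the two slope sampling
    variances: ``[64(1 - h2_LS) + 12 h2_LS^2]/n_LS`` for the linkage arm
    and ``2 (8 - 4 h2_AS^2)/n_AS^2`` for the association arm.
    """
    for h2 in (h2_LS, h2_AS):
        if not 0 <= h2 < 1:
            raise ValueError(f"heritability must be in [0,1), got {h2}")
    for n in (n_LS, n_AS):
        if n < 3:
            raise ValueError(f"sample size must be >= 3, got {n}")
    num = (2.0 * h2_LS - 2.0 * h2_AS) ** 2
    den = ((64.0 * (1.0 - h2_LS) + 12.0 * h2_LS ** 2) / n_LS
           + 2.0 * (8.0 - 4.0 * h2_AS ** 2) / n_AS ** 2)
    return num / den


def ncp_symmetry_II(h2_LW: float, h2_AW: float, n_LW: int, n_AW: int,
                    L: float = analytic_stats.DEFAULT_L,
                    rho2mm: float = 1e-5) -> float:
    """Noncentrality of Symmetry Test II (whole-genome designs).

    Linkage-arm variance ``[16 L (2 h2_LW^2 + 8 (1 - h2_LW)) - 4 h2_LW^2]
    / n_LW``; association-arm variance
    ``2 (8 - 4 h2_AW^2 rho2mm) / (rho2mm n_AW^2)``.
    """
    for h2 in (h2_LW, h2_AW):
        if not 0 <= h2 < 1:
            raise ValueError(f"heritability must be in [0,1), got {h2}")
    for n in (n_LW, n_AW):
        if n < 3:
            raise ValueError(f"sample size must be >= 3, got {n}")
    if L <= 0:
        raise ValueError("L must be positive")
    if not 0 < rho2mm <= 1:
        raise ValueError("rho2mm must be in (0,1]")
    num = (2.0 * h2_LW - 2.0 * h2_AW) ** 2
    den = ((16.0 * L * (2.0 * h2_LW ** 2 + 8.0 * (1.0 - h2_LW))
            - 4.0 * h2_LW ** 2) / n_LW
           + 2.0 * (8.0 - 4.0 * h2_AW ** 2 * rho2mm) / (rho2mm * n_AW ** 2))
    return num / den


def symmetry_power_grid(test: str = "II",
                        gxe_grid=tuple(np.round(np.arange(0.0, 0.201, 0.02), 3)),
                        h2_baselines=(0.25, 0.6),
                        n_linkage=(50_000, 150_000, 300_000),
                        n_assoc=(10_000, 100_000),
                        alpha: float = analytic_stats.DEFAULT_ALPHA,
                        L: float = analytic_stats.DEFAULT_L,
                        rho2mm: float = 1e-5) -> pd.DataFrame:
    """Power table over a GxE grid for the experimental layout of the
    symmetry analyses.

    For each baseline heritability h2, the linkage arm sees h2 + GxE and
    the association arm sees h2 (Test II) or 0 + GxE vs 0 style single-locus
    contrast (Test I, where the baseline is the association h2).
    """
    if test not in ("I", "II"):
        raise ValueError("test must be 'I' or 'II'")
    rows = []
    for h2 in h2_baselines:
        for g in gxe_grid:
            h2_link = h2 + g
            if not h2_link < 1:
                raise ValueError(f"h2 + GxE = {h2_link} out of range")
            for nl in n_linkage:
                for na in n_assoc:
                    if test == "I":
                        ncp_val = ncp_symmetry_I(h2_link, h2, nl, na)
                    else:
                        ncp_val = ncp_symmetry_II(h2_link, h2, nl, na,
                                                  L=L, rho2mm=rho2mm)
                    power = analytic_stats.power_noncentral_chisq(
                        ncp_val, alpha)
                    rows.append({
                        "test": test, "h2_baseline": h2, "gxe": g,
                        "h2_linkage": h2_link, "n_linkage": nl,
                        "n_assoc": na, "ncp": ncp_val, "power": power,
                    })
    return pd.DataFrame(rows)
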