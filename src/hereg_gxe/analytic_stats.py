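"""Closed-form HE-regression test statistics, noncentrality, and power.

The four designs share the skeleton ``t = B / sigma_B`` with slope
expectation ``B = -2 h^2`` and a design-specific sampling SE built from
``var(Y) = 8 (1-theta)^2 h^4 + 8 (1-h^2)`` (variance of the squared sib
difference; ``theta = 1/2`` for sib pairs) and the predictor variance
(1/8 for single-locus sib IBD, ``1/(16 L)`` for genome-wide IBD with map
length ``L`` Morgans, and the mean squared marker correlation
``rho2mm`` for IBS scores).

Squared t statistics are referred to a 1-df noncentral chi-square for
power; the per-test type-I rate defaults to the genome-wide-scan level
``0.05 / 1,000,000``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hereg_core import (ASSOC_GENOME, ASSOC_SINGLE, DESIGNS, LINKAGE_GENOME,
                         LINKAGE_SINGLE)

DEFAULT_THETA = 0.5
DEFAULT_L = 32.0          # Morgans, 22 human autosomes
DEFAULT_ALPHA = 0.05 / 1_000_000


@dataclass(frozen=True)
class DesignSpec:
    """Constants attached to a design: pair type theta, map length L,
    marker panel rho2mm."""

    design: str
    theta: float = DEFAULT_THETA
    L: float = DEFAULT_L
    rho2mm: float = 1.0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0,1]")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not 0 < self.rho2mm <= 1:
            raise ValueError("rho2mm must be in (0,1]")


@dataclass(frozen=True)
class TestStat:
    """Analytic t statistic (signed) with its approximate form and the
    implied noncentrality ``t^2``."""

    design: str
    t: float
    t_approx: float
    n: int
    h2: float

    @property
    def ncp(self) -> float:
        return self.t * self.t


def _check_nh2(n: int, h2: float) -> None:
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not 0 <= h2 < 1:
        raise ValueError(f"h2 must be in [0,1), got {h2}")


def var_squared_difference(h2: float, theta: float = DEFAULT_THETA) -> float:
    """Variance of the squared sib difference:
    ``8 (1-theta)^2 h^4 + 8 (1-h^2)`` (equals 8 under the null)."""
    if not 0 <= h2 <= 1:
        raise ValueError(f"h2 must be in [0,1], got {h2}")
    if not 0 <= theta <= 1:
        raise ValueError(f"theta must be in [0,1], got {theta}")
    return 8.0 * (1.0 - theta) ** 2 * h2 ** 2 + 8.0 * (1.0 - h2)


def t_linkage_single(n: int, h2: float,
                     theta: float = DEFAULT_THETA) -> TestStat:
    """Single-locus linkage t-test for sib pairs.

    Exact form ``-sqrt(n-2) / sqrt([16(1-theta)^2 - 1] + 16(1-h2)/h2^2)``
    (the denominator is 3 + 16(1-h2)/h^4 at theta = 1/2), with the small-h2
    approximation ``-(h2/4) sqrt(n)``.
    """
    _check_nh2(n, h2)
    if h2 == 0:
        return TestStat(LINKAGE_SINGLE, 0.0, 0.0, n, h2)
    denom = (16.0 * (1.0 - theta) ** 2 - 1.0) + 16.0 * (1.0 - h2) / h2 ** 2
    t = -np.sqrt(n - 2) / np.sqrt(denom)
    return TestStat(LINKAGE_SINGLE, float(t), -(h2 / 4.0) * np.sqrt(n), n, h2)


def t_assoc_single(n: int, h2: float) -> TestStat:
    """Single-marker association (IBS) HE t-test over all n(n-1)/2 pairs:
    ``-sqrt(n(n-1)/2 - 2) / sqrt(2/h^4 - 1)``, approximately
    ``-(n/2) h2``."""
    _check_nh2(n, h2)
    if h2 == 0:
        return TestStat(ASSOC_SINGLE, 0.0, 0.0, n, h2)
    npairs = n * (n - 1) / 2.0
    t = -np.sqrt(npairs - 2.0) / np.sqrt(2.0 / h2 ** 2 - 1.0)
    return TestStat(ASSOC_SINGLE, float(t), -(n / 2.0) * h2, n, h2)


def t_linkage_genome(n: int, htilde2: float, L: float = DEFAULT_L,
                     theta: float = DEFAULT_THETA) -> TestStat:
    """Whole-genome linkage t-test on genome-wide IBD:
    ``-sqrt(n-2) / sqrt(16 L [2(1-theta)^2 + 2(1-h2)/h^4] - 1)``."""
    _check_nh2(n, htilde2)
    if L <= 0:
        raise ValueError(f"genetic length must be positive, got {L}")
    if htilde2 == 0:
        return TestStat(LINKAGE_GENOME, 0.0, 0.0, n, htilde2)
    denom = 16.0 * L * (2.0 * (1.0 - theta) ** 2
                        + 2.0 * (1.0 - htilde2) / htilde2 ** 2) - 1.0
    t = -np.sqrt(n - 2) / np.sqrt(denom)
    return TestStat(LINKAGE_GENOME, float(t), float(t), n, htilde2)


def t_assoc_genome(n: int, htilde2: float, rho2mm: float) -> TestStat:
    """Whole-genome association (IBS) HE t-test:
    ``-sqrt(n(n-1)/2 - 2) / sqrt((2/h^4)(1/rho2mm) - 1)``, approximately
    ``-(n/2) h2 sqrt(rho2mm)``.  With rho2mm = 1 this reduces exactly to
    the single-marker association test."""
    _check_nh2(n, htilde2)
    if not 0 < rho2mm <= 1:
        raise ValueError(f"rho2mm must be in (0,1], got {rho2mm}")
    if htilde2 == 0:
        return TestStat(ASSOC_GENOME, 0.0, 0.0, n, htilde2)
    npairs = n * (n - 1) / 2.0
    t = -np.sqrt(npairs - 2.0) / np.sqrt(2.0 / (htilde2 ** 2 * rho2mm) - 1.0)
    return TestStat(ASSOC_GENOME, float(t),
                    -(n / 2.0) * htilde2 * np.sqrt(rho2mm), n, htilde2)


def expected_assoc_slope(marker_corr: np.ndarray, causal_idx: np.ndarray,
                         beta: np.ndarray) -> tuple[float, float]:
    """Exact and collapsed expectations of the association HE slope.

    ``marker_corr`` is the m x m marker correlation matrix, ``beta`` the
    causal effects (standardized-genotype scale) at columns ``causal_idx``.
    The exact value is

        (1/m) * (-2 sum_k sum_l1 sum_l2 rho[k,l1] rho[k,l2] b_l1 b_l2)
        / rho2mm,

    and the collapsed form is ``-2 h2 * rho2_mQ / rho2mm`` with
    ``h2 = sum beta^2``; the two coincide (at ``-2 sum beta^2``) for
    independent, fully causal markers.
    """
    R = np.asarray(marker_corr, dtype=float)
    beta = np.asarray(beta, dtype=float)
    causal_idx = np.asarray(causal_idx, dtype=int)
    m = R.shape[0]
    if R.shape != (m, m):
        raise ValueError("marker_corr must be square")
    if len(beta) != len(causal_idx):
        raise ValueError("beta / causal_idx length mismatch")
    if np.any((causal_idx < 0) | (causal_idx >= m)):
        raise ValueError("causal index out of range")
    rho2mm = float((R ** 2).mean())
    v = R[:, causal_idx] @ beta               # sum_l rho[k,l] beta_l per k
    exact = (1.0 / m) * (-2.0 * float(v @ v)) / rho2mm
    q = len(causal_idx)
    rho2_mq = float((R[:, causal_idx] ** 2).sum()) / (m * q)
    h2 = float(beta @ beta)
    approx = -2.0 * h2 * rho2_mq / rho2mm
    return exact, approx


# ---------------------------------------------------------------------------
# Noncentrality and power
# ---------------------------------------------------------------------------

def ncp(design: str | DesignSpec, n: int, h2: float, *,
        L: float = DEFAULT_L, rho2mm: float = 1.0,
        form: str = "exact") -> float:
    """Noncentrality parameter of the squared t statistic for a design.

    ``form='exact'`` squares the exact t-test (default); ``form='table'``
    uses the tabulated large-n forms: ``(n/16) h^4`` (linkage-single),
    ``(n^2/4) h^4`` (assoc-single), ``(n-2)/(8L + 32L(1-h2)/h^4 - 1)``
    (linkage-genome, identical to the exact t^2 at theta = 1/2) and
    ``(n^2/4) h^4 rho2mm`` (assoc-genome).
    """
    if isinstance(design, DesignSpec):
        L, rho2mm = design.L, design.rho2mm
        design = design.design
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    _check_nh2(n, h2)
    if form == "exact":
        if design == LINKAGE_SINGLE:
            return t_linkage_single(n, h2).ncp
        if design == ASSOC_SINGLE:
            return t_assoc_single(n, h2).ncp
        if design == LINKAGE_GENOME:
            return t_linkage_genome(n, h2, L).ncp
        return t_assoc_genome(n, h2, rho2mm).ncp
    if form == "table":
        if design == LINKAGE_SINGLE:
            return n / 16.0 * h2 ** 2
        if design == ASSOC_SINGLE:
            return n ** 2 / 4.0 * h2 ** 2
        if design == LINKAGE_GENOME:
            if h2 == 0:
                return 0.0
            return (n - 2) / (8.0 * L + 32.0 * L * (1.0 - h2) / h2 ** 2 - 1.0)
        return n ** 2 / 4.0 * h2 ** 2 * rho2mm
    raise ValueError(f"form must be 'exact' or 'table', got {form!r}")


def power_noncentral_chisq(ncp_value: float, alpha: float) -> float:
    """Power of a 1-df chi-square test: upper-tail mass of
    ``chi2_1(ncp)`` beyond the central critical value at level alpha."""
    if ncp_value < 0:
        raise ValueError(f"ncp must be >= 0, got {ncp_value}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if ncp_value == 0:
        return alpha
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp_value))


def power_normal_approx(ncp_value: float, alpha: float) -> float:
    """Two-sided normal approximation ``P(Z > z_crit - sqrt(ncp))``;
    cross-check utility for the noncentral chi-square power."""
    if ncp_value < 0:
        raise ValueError("ncp must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    z_crit = np.sqrt(stats.chi2.ppf(1.0 - alpha, df=1))
    delta = np.sqrt(ncp_value)
    return float(stats.norm.sf(z_crit - delta) + stats.norm.cdf(-z_crit - delta))


DEFAULT_N_GRID = tuple(range(500_000, 10_000_001, 500_000))


def required_sample_size(design: str, h2: float,
                         alpha: float = DEFAULT_ALPHA,
                         target_power: float = 0.85,
                         n_grid=DEFAULT_N_GRID, *,
                         L: float = DEFAULT_L, rho2mm: float = 1.0,
                         form: str = "exact",
                         refine: bool = False) -> int | None:
    """Smallest grid sample size reaching ``target_power``.

    Scans the ascending ``n_grid`` (default: the 500k-step grid from
    500,000 to 10,000,000), returns the first n whose noncentral
    chi-square power meets the target, or ``None`` if the grid tops out.
    ``refine=True`` bisects between the bracketing grid points and returns
    the (labelled-exact) integer threshold instead of the grid value.
    """
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    if sorted(n_grid) != n_grid:
        raise ValueError("n_grid must be ascending")

    def pw(n: int) -> float:
        return power_noncentral_chisq(
            ncp(design, n, h2, L=L, rho2mm=rho2mm, form=form), alpha)

    hit = None
    for i, n in enumerate(n_grid):
        if pw(n) >= target_power:
            hit = i
            break
    if hit is None:
        return None
    if not refine:
        return n_grid[hit]
    lo = n_grid[hit - 1] if hit > 0 else 3
    hi = n_grid[hit]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def slope_se(design: str, n: int, h2: float, *,
             theta: float = DEFAULT_THETA, L: float = DEFAULT_L,
             rho2mm: float = 1.0) -> float:
    """Analytic sampling SE of the HE slope for a design (the sigma_B
    column of the test-statistic table).

    linkage-single:  sqrt([8 var(Y) - 4 h^4] / (n-2))
    assoc-single:    sqrt([8 - 4 h^4] / (n(n-1)/2 - 2))
    linkage-genome:  sqrt([16 L var(Y) - 4 h^4] / (n-2))
    assoc-genome:    sqrt([(8 - 4 h^4 rho2mm)/rho2mm] / (n(n-1)/2 - 2))
    """
    _check_nh2(n, h2)
    h4 = h2 ** 2
    if design == LINKAGE_SINGLE:
        return float(np.sqrt(
            (8.0 * var_squared_difference(h2, theta) - 4.0 * h4) / (n - 2)))
    if design == ASSOC_SINGLE:
        return float(np.sqrt((8.0 - 4.0 * h4) / (n * (n - 1) / 2.0 - 2.0)))
    if design == LINKAGE_GENOME:
        return float(np.sqrt(
            (16.0 * L * var_squared_difference(h2, theta) - 4.0 * h4)
            / (n - 2)))
    if design == ASSOC_GENOME:
        if not 0 < rho2mm <= 1:
            raise ValueError("rho2mm must be in (0,1]")
        return float(np.sqrt(((8.0 - 4.0 * h4 * rho2mm) / rho2mm)
                             / (n * (n - 1) / 2.0 - 2.0)))
    raise ValueError(f"unknown design {design!r}")
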