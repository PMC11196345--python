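"""Synthetic cohorts for Haseman-Elston regression under crossover GxE.

Generators for the three study designs the estimators consume:

* nuclear-family sib pairs with Mendelian transmission at a single causal
  locus, whose additive effect may flip sign between environments
  ("crossover" norm of reaction, Schemes I and II);
* unrelated cohorts genotyped at ``m`` independent (or user-correlated)
  markers for IBS-based association HE regression and single-locus GWAS;
* sib-style pairs carrying genome-wide IBD sharing for the whole-genome
  linkage design.

All phenotypes live on the unit-variance scale: the residual variance is
``1 - sigma_a^2 - sigma_d^2`` so that heritability parameters are directly
the variance fractions the downstream test statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_LABELS = {0: "bb", 1: "Bb", 2: "BB"}
_LABEL_TO_COUNT = {v: k for k, v in GENOTYPE_LABELS.items()}


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Models and locus calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GxEModel:
    """Per-environment genotype effect scheme with mixture weights.

    ``effects[f]`` maps genotype label (``BB``/``Bb``/``bb``) to its
    genotypic value in environment ``f``; ``weights[f]`` is the fraction
    of families (or individuals) drawn from that environment.
    """

    weights: tuple[float, ...]
    effects: tuple[dict[str, float], ...]
    #: optional continuous-GxE parameters: mean marginal effect and
    #: between-environment SD of the per-family additive effect
    effect_mean: float | None = None
    effect_sd: float | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.effects):
            raise ValueError("one weight per environment required")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("environment weights must be >= 0 and sum to 1")
        for eff in self.effects:
            if set(eff) != {"BB", "Bb", "bb"}:
                raise ValueError("each environment needs BB/Bb/bb values")

    @property
    def n_environments(self) -> int:
        return len(self.weights)

    @classmethod
    def crossover(cls, a: float, d: float = 0.0,
                  weights: tuple[float, float] = (0.5, 0.5)) -> "GxEModel":
        """Two-environment crossover model: Scheme I ``(a, d, -a)`` in the
        first environment, Scheme II ``(-a, d, a)`` in the second."""
        return cls(
            weights=tuple(weights),
            effects=(
                {"BB": a, "Bb": d, "bb": -a},
                {"BB": -a, "Bb": d, "bb": a},
            ),
        )

    def value(self, genotype: str | int, environment: int) -> float:
        return assign_genotype_value(genotype, environment, self)


def assign_genotype_value(genotype: str | int, environment: int,
                          model: GxEModel) -> float:
    """Genotypic value of ``genotype`` (label or 0/1/2 allele count) in the
    given environment of ``model``."""
    if isinstance(genotype, (int, np.integer)):
        try:
            genotype = GENOTYPE_LABELS[int(genotype)]
        except KeyError:
            raise ValueError(f"allele count must be 0, 1 or 2: {genotype}")
    if genotype not in _LABEL_TO_COUNT:
        raise ValueError(f"unknown genotype {genotype!r}")
    if not 0 <= environment < model.n_environments:
        raise ValueError(f"unknown environment {environment}")
    return float(model.effects[environment][genotype])


def calibrate_additive_effect(p: float, target_h2: float, d: float = 0.0) -> float:
    """Additive effect ``a`` such that the locus explains ``target_h2`` of a
    unit-variance trait: ``sigma_a^2 = 2pq [a - (p-q) d]^2``.

    With ``d=0`` this is ``a = sqrt(h2 / (2pq))``; otherwise the positive
    root of the quadratic is taken.
    """
    if not 0 < p < 1:
        raise ValueError(f"allele frequency must be in (0,1), got {p}")
    if not 0 <= target_h2 < 1:
        raise ValueError(f"target_h2 must be in [0,1), got {target_h2}")
    q = 1.0 - p
    return (p - q) * d + np.sqrt(target_h2 / (2.0 * p * q))


def dominance_variance(p: float, d: float) -> float:
    q = 1.0 - p
    return 4.0 * p * p * q * q * d * d


@dataclass(frozen=True)
class LocusSpec:
    """A biallelic causal locus calibrated to a target variance fraction."""

    p: float
    target_h2: float
    d: float = 0.0
    a: float = field(init=False)

    def __post_init__(self) -> None:
        a = calibrate_additive_effect(self.p, self.target_h2, self.d)
        object.__setattr__(self, "a", a)
        if self.sigma_a2 + self.sigma_d2 >= 1.0:
            raise ValueError(
                "infeasible variance budget: sigma_a^2 + sigma_d^2 = "
                f"{self.sigma_a2 + self.sigma_d2:.4f} >= 1"
            )

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def sigma_a2(self) -> float:
        return 2.0 * self.p * self.q * (self.a - (self.p - self.q) * self.d) ** 2

    @property
    def sigma_d2(self) -> float:
        return dominance_variance(self.p, self.d)

    @property
    def sigma_e2(self) -> float:
        return 1.0 - self.sigma_a2 - self.sigma_d2


def sample_allele_frequency(rng: int | np.random.Generator | None = None,
                            size: int | None = None):
    """Random reference-allele frequency, Uniform(0.01, 0.5)."""
    return _as_rng(rng).uniform(0.01, 0.5, size=size)


# ---------------------------------------------------------------------------
# Mendelian machinery
# ---------------------------------------------------------------------------

def draw_parent_genotypes(K: int, p: float,
                          seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Labelled parental alleles for ``K`` families under HWE.

    Returns an int array of shape ``(K, 2, 2)``: family x parent x allele
    copy, each entry 1 (reference allele ``B``) with probability ``p``.
    Allele *positions* are retained so IBD is computable after transmission.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if not 0 <= p <= 1:
        raise ValueError(f"allele frequency must be in [0,1], got {p}")
    if p in (0.0, 1.0):
        # degenerate but well-defined: monomorphic population
        return np.full((K, 2, 2), int(p), dtype=np.int8)
    rng = _as_rng(seed)
    return (rng.random((K, 2, 2)) < p).astype(np.int8)


def mendelian_transmit(parent_alleles: np.ndarray,
                       seed: int | np.random.Generator | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transmit alleles to a sib pair and record single-locus IBD.

    Each child inherits one uniformly chosen allele copy from each parent.
    pi counts the parents from whom both sibs inherited the same copy,
    divided by 2, so pi in {0, 1/2, 1}.

    Returns ``(g1, g2, pi)``: allele counts (0/1/2) of the two sibs and the
    IBD proportion, each of length ``K``.
    """
    parent_alleles = np.asarray(parent_alleles)
    if parent_alleles.ndim != 3 or parent_alleles.shape[1:] != (2, 2):
        raise ValueError("parent_alleles must have shape (K, 2, 2)")
    K = parent_alleles.shape[0]
    rng = _as_rng(seed)
    # chosen allele copy index, per child x parent
    idx = rng.integers(0, 2, size=(K, 2, 2))  # family x child x parent
    fam = np.arange(K)[:, None]
    par = np.arange(2)[None, :]
    g1 = parent_alleles[fam, par, idx[:, 0, :]].sum(axis=1)
    g2 = parent_alleles[fam, par, idx[:, 1, :]].sum(axis=1)
    pi = (idx[:, 0, :] == idx[:, 1, :]).sum(axis=1) / 2.0
    return g1.astype(np.int8), g2.astype(np.int8), pi


# ---------------------------------------------------------------------------
# Sib-pair cohorts
# ---------------------------------------------------------------------------

@dataclass
class SibPairSample:
    """Simulated sib pairs: one record per family.

    ``env`` is the family-level environment index (0 = Scheme I,
    1 = Scheme II for the crossover model); ``pi`` the single-locus IBD.
    Parents are carried along (optional) so the same families can feed a
    pooled-parent GWAS sample.
    """

    family_id: np.ndarray
    env: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    pi: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    locus: LocusSpec | None = None
    model: GxEModel | None = None
    parent_genotypes: np.ndarray | None = None  # (K, 2) allele counts
    parent_phenotypes: np.ndarray | None = None  # (K, 2)

    @property
    def n_pairs(self) -> int:
        return len(self.family_id)

    @property
    def env_counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.env, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "family_id": self.family_id,
            "env": self.env,
            "y1": self.y1,
            "y2": self.y2,
            "pi": self.pi,
        })

    def parents_pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pooled parent sample ``(genotype counts, phenotypes, env)`` for
        GWAS, 2 per family."""
        if self.parent_genotypes is None or self.parent_phenotypes is None:
            raise ValueError("sample was generated without include_parents")
        g = self.parent_genotypes.reshape(-1)
        y = self.parent_phenotypes.reshape(-1)
        env = np.repeat(self.env, 2)
        return g, y, env


def simulate_sibpairs(K1: int, K2: int, p: float | None = None,
                      target_h2: float = 0.0, d: float = 0.0,
                      effect_sd: float = 0.0,
                      seed: int | np.random.Generator | None = None,
                      include_parents: bool = False,
                      randomize_env: bool = False) -> SibPairSample:
    """Simulate ``K1`` Scheme-I and ``K2`` Scheme-II nuclear families.

    Each family contributes a sib pair with phenotype ``y = G + e``,
    ``e ~ N(0, 1 - sigma_a^2 - sigma_d^2)``, where ``G`` is the crossover
    genotypic value in the family's environment.  Families are assigned
    deterministically by order (first ``K1`` to Scheme I) unless
    ``randomize_env`` shuffles the labels.

    ``effect_sd`` switches on the continuous-GxE variant: each family's
    additive effect is drawn ``N(a, effect_sd^2)`` (requires ``d = 0``),
    so the variance captured by linkage becomes
    ``2pq (a^2 + effect_sd^2)`` while the marginal (association) effect
    stays at ``a``.
    """
    if K1 < 0 or K2 < 0 or K1 + K2 < 2:
        raise ValueError("need K1, K2 >= 0 with K1 + K2 >= 2")
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if effect_sd > 0 and d != 0:
        raise ValueError("continuous-GxE variant requires d = 0")
    rng = _as_rng(seed)
    if p is None:
        p = float(sample_allele_frequency(rng))
    K = K1 + K2
    locus = LocusSpec(p=p, target_h2=target_h2, d=d)
    if effect_sd > 0:
        h2_link = 2 * p * (1 - p) * (locus.a ** 2 + effect_sd ** 2)
        if h2_link + locus.sigma_d2 >= 1.0:
            raise ValueError(
                "infeasible variance budget: sigma_a^2 + sigma_d^2 = "
                f"{h2_link + locus.sigma_d2:.4f} >= 1")
        sigma_e2 = 1.0 - h2_link
    else:
        sigma_e2 = locus.sigma_e2
    model = GxEModel.crossover(locus.a, d, weights=(K1 / K, K2 / K))

    env = np.concatenate([np.zeros(K1, dtype=np.int8),
                          np.ones(K2, dtype=np.int8)])
    if randomize_env:
        rng.shuffle(env)

    parents = draw_parent_genotypes(K, p, rng)
    g1, g2, pi = mendelian_transmit(parents, rng)

    # crossover decomposition: value = sign_env * a_fam * (g - 1) + d*[g==1]
    sign = np.where(env == 0, 1.0, -1.0)
    a_fam = locus.a + (rng.normal(0.0, effect_sd, size=K)
                       if effect_sd > 0 else 0.0)
    add = sign * a_fam

    def value(g: np.ndarray) -> np.ndarray:
        return add * (g - 1.0) + d * (g == 1)

    e = rng.normal(0.0, np.sqrt(sigma_e2), size=(K, 2))
    y1 = value(g1) + e[:, 0]
    y2 = value(g2) + e[:, 1]

    pg = pp = None
    if include_parents:
        pg = parents.sum(axis=2)  # (K, 2) allele counts
        pe = rng.normal(0.0, np.sqrt(sigma_e2), size=(K, 2))
        pp = (add[:, None] * (pg - 1.0) + d * (pg == 1)) + pe

    return SibPairSample(
        family_id=np.arange(K), env=env, y1=y1, y2=y2, pi=pi,
        g1=g1, g2=g2, locus=locus, model=model,
        parent_genotypes=pg, parent_phenotypes=pp,
    )


# ---------------------------------------------------------------------------
# Unrelated cohorts
# ---------------------------------------------------------------------------

@dataclass
class UnrelatedSample:
    """Unrelated cohort: genotype counts, standardized genotypes,
    standardized phenotypes, environments, and the causal-marker indices."""

    genotypes: np.ndarray        # (n, m) allele counts 0/1/2
    z: np.ndarray                # (n, m) sample-standardized columns
    z_pop: np.ndarray            # (n, m) standardized by generating freqs
    y: np.ndarray                # (n,) standardized phenotype
    env: np.ndarray              # (n,)
    freqs: np.ndarray            # (m,) generating allele frequencies
    causal: np.ndarray           # indices of causal markers
    effects: np.ndarray          # per-causal additive effect a_k

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def genotype_dataframe(self) -> pd.DataFrame:
        cols = {f"m{k}": self.genotypes[:, k] for k in range(self.m)}
        return pd.DataFrame({"iid": np.arange(self.n), **cols})

    def phenotype_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"iid": np.arange(self.n), "y": self.y,
                             "env": self.env})


def standardize_columns(g: np.ndarray, mode: str = "sample") -> np.ndarray:
    """Column-standardize a genotype matrix.

    ``mode='sample'`` z-scores each column (exact mean 0, variance 1);
    ``mode='allele-freq'`` uses ``(g - 2 p_hat)/sqrt(2 p_hat q_hat)`` with
    the sample allele frequency, which is the population-genetics convention
    but has sample variance 1 only under exact HWE proportions.
    """
    g = np.asarray(g, dtype=float)
    if mode == "sample":
        mu = g.mean(axis=0)
        sd = g.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic marker cannot be standardized")
        return (g - mu) / sd
    if mode == "allele-freq":
        phat = g.mean(axis=0) / 2.0
        denom = np.sqrt(2.0 * phat * (1.0 - phat))
        if np.any(denom == 0):
            raise ValueError("monomorphic marker cannot be standardized")
        return (g - 2.0 * phat) / denom
    raise ValueError(f"unknown standardization mode {mode!r}")


def simulate_unrelated(n: int, m: int, n_causal: int,
                       target_h2_total: float,
                       gxe: GxEModel | None = None,
                       p: np.ndarray | float | None = None,
                       marker_corr: np.ndarray | None = None,
                       seed: int | np.random.Generator | None = None
                       ) -> UnrelatedSample:
    """Unrelated cohort of ``n`` individuals at ``m`` biallelic markers.

    ``n_causal`` markers (chosen at random) carry equal variance shares
    summing to ``target_h2_total``.  With ``gxe`` given, each individual
    draws an environment with the model's weights and causal effects follow
    the environment's scheme (sign flips for the crossover model).  Markers
    are independent by default; ``marker_corr`` induces LD through the
    symmetric square root of the correlation matrix on the latent gamete
    scale (approximate on the genotype scale).
    """
    if not 1 <= n_causal <= m:
        raise ValueError(f"need 1 <= n_causal <= m, got {n_causal} > {m}")
    if not 0 <= target_h2_total < 1:
        raise ValueError("target_h2_total must be in [0,1)")
    rng = _as_rng(seed)
    if p is None:
        freqs = sample_allele_frequency(rng, size=m)
    else:
        freqs = np.broadcast_to(np.asarray(p, dtype=float), (m,)).copy()
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must be in (0,1)")

    if marker_corr is None:
        g = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    else:
        C = np.asarray(marker_corr, dtype=float)
        if C.shape != (m, m):
            raise ValueError("marker_corr must be m x m")
        w, V = np.linalg.eigh(C)
        root = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
        from scipy.stats import norm
        thresh = norm.ppf(freqs)
        g = np.zeros((n, m), dtype=np.int8)
        for _ in range(2):  # two gametes
            latent = rng.standard_normal((n, m)) @ root.T
            g += (latent < thresh).astype(np.int8)

    causal = np.sort(rng.choice(m, size=n_causal, replace=False))
    a = np.sqrt(target_h2_total / n_causal /
                (2.0 * freqs[causal] * (1.0 - freqs[causal])))

    if gxe is None:
        env = np.zeros(n, dtype=np.int8)
        sign = np.ones((1, n_causal))
    else:
        env = rng.choice(gxe.n_environments, size=n, p=gxe.weights).astype(np.int8)
        # crossover convention: sign of a flips with BB value's sign
        signs = np.array([np.sign(eff["BB"]) if eff["BB"] != 0 else 1.0
                          for eff in gxe.effects])
        sign = signs[env][:, None]

    G = ((g[:, causal] - 2.0 * freqs[causal]) * a * sign).sum(axis=1)
    e = rng.normal(0.0, np.sqrt(1.0 - target_h2_total), size=n)
    # population-standardized trait: unit variance by construction (sample
    # z-scoring would pin the total pair sum of squared differences and
    # shrink the HE slope's sampling variance below its analytic value)
    y = G + e

    z = standardize_columns(g, mode="sample")
    # population standardization keeps individuals independent across
    # columns; sample centering pins each column sum and shrinks the
    # association HE slope's sampling variance below the analytic value
    z_pop = (g - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    return UnrelatedSample(genotypes=g, z=z, z_pop=z_pop, y=y, env=env,
                           freqs=freqs, causal=causal, effects=a)


# ---------------------------------------------------------------------------
# Whole-genome IBD pairs
# ---------------------------------------------------------------------------

@dataclass
class GenomeIBDPairs:
    """Sib-style pairs with genome-wide IBD sharing ``pi_tilde`` and
    phenotypes correlated ``pi_tilde * htilde2`` within pair."""

    pi_tilde: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    htilde2: float
    L: float
    n_truncated: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pi_tilde)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_id": np.arange(self.n_pairs),
            "y1": self.y1, "y2": self.y2, "pi_tilde": self.pi_tilde,
        })


def simulate_genomewide_ibd_pairs(n_pairs: int, htilde2: float,
                                  L: float = 32.0,
                                  seed: int | np.random.Generator | None = None
                                  ) -> GenomeIBDPairs:
    """Sib pairs under the whole-genome linkage design.

    Genome-wide IBD is drawn Normal(1/2, 1/(16 L)) truncated to [0,1]
    (truncation is negligible at the human autosomal length L = 32 Morgan),
    and phenotype pairs are bivariate standard normal with correlation
    ``pi_tilde * htilde2``, so the regression of squared differences on
    ``pi_tilde`` has expected slope ``-2 htilde2``.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    if not 0 <= htilde2 < 1:
        raise ValueError("htilde2 must be in [0,1)")
    if L <= 0:
        raise ValueError(f"genetic length must be positive, got {L}")
    rng = _as_rng(seed)
    pi = rng.normal(0.5, np.sqrt(1.0 / (16.0 * L)), size=n_pairs)
    n_trunc = int(np.sum((pi < 0) | (pi > 1)))
    pi = np.clip(pi, 0.0, 1.0)
    r = pi * htilde2
    u = rng.standard_normal(n_pairs)
    v = rng.standard_normal(n_pairs)
    y1 = u
    y2 = r * u + np.sqrt(1.0 - r * r) * v
    return GenomeIBDPairs(pi_tilde=pi, y1=y1, y2=y2, htilde2=htilde2, L=L,
                          n_truncated=n_trunc)
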