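"""Table formats, provenance, and the validation / power experiment runners.

All tables are tab-delimited UTF-8 with '.'-decimal and no missing values;
writers prepend commented ``#`` provenance lines (parameters, seed,
package version) and every reader tolerates them.
"""

from __future__ import annotations

import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np
import pandas as pd

from . import analytic_stats, gxe_sim, hereg_core

logger = logging.getLogger("hereg_gxe")

try:
    __version__ = _pkg_version("hereg-gxe")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    __version__ = "0+unknown"

#: declared column schemas, by table kind
SCHEMAS = {
    "sibpair": ["family_id", "env", "y1", "y2", "pi"],
    "phenotype": ["iid", "y", "env"],
    "summary": ["design", "slope", "se", "n"],
    "fit": ["design", "slope", "se", "t", "df", "n_pairs", "h2_implied"],
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a TSV with commented provenance header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# hereg-gxe {__version__}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    """Read a TSV (commented ``#`` header tolerated), validating the
    declared schema for ``kind`` when given."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if kind is not None:
        required = SCHEMAS[kind]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {', '.join(missing)} "
                f"for a {kind} table")
        for col in required:
            if col in ("design",):
                continue
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # 1-based + header line
                raise SchemaError(
                    f"{path}: non-numeric value in column {col!r} "
                    f"near line {line}")
        if kind == "summary" and (df["se"] <= 0).any():
            line = int((df["se"] <= 0).idxmax()) + 2
            raise SchemaError(f"{path}: non-positive SE near line {line}")
    return df


def write_genotype_table(sample: gxe_sim.UnrelatedSample, path,
                         provenance: dict | None = None) -> None:
    write_table(sample.genotype_dataframe(), path, provenance)


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "iid" not in df.columns or df.shape[1] < 2:
        raise SchemaError(f"{path}: genotype table needs 'iid' plus at "
                          "least one marker column")
    markers = df.drop(columns="iid")
    if not markers.isin([0, 1, 2]).all().all():
        raise SchemaError(f"{path}: genotype entries must be 0/1/2 counts")
    return df


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

def run_fig1_validation(K_grid=(200, 500), h2_grid=(0.1, 0.25, 0.5),
                        replicates: int = 200,
                        seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo validation of the single-locus linkage and GWAS t-tests
    under crossover GxE.

    For each (K, h2) scenario three samples are analysed per replicate: a
    Scheme-I cohort of K families, a Scheme-II cohort of K families, and
    their pooled concatenation (2K families).  Sib pairs are fit by HE
    regression on single-locus IBD; the families' 2 parents each are
    pooled into a GWAS sample.  The reference allele frequency is drawn
    Uniform(0.01, 0.5) per replicate and the locus itself is causal.

    Expected values: the analytic linkage t at the sample's own pair
    count for HE; ``sign * sqrt((n-2) h2/(1-h2))`` for single-scheme GWAS
    (positive for Scheme I, negative for Scheme II) and 0 for the pooled
    GWAS sample, where the crossover effects cancel.  The pass columns
    compare the SIGNED simulated mean with the signed expectation within
    3 SEM - the magnitude of a noisy t is upward-biased at small
    noncentrality, so mean |t| is reported for display only.
    """
    rows = []
    scen = 0
    for K in K_grid:
        for h2 in h2_grid:
            sims = {name: {"t_he": [], "t_gwas": []}
                    for name in ("scheme-I", "scheme-II", "pooled")}
            for rep in range(replicates):
                rng = np.random.default_rng([seed, scen, rep])
                p = float(gxe_sim.sample_allele_frequency(rng))
                samples = {
                    "scheme-I": gxe_sim.simulate_sibpairs(
                        K, 0, p=p, target_h2=h2, seed=rng,
                        include_parents=True),
                    "scheme-II": gxe_sim.simulate_sibpairs(
                        0, K, p=p, target_h2=h2, seed=rng,
                        include_parents=True),
                    "pooled": gxe_sim.simulate_sibpairs(
                        K, K, p=p, target_h2=h2, seed=rng,
                        include_parents=True),
                }
                for name, sample in samples.items():
                    fit = hereg_core.he_fit(
                        hereg_core.PairedResponse.from_sibpairs(sample))
                    sims[name]["t_he"].append(fit.t)
                    g, y, _ = sample.parents_pooled()
                    z = gxe_sim.standardize_columns(g[:, None])[:, 0]
                    sims[name]["t_gwas"].append(hereg_core.gwas_fit(y, z).t)
            for name in sims:
                n_sib = 2 * K if name == "pooled" else K
                n_gwas = 2 * n_sib
                t_he = np.array(sims[name]["t_he"])
                t_gw = np.array(sims[name]["t_gwas"])
                exp_he = analytic_stats.t_linkage_single(n_sib, h2).t
                if name == "pooled":
                    exp_gw = 0.0
                else:
                    sign = 1.0 if name == "scheme-I" else -1.0
                    exp_gw = sign * np.sqrt((n_gwas - 2) * h2 / (1 - h2))
                sem_he = t_he.std(ddof=1) / np.sqrt(replicates)
                sem_gw = t_gw.std(ddof=1) / np.sqrt(replicates)
                rows.append({
                    "K": K, "h2": h2, "scheme": name, "n_sib": n_sib,
                    "n_gwas": n_gwas,
                    "t_he_expected": exp_he,
                    "t_he_sim_mean": t_he.mean(),
                    "t_he_sim_sem": sem_he,
                    "t_he_sim_mean_abs": np.abs(t_he).mean(),
                    "pass_he": bool(abs(t_he.mean() - exp_he) <= 3 * sem_he),
                    "t_gwas_expected": exp_gw,
                    "t_gwas_sim_mean": t_gw.mean(),
                    "t_gwas_sim_sem": sem_gw,
                    "t_gwas_sim_mean_abs": np.abs(t_gw).mean(),
                    "pass_gwas": bool(abs(t_gw.mean() - exp_gw)
                                      <= 3 * sem_gw),
                })
            scen += 1
    return pd.DataFrame(rows)


def run_fig2_power(h2_grid=(0.005, 0.0075, 0.01, 0.015, 0.02),
                   alpha: float = analytic_stats.DEFAULT_ALPHA,
                   n_grid=analytic_stats.DEFAULT_N_GRID,
                   target_power: float = 0.85
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analytic power of the single-locus linkage HE test over a sample
    size grid, with the smallest-n summary per heritability.

    Returns ``(grid, summary)``; a summary ``n_required`` of -1 marks a
    heritability the grid cannot power to the target.
    """
    grid_rows = []
    summary_rows = []
    for h2 in h2_grid:
        for n in n_grid:
            ncp_val = analytic_stats.ncp(hereg_core.LINKAGE_SINGLE, n, h2)
            grid_rows.append({
                "design": hereg_core.LINKAGE_SINGLE, "h2": h2, "n": n,
                "ncp": ncp_val,
                "power": analytic_stats.power_noncentral_chisq(ncp_val,
                                                               alpha),
            })
        n_req = analytic_stats.required_sample_size(
            hereg_core.LINKAGE_SINGLE, h2, alpha=alpha,
            target_power=target_power, n_grid=n_grid)
        summary_rows.append({
            "h2": h2, "alpha": alpha, "target_power": target_power,
            "n_required": -1 if n_req is None else n_req,
        })
    return pd.DataFrame(grid_rows), pd.DataFrame(summary_rows)
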