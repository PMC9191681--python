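"""Prune-and-threshold polygenic risk scoring on synthetic genotype panels.

The pipeline mirrors standard GWAS practice: variant QC (imputation INFO,
Hardy-Weinberg, missingness, minor allele frequency), p-value thresholding
of the summary statistics, greedy LD pruning within a sliding base-pair
window, additive scoring of effect-allele counts (log-odds weights,
mean imputation of missing calls), standardization, and residualization on
the leading genotype principal components.

Summary-statistic tables are plain DataFrames with columns
``SNP, CHR, BP, A1, A2, BETA, P`` and the QC columns ``FRQ, INFO, HWE_P,
MISS``; genotypes are participants x variants DataFrames of allele counts
in {0, 1, 2} with NaN for missing (see :func:`neurosig.simulate.generate_genotypes`).
Allele harmonization against external references is out of scope: synthetic
stats are pre-harmonized by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

SUMMARY_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "P", "FRQ", "INFO", "HWE_P", "MISS")


def filter_variants(
    stats: pd.DataFrame,
    info_min: float = 0.8,
    hwe_p_min: float = 1e-10,
    miss_max: float = 0.05,
    maf_min: float = 0.001,
) -> pd.DataFrame:
    """Variant QC: INFO > 0.8, HWE p > 1e-10, missingness < 5%, MAF > 0.1%.

    All comparisons are strict, so a variant exactly at a boundary is
    excluded.  Removal counts per criterion are attached as
    ``result.attrs["removed"]``.
    """
    maf = np.minimum(stats["FRQ"], 1.0 - stats["FRQ"])
    rules = {
        "info": stats["INFO"] > info_min,
        "hwe": stats["HWE_P"] > hwe_p_min,
        "missingness": stats["MISS"] < miss_max,
        "maf": maf > maf_min,
    }
    keep = np.logical_and.reduce(list(rules.values()))
    out = stats.loc[keep].copy()
    out.attrs["removed"] = {name: int((~ok).sum()) for name, ok in rules.items()}
    return out


def _genotype_r2(G: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of mean-imputed allele counts."""
    G = G.copy()
    mu = np.nanmean(G, axis=0)
    nan = np.isnan(G)
    G[nan] = np.take(mu, np.where(nan)[1])
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(G.T)
    return np.nan_to_num(r) ** 2


def threshold_and_prune(
    stats: pd.DataFrame,
    genotypes: pd.DataFrame,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.5,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """P < 0.05 thresholding followed by frequency-informed LD pruning.

    After dropping variants with p >= ``p_threshold``, variants are pruned
    greedily in order of ascending p (ties broken toward the higher minor
    allele frequency — the frequency-informed rule — then by position): a
    variant is kept only if no already-kept variant on the same chromosome
    within ``window_bp`` has in-sample genotype r^2 >= ``r2_threshold``.
    Best-p-first ordering realizes "remove the higher-p member of a
    violating pair" globally and guarantees that no surviving pair within
    the window violates the r^2 bound.
    """
    sig = stats.loc[stats["P"] < p_threshold].copy()
    if sig.empty:
        return sig
    missing = [v for v in sig["SNP"] if v not in genotypes.columns]
    if missing:
        raise KeyError(f"variants absent from genotype matrix: {missing[:5]}")
    if not sig["BP"].is_monotonic_increasing:
        sig = sig.sort_values(["CHR", "BP"], kind="stable")

    maf = np.minimum(sig["FRQ"].to_numpy(float), 1.0 - sig["FRQ"].to_numpy(float))
    order = np.lexsort((sig["BP"].to_numpy(), -maf, sig["P"].to_numpy(float)))
    G = genotypes.loc[:, sig["SNP"]].to_numpy(float)
    r2 = _genotype_r2(G)
    chrom = sig["CHR"].to_numpy()
    bp = sig["BP"].to_numpy(float)

    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if chrom[j] == chrom[i] and abs(bp[j] - bp[i]) <= window_bp:
                if r2[i, j] >= r2_threshold:
                    ok = False
                    break
        if ok:
            kept.append(int(i))
    out = sig.iloc[sorted(kept)].copy()
    out.attrs["pruning"] = {
        "p_threshold": p_threshold,
        "r2_threshold": r2_threshold,
        "window_bp": window_bp,
        "rule": "best-p-first greedy; ties keep higher MAF (frequency-informed)",
        "n_input": int(len(stats)),
        "n_after_threshold": int(len(sig)),
        "n_kept": int(len(out)),
    }
    return out


def score_prs(stats: pd.DataFrame, genotypes: pd.DataFrame) -> pd.Series:
    """Additive PRS: sum of weight x effect-allele count over the variant set.

    Missing genotype calls are replaced by the variant's sample mean count
    before scoring.
    """
    missing = [v for v in stats["SNP"] if v not in genotypes.columns]
    if missing:
        raise KeyError(f"variants absent from genotype matrix: {missing[:5]}")
    G = genotypes.loc[:, stats["SNP"]].to_numpy(float)
    mu = np.nanmean(G, axis=0)
    nan = np.isnan(G)
    if nan.any():
        G = G.copy()
        G[nan] = np.take(mu, np.where(nan)[1])
    w = stats["BETA"].to_numpy(float)
    return pd.Series(G @ w, index=genotypes.index, name="PRS_raw")


def genotype_pcs(genotypes: pd.DataFrame, n_components: int = 10) -> pd.DataFrame:
    """Leading principal components of the standardized genotype matrix."""
    G = genotypes.to_numpy(float)
    mu = np.nanmean(G, axis=0)
    nan = np.isnan(G)
    if nan.any():
        G = G.copy()
        G[nan] = np.take(mu, np.where(nan)[1])
    sd = G.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    pcs = PCA(n_components=min(n_components, Z.shape[1], Z.shape[0] - 1)).fit_transform(Z)
    return pd.DataFrame(
        pcs, index=genotypes.index, columns=[f"PC{k + 1}" for k in range(pcs.shape[1])]
    )


def standardize_and_deconfound(
    raw_scores: pd.Series, pcs: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Z-score the raw PRS, then regress out the genotype PCs.

    Returns ``(standardized, pc_residual)``; the residuals are orthogonal
    to every PC column.  Standardization is over the provided (reference)
    sample: mean 0, SD 1.
    """
    raw = np.asarray(raw_scores, float)
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("raw PRS is constant; cannot standardize")
    z = (raw - raw.mean()) / sd
    C = np.column_stack([np.ones(len(z)), np.asarray(pcs, float)])
    coef, *_ = np.linalg.lstsq(C, z, rcond=None)
    resid = z - C @ coef
    idx = raw_scores.index if isinstance(raw_scores, pd.Series) else None
    return (
        pd.Series(z, index=idx, name="PRS_standardized"),
        pd.Series(resid, index=idx, name="PRS_pc_residual"),
    )
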