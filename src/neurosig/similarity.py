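"""Cross-disorder similarity of case-control neural signatures.

A disorder's signature is its vector of per-feature case-vs-control
t statistics from the mass-univariate GLMs.  Similarity between two
disorders is the Pearson correlation of their signatures over a common
feature panel (connectivity and thickness are never mixed in one call).

Significance comes from a refit permutation null: each iteration applies
one row permutation to the outcome panel, refits the identical GLM (same
design, same covariates), recomputes every contrast's t vector, and
collects the pairwise correlations.  Using a single shared permutation per
iteration across all contrasts preserves the dependence induced by the
shared control group, and row-wise shuffling preserves inter-feature
correlation under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neurosig.glm import fit_feature_glm, _perm_pvalue


@dataclass
class SimilarityMatrix:
    """Pairwise signature correlations, optionally with permutation p-values."""

    r: pd.DataFrame
    p_perm: pd.DataFrame | None = None
    modality: str | None = None
    n_features: int = 0
    null_r: np.ndarray | None = None  # (n_perm, n_pairs) upper-triangle order

    @property
    def contrasts(self) -> list:
        return list(self.r.index)

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        if self.p_perm is None:
            raise ValueError("no permutation p-values attached")
        return self.p_perm < alpha


def signature_similarity(
    signatures: pd.DataFrame | dict, modality: str | None = None
) -> SimilarityMatrix:
    """Pearson correlations between signature vectors.

    ``signatures`` is a contrasts x features DataFrame (as returned by
    :meth:`CaseControlGLM.signatures`) or a ``{name: vector}`` mapping of
    equal-length vectors in the same feature order.
    """
    if isinstance(signatures, dict):
        lengths = {k: len(np.asarray(v)) for k, v in signatures.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"signature length mismatch: {lengths}")
        signatures = pd.DataFrame({k: np.asarray(v, float) for k, v in signatures.items()}).T
    mat = signatures.to_numpy(float)
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        bad = signatures.index[np.where(sds == 0)[0][0]]
        raise ValueError(f"signature {bad!r} has zero variance")
    r = np.corrcoef(mat)
    r = pd.DataFrame(r, index=signatures.index, columns=signatures.index)
    return SimilarityMatrix(r=r, modality=modality, n_features=mat.shape[1])


def _pairwise_r(t_matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise correlations of rows (k x m -> k*(k-1)/2)."""
    r = np.corrcoef(t_matrix)
    iu = np.triu_indices(r.shape[0], 1)
    return r[iu]


def permutation_null_similarity(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    panel: str = "connectivity",
    with_prs: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    two_sided: bool = True,
    reference: str = "CTRL",
) -> SimilarityMatrix:
    """Signature similarity with a refit permutation null.

    Per iteration: one shared row permutation of the feature panel, a refit
    of the identical GLM specification, pairwise correlations of the
    refitted t vectors.  p per pair is (1 + #{|r_null| >= |r_obs|}) /
    (1 + n_perm) when ``two_sided`` (default; one-sided on signed r
    otherwise).  Correlations at p < 0.01 are conventionally reported as
    significant.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    fit = fit_feature_glm(cohort, features, panel=panel, with_prs=with_prs,
                          reference=reference)
    contrasts = fit.case_groups_
    if len(contrasts) < 2:
        raise ValueError("need at least two case groups for a similarity matrix")
    obs_t = fit.signatures().to_numpy()
    r_obs_flat = _pairwise_r(obs_t)

    # Refit machinery: the permuted fits reuse the observed design exactly.
    X, Y = fit._X, fit._Y
    from scipy.linalg import solve_triangular

    n, p = X.shape
    Q, R = np.linalg.qr(X)
    Rinv = solve_triangular(R, np.eye(p))
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    grp_idx = np.array([fit.group_columns_[g] for g in contrasts])
    df = fit.df_

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(r_obs_flat)))
    for b in range(n_perm):
        Yp = Y[rng.permutation(n)]
        beta = solve_triangular(R, Q.T @ Yp)
        resid = Yp - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        t = beta[grp_idx] / np.sqrt(np.outer(xtx_inv_diag[grp_idx], sigma2))
        null[b] = _pairwise_r(t)

    if two_sided:
        p_flat = _perm_pvalue(np.abs(r_obs_flat), np.abs(null))
    else:
        p_flat = _perm_pvalue(r_obs_flat, null)

    k = len(contrasts)
    r_mat = np.eye(k)
    p_mat = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    r_mat[iu] = r_obs_flat
    r_mat.T[iu] = r_obs_flat
    p_mat[iu] = p_flat
    p_mat.T[iu] = p_flat
    np.fill_diagonal(p_mat, 0.0)
    return SimilarityMatrix(
        r=pd.DataFrame(r_mat, index=contrasts, columns=contrasts),
        p_perm=pd.DataFrame(p_mat, index=contrasts, columns=contrasts),
        modality=panel,
        n_features=Y.shape[1],
        null_r=null,
    )


def compare_similarity_settings(
    matrices: dict[str, SimilarityMatrix],
) -> dict[str, pd.DataFrame]:
    """Elementwise deltas of similarity matrices across analysis settings.

    Given named matrices (e.g. full sample, ancestry subset, PRS-covaried),
    returns ``{"<name> - <first>": r_name - r_first}`` for every setting
    after the first.  All matrices must share contrasts and modality.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two settings to compare")
    names = list(matrices)
    base_name = names[0]
    base = matrices[base_name]
    deltas = {}
    for name in names[1:]:
        other = matrices[name]
        if list(other.r.index) != list(base.r.index):
            raise ValueError(
                f"contrast mismatch between {base_name!r} and {name!r}"
            )
        if other.modality != base.modality:
            raise ValueError("cannot compare similarity matrices across modalities")
        deltas[f"{name} - {base_name}"] = other.r - base.r
    return deltas
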