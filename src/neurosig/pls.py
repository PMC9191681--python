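"""PLS regression linking confound-residualized connectivity to cognition.

The analysis sample is confound-cleaned first: age, sex, and site are
regressed out of both the imaging and the cognitive variables (head motion
additionally out of the imaging side), and the z-scored residuals form the
predictor matrix X (participants x 210) and outcome matrix Y
(participants x 4).

PLS2 regression (NIPALS) then extracts components whose X and Y scores
have maximal covariance.  Three layers of inference sit on top:

* **permutation** of the rows of Y against the total percentage of Y
  variance explained by the retained components;
* **bootstrap-ratio feature selection** (default n = 5,000 resamples):
  each predictor's full-sample component weight divided by its bootstrap
  standard deviation, thresholded at |Z| > 3;
* **hold-out robustness**: a 4-fold split, training on 75% and correlating
  predicted with observed cognition in the held-out 25%; residualization
  parameters are estimated on the training fold only (leakage-free
  default; a literal whole-sample mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from neurosig.glm import PermutationResult, _perm_pvalue

__all__ = [
    "BootstrapWeights",
    "BrainCognitionPLS",
    "ConfoundResidualizer",
    "HoldoutResult",
    "bootstrap_weights",
    "holdout_evaluate",
    "permute_pls_variance",
    "pls_fit",
    "residualize_confounds",
]


def _confound_design(cohort: pd.DataFrame, confounds: list[str]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for c in confounds:
        if c not in cohort.columns:
            raise ValueError(f"confound {c!r} not in cohort")
        col = cohort[c]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(pd.unique(col))
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


class ConfoundResidualizer(TransformerMixin, BaseEstimator):
    """OLS confound removal followed by z-scoring.

    ``fit(X, C)`` learns, per column of X, the least-squares projection on
    the confound design C (with intercept; categorical confounds are
    expanded to indicators) together with the mean and SD of the training
    residuals; ``transform`` returns z-scored residuals using the learned
    parameters, so test data can be cleaned without leakage.
    """

    def __init__(self, min_residual_sd: float = 1e-10):
        self.min_residual_sd = min_residual_sd

    def fit(self, X, confounds) -> "ConfoundResidualizer":
        X = np.asarray(X, float)
        C = np.asarray(confounds, float)
        if X.shape[0] != C.shape[0]:
            raise ValueError("X and confounds have different numbers of rows")
        if X.shape[0] <= C.shape[1]:
            raise ValueError("fewer rows than confound columns")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        self.coef_, *_ = np.linalg.lstsq(C, X, rcond=None)
        resid = X - C @ self.coef_
        self.mean_ = resid.mean(axis=0)
        self.scale_ = resid.std(axis=0, ddof=1)
        if np.any(self.scale_ <= self.min_residual_sd):
            j = int(np.argmin(self.scale_))
            raise ValueError(
                f"column {j} has ~zero residual variance after confound removal"
            )
        return self

    def transform(self, X, confounds) -> np.ndarray:
        X = np.asarray(X, float)
        C = np.asarray(confounds, float)
        resid = X - C @ self.coef_
        return (resid - self.mean_) / self.scale_


def residualize_confounds(
    data: pd.DataFrame,
    cohort: pd.DataFrame,
    confounds: list[str] = ("age", "sex", "site"),
) -> pd.DataFrame:
    """Regress the named cohort covariates out of each column and z-score.

    Residuals are orthogonal to the confound columns; output columns have
    mean 0 and SD 1 over the sample.  Include ``"motion"`` in ``confounds``
    for fMRI-derived panels.
    """
    C = _confound_design(cohort, list(confounds))
    res = ConfoundResidualizer().fit(np.asarray(data, float), C)
    out = res.transform(np.asarray(data, float), C)
    if isinstance(data, pd.DataFrame):
        return pd.DataFrame(out, index=data.index, columns=data.columns)
    return out


class BrainCognitionPLS(BaseEstimator):
    """PLS2 regression (NIPALS) of a cognition panel on a brain panel.

    Attributes after :meth:`fit` (n = rows, p = predictors, q = outcomes,
    c = components):

    x_weights_ : (p, c) component weight vectors (unit norm)
    x_scores_ : (n, c) predictor scores (XS); mutually orthogonal
    x_loadings_, y_loadings_ : (p, c), (q, c)
    coef_ : (p, q) regression coefficients mapping X to predicted Y
    pct_var_y_ : (c,) percentage of total Y variance explained by each
        component (marginal gain of the cumulative reconstruction)
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, Y) -> "BrainCognitionPLS":
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("NaN in PLS input")
        if self.n_components > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"n_components = {self.n_components} exceeds the rank bound "
                f"min(n - 1, p) = {min(X.shape[0] - 1, X.shape[1])}"
            )
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(X, Y)
        self._pls = pls
        self.x_weights_ = pls.x_weights_
        self.x_scores_ = pls.x_scores_
        self.x_loadings_ = pls.x_loadings_
        self.y_loadings_ = pls.y_loadings_
        self.coef_ = pls.coef_.T  # (p, q)

        # Variance of Y explained: cumulative reconstruction from scores
        # and loadings, reported as the marginal gain per component.
        Yc = Y - Y.mean(axis=0)
        sst = (Yc**2).sum()
        sse_prev = sst
        gains = []
        for c in range(1, self.n_components + 1):
            Yhat = self.x_scores_[:, :c] @ self.y_loadings_[:, :c].T
            sse = ((Yc - Yhat) ** 2).sum()
            gains.append(100.0 * (sse_prev - sse) / sst)
            sse_prev = sse
        self.pct_var_y_ = np.array(gains)
        return self

    def predict(self, X) -> np.ndarray:
        return self._pls.predict(np.asarray(X, float))

    def transform(self, X) -> np.ndarray:
        """Predictor scores (XS) for new data."""
        return self._pls.transform(np.asarray(X, float))

    @property
    def total_pct_var_y_(self) -> float:
        return float(self.pct_var_y_.sum())


def pls_fit(X, Y, n_components: int = 3) -> BrainCognitionPLS:
    """Fit the brain-cognition PLS (thin estimator wrapper)."""
    return BrainCognitionPLS(n_components=n_components).fit(X, Y)


def permute_pls_variance(
    X, Y, n_components: int = 3, n_perm: int = 1000, seed: int = 0,
    permute: str = "Y",
) -> PermutationResult:
    """Permutation test of the total % Y variance explained.

    The rows of Y (default; X selectable) are permuted, the PLS refit, and
    the summed per-component variance explained compared with the observed
    value; p = (1 + b) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if permute not in ("Y", "X"):
        raise ValueError("permute must be 'Y' or 'X'")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    obs = pls_fit(X, Y, n_components).total_pct_var_y_
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(Y))
        if permute == "Y":
            null[b] = pls_fit(X, Y[perm], n_components).total_pct_var_y_
        else:
            null[b] = pls_fit(X[perm], Y, n_components).total_pct_var_y_
    null = null[:, None]
    p = float(_perm_pvalue(obs, null)[0])
    return PermutationResult(obs, null.ravel(), p, n_perm)


@dataclass
class BootstrapWeights:
    """Bootstrap-ratio Z per predictor and component (weight / bootstrap SD)."""

    z: pd.DataFrame                  # predictors x components
    weights: pd.DataFrame            # full-sample weights
    boot_sd: pd.DataFrame
    n_boot: int
    threshold: float = 3.0
    n_redrawn: int = 0

    def selected(self, component: int = 0) -> pd.Series:
        """|Z| > threshold mask for one component (0-based)."""
        return self.z.iloc[:, component].abs() > self.threshold


def _align_components(ref_w: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Match replicate components to the reference by maximal |correlation|.

    PLS components have sign indeterminacy and can swap order across
    resamples; greedy matching on the |correlation| of weight vectors picks
    for each reference component its best replicate partner and flips the
    sign when the correlation is negative.
    """
    c = ref_w.shape[1]
    corr = np.corrcoef(ref_w.T, w.T)[:c, c:]
    aligned = np.empty_like(ref_w)
    taken: set[int] = set()
    for i in np.argsort(-np.max(np.abs(corr), axis=1)):
        order = np.argsort(-np.abs(corr[i]))
        j = next(int(jj) for jj in order if int(jj) not in taken)
        taken.add(j)
        aligned[:, i] = w[:, j] * np.sign(corr[i, j] if corr[i, j] != 0 else 1.0)
    return aligned


def bootstrap_weights(
    X, Y, n_components: int = 3, n_boot: int = 5000, seed: int = 0,
    threshold: float = 3.0, stratify: np.ndarray | None = None,
    feature_ids: list | None = None,
) -> BootstrapWeights:
    """Bootstrap-ratio selection of robust PLS predictors.

    Rows are resampled with replacement (optionally within strata, e.g.
    diagnosis), the PLS refit, replicate components sign/order-aligned to
    the full-sample solution, and Z computed as full-sample weight over the
    bootstrap SD of the aligned weights.  |Z| > 3 flags robust predictors.
    Resamples that leave a constant column are redrawn (count reported).
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = len(X)
    ref = pls_fit(X, Y, n_components)
    rng = np.random.default_rng(seed)
    if stratify is not None:
        stratify = np.asarray(stratify)
        strata = [np.where(stratify == s)[0] for s in np.unique(stratify)]

    boots = np.empty((n_boot, X.shape[1], n_components))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        if stratify is None:
            idx = rng.integers(n, size=n)
        else:
            idx = np.concatenate([s[rng.integers(len(s), size=len(s))] for s in strata])
        Xb, Yb = X[idx], Y[idx]
        if np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0):
            n_redrawn += 1
            continue
        boots[b] = _align_components(ref.x_weights_, pls_fit(Xb, Yb, n_components).x_weights_)
        b += 1

    sd = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, ref.x_weights_ / sd, np.nan)
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    comp_ids = [f"PLS{c + 1}" for c in range(n_components)]
    return BootstrapWeights(
        z=pd.DataFrame(z, index=feature_ids, columns=comp_ids),
        weights=pd.DataFrame(ref.x_weights_, index=feature_ids, columns=comp_ids),
        boot_sd=pd.DataFrame(sd, index=feature_ids, columns=comp_ids),
        n_boot=n_boot,
        threshold=threshold,
        n_redrawn=n_redrawn,
    )


@dataclass
class HoldoutResult:
    """Per-fold out-of-sample performance of the PLS model."""

    fold_assignments: pd.Series        # participant/row -> fold id
    r_pred_obs: pd.DataFrame           # folds x outcomes
    train_sizes: list[int]
    test_sizes: list[int]

    def mean_r(self) -> pd.Series:
        return self.r_pred_obs.mean(axis=0)


def holdout_evaluate(
    X, Y, n_components: int = 3, n_folds: int = 4, seed: int = 0,
    cohort: pd.DataFrame | None = None,
    confounds: list[str] | None = None,
    leakage_free: bool = True,
    outcome_ids: list | None = None,
) -> HoldoutResult:
    """K-fold hold-out robustness of the brain-cognition PLS.

    The sample is split into ``n_folds`` folds (default 4: train on 75%,
    test on 25%); per fold, the PLS regression coefficients fitted on the
    training folds predict the held-out cognition, and the per-outcome
    Pearson r between predicted and observed is reported.

    When ``cohort``/``confounds`` are given, X and Y are raw panels and
    residualization is performed inside the loop — fitted on the training
    fold only when ``leakage_free`` (default), or on the whole sample when
    not (the literal single-pass variant).
    """
    Xa = np.asarray(X, float)
    Ya = np.asarray(Y, float)
    n = len(Xa)
    if n < n_folds:
        raise ValueError("fewer rows than folds")
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    if outcome_ids is None:
        outcome_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else list(range(Ya.shape[1]))

    C = None
    if confounds is not None:
        if cohort is None:
            raise ValueError("confound residualization requires the cohort table")
        C = _confound_design(cohort, list(confounds))
        Cx = _confound_design(cohort, list(confounds) + (["motion"] if "motion" in cohort.columns and "motion" not in confounds else []))
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assign = pd.Series(index=index, dtype=int, name="fold")
    rows = []
    train_sizes, test_sizes = [], []
    for k, (tr, te) in enumerate(folds.split(Xa)):
        if len(te) < 2:
            raise ValueError("fold smaller than 2 rows")
        assign.iloc[te] = k
        if C is None:
            Xtr, Xte, Ytr, Yte = Xa[tr], Xa[te], Ya[tr], Ya[te]
        elif leakage_free:
            rx = ConfoundResidualizer().fit(Xa[tr], Cx[tr])
            ry = ConfoundResidualizer().fit(Ya[tr], C[tr])
            Xtr, Xte = rx.transform(Xa[tr], Cx[tr]), rx.transform(Xa[te], Cx[te])
            Ytr, Yte = ry.transform(Ya[tr], C[tr]), ry.transform(Ya[te], C[te])
        else:
            rx = ConfoundResidualizer().fit(Xa, Cx)
            ry = ConfoundResidualizer().fit(Ya, C)
            Xr, Yr = rx.transform(Xa, Cx), ry.transform(Ya, C)
            Xtr, Xte, Ytr, Yte = Xr[tr], Xr[te], Yr[tr], Yr[te]
        model = pls_fit(Xtr, Ytr, n_components)
        pred = model.predict(Xte)
        r = [float(np.corrcoef(pred[:, j], Yte[:, j])[0, 1]) for j in range(Ya.shape[1])]
        rows.append(r)
        train_sizes.append(len(tr))
        test_sizes.append(len(te))
    return HoldoutResult(
        fold_assignments=assign,
        r_pred_obs=pd.DataFrame(rows, columns=outcome_ids,
                                index=[f"fold{k + 1}" for k in range(n_folds)]),
        train_sizes=train_sizes,
        test_sizes=test_sizes,
    )
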