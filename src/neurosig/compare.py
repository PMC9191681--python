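"""Direct comparison of brain-cognition associations between two groups.

Cognition is reduced to its first principal component (PC1 of the z-scored
test battery), each connectivity feature is correlated with the PC1 score
within each group, and the two correlations are compared with the Fisher
r-to-z statistic

    Z_observed = (atanh(r1) - atanh(r2)) / sqrt(1/(n1 - 3) + 1/(n2 - 3)),

flagged at |Z| > 1.96 (uncorrected p < 0.05, as conventionally reported
for this scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


@dataclass
class PCASummary:
    pc1_scores: pd.Series
    pc1_loadings: pd.Series      # unit norm
    pct_var: float               # fraction of cognition variance on PC1


class CognitionPCA(TransformerMixin, BaseEstimator):
    """First principal component of a (z-scored) cognition battery.

    The loading vector has unit norm; its sign is fixed so that the test
    with the largest |loading| loads positively — a declared convention,
    since downstream correlation signs depend on it.  Fit the loadings on a
    pooled sample and transform each group for comparable scores.
    """

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y=None) -> "CognitionPCA":
        X = np.asarray(X, float)
        if X.shape[0] < 3 or X.shape[1] < 2:
            raise ValueError("need >= 3 participants and >= 2 tests")
        if np.isnan(X).any():
            raise ValueError("missing values in cognition matrix")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"test column {int(np.argmin(sd))} has zero variance")
        self.mean_ = X.mean(axis=0)
        self.scale_ = sd
        Z = (X - self.mean_) / self.scale_
        pca = PCA(n_components=self.n_components)
        pca.fit(Z)
        comps = pca.components_.copy()
        for c in range(comps.shape[0]):
            if comps[c, np.argmax(np.abs(comps[c]))] < 0:
                comps[c] = -comps[c]
        self.components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        return Z @ self.components_.T


def pca_first_component(cognition: pd.DataFrame) -> PCASummary:
    """PC1 scores, unit-norm loadings, and captured variance fraction."""
    pca = CognitionPCA(n_components=1).fit(cognition)
    scores = pca.transform(cognition)[:, 0]
    index = cognition.index if isinstance(cognition, pd.DataFrame) else None
    cols = (
        list(cognition.columns)
        if isinstance(cognition, pd.DataFrame)
        else list(range(np.asarray(cognition).shape[1]))
    )
    return PCASummary(
        pc1_scores=pd.Series(scores, index=index, name="PC1"),
        pc1_loadings=pd.Series(pca.components_[0], index=cols, name="loading"),
        pct_var=float(pca.explained_variance_ratio_[0]),
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Fisher r-to-z test of a correlation difference between two groups.

    Antisymmetric under swapping the groups; requires n > 3 and |r| < 1.
    """
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"group size {n} <= 3: z transform undefined")
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| = {abs(r)} >= 1")
    return float(
        (np.arctanh(r1) - np.arctanh(r2))
        / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    )


def groupwise_correlation_scan(
    features: pd.DataFrame,
    pc1_scores: pd.Series,
    groups: pd.Series,
    group_pair: tuple[str, str],
    z_crit: float = 1.96,
) -> pd.DataFrame:
    """Per-feature correlation with cognition PC1 in each group, and Z.

    Returns a DataFrame with columns ``r_<g1>``, ``r_<g2>``, ``z_observed``
    and ``significant`` (|Z| > 1.96, uncorrected).
    """
    g1, g2 = group_pair
    rows = {}
    ns = {}
    for g in group_pair:
        idx = groups[groups == g].index.intersection(pc1_scores.dropna().index)
        if len(idx) < 4:
            raise ValueError(f"group {g!r} has fewer than 4 usable members")
        F = features.loc[idx].to_numpy(float)
        y = pc1_scores.loc[idx].to_numpy(float)
        Fc = F - F.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((Fc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[g] = (Fc.T @ yc) / denom
        ns[g] = len(idx)
    z = np.array(
        [
            fisher_z_compare(r_a, ns[g1], r_b, ns[g2])
            for r_a, r_b in zip(rows[g1], rows[g2])
        ]
    )
    return pd.DataFrame(
        {
            f"r_{g1}": rows[g1],
            f"r_{g2}": rows[g2],
            "z_observed": z,
            "significant": np.abs(z) > z_crit,
        },
        index=features.columns,
    )
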