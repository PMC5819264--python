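"""PCA reduction of the mutant Z matrix with CCR-based component selection.

The principal components are fitted on the mutants only (centered on the
mutant mean, no column re-scaling: Z is already variance-calibrated by the
wild-type nulls); wild-type replicates are projected onto the mutant axes
afterwards.  Components are retained up to a target cumulative contribution
ratio (CCR), the running sum of per-PC variance fractions.  Loading signs
are fixed deterministically (largest-magnitude element positive) so score
files are reproducible; all downstream distances are sign-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .errors import ValidationError


@dataclass
class PCEmbedding:
    """A fitted PCA embedding of the mutant Z matrix."""

    loadings: pd.DataFrame        # traits × PCs, orthonormal columns
    contribution: np.ndarray      # per-PC variance fraction, descending
    ccr: np.ndarray               # cumulative contribution ratio
    mutant_scores: pd.DataFrame   # mutants × PCs
    center: pd.Series             # per-trait mutant mean used for centering
    retained: int                 # PCs kept at the fitting CCR target
    wt_scores: pd.DataFrame | None = None

    @property
    def pc_names(self) -> pd.Index:
        return self.loadings.columns


def select_pcs(contribution, ccr_target: float) -> int:
    """Smallest k whose cumulative contribution reaches ``ccr_target``.

    The comparison is ≥ (a CCR exactly on the target retains that PC).
    ``ccr_target=1`` retains all PCs with nonzero contribution.
    """
    if not 0.0 < ccr_target <= 1.0:
        raise ValidationError("ccr_target must be in (0, 1]")
    c = np.asarray(getattr(contribution, "contribution", contribution),
                   float)
    if ccr_target == 1.0:
        return int(np.count_nonzero(c))
    ccr = np.cumsum(c)
    k = int(np.searchsorted(ccr, ccr_target - 1e-12) + 1)
    return min(k, c.size)


def fit_pca(z_mutants: pd.DataFrame, ccr_target: float = 0.8) -> PCEmbedding:
    """Full-rank PCA of the mutant Z matrix.

    Components are ordered by decreasing variance; zero-variance components
    carry contribution 0.  Deterministic up to the fixed sign convention.
    """
    if z_mutants.shape[0] < 2 or z_mutants.shape[1] < 2:
        raise ValidationError("PCA needs ≥2 mutants and ≥2 traits")
    if z_mutants.isna().any().any():
        raise ValidationError("PCA input contains missing values")
    pca = PCA(n_components=min(z_mutants.shape), svd_solver="full")
    scores = pca.fit_transform(z_mutants.to_numpy(float))
    loadings = pca.components_.T  # traits × PCs
    # sign convention: largest-|loading| element of each PC is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    pc_names = pd.Index([f"PC{i + 1}" for i in range(loadings.shape[1])])
    contribution = pca.explained_variance_ratio_
    emb = PCEmbedding(
        loadings=pd.DataFrame(loadings, index=z_mutants.columns,
                              columns=pc_names),
        contribution=contribution,
        ccr=np.cumsum(contribution),
        mutant_scores=pd.DataFrame(scores, index=z_mutants.index,
                                   columns=pc_names),
        center=pd.Series(pca.mean_, index=z_mutants.columns),
        retained=select_pcs(contribution, ccr_target),
    )
    return emb


def project(embedding: PCEmbedding, z: pd.DataFrame) -> pd.DataFrame:
    """Project rows of ``z`` (same traits as the fit) onto the PC axes."""
    missing = embedding.loadings.index.difference(z.columns)
    if len(missing):
        raise ValidationError(f"projection input lacks trait(s): "
                              f"{missing.tolist()[:5]}")
    z = z[embedding.loadings.index]
    centered = z.to_numpy(float) - embedding.center.to_numpy()
    return pd.DataFrame(centered @ embedding.loadings.to_numpy(),
                        index=z.index, columns=embedding.pc_names)


def project_wt(embedding: PCEmbedding, z_wt: pd.DataFrame) -> PCEmbedding:
    """Attach projected wild-type scores to the embedding (returns it)."""
    embedding.wt_scores = project(embedding, z_wt)
    return embedding


class CCRPCA(TransformerMixin, BaseEstimator):
    """PCA with CCR-based retention, as a scikit-learn transformer.

    fit(X) runs a full PCA of the (DataFrame) Z matrix; transform(X)
    projects onto the retained components only.

    Parameters
    ----------
    ccr_target : float
        Cumulative contribution ratio at which components are retained
        (0.8 for holistic-distance work, 0.99 for similarity profiles).

    Attributes
    ----------
    embedding_ : PCEmbedding
    n_retained_ : int
    """

    def __init__(self, ccr_target: float = 0.8):
        self.ccr_target = ccr_target

    def fit(self, X: pd.DataFrame, y=None):
        self.embedding_ = fit_pca(X, ccr_target=self.ccr_target)
        self.n_retained_ = self.embedding_.retained
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scores = project(self.embedding_, X)
        return scores.iloc[:, : self.n_retained_]
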