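"""Holistic morphological abnormality: distance statistic and gamma null.

A mutant's holistic abnormality is its Euclidean distance from the
wild-type mean over the retained principal components, after each PC score
is standardized by the wild-type replicates' mean and standard deviation
(MLE divisor n).  The null distribution of the distance is calibrated by a
two-parameter gamma fit to the wild-type replicate distances; mutants are
called holistic when the Storey q-value of their upper-tail p-value falls
at or below the FDR target (abnormality is one-directional, so only the
upper tail is tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .embedding import PCEmbedding, fit_pca, project
from .errors import FitError, ValidationError
from .trait_stats import qvalues

logger = logging.getLogger(__name__)


@dataclass
class GammaNull:
    """Gamma null of wild-type distances (shape/rate parameterization)."""

    shape: float
    rate: float
    n_fit: int

    def sf(self, d):
        return stats.gamma.sf(d, self.shape, scale=1.0 / self.rate)

    def cdf(self, d):
        return stats.gamma.cdf(d, self.shape, scale=1.0 / self.rate)


def standardize_scores(embedding: PCEmbedding, retained: int | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize mutant and wild-type PC scores by the wild type.

    Each retained PC is centered on the wild-type mean and divided by the
    wild-type sd (divisor n); the wild-type mean vector is 0 afterwards.
    """
    if embedding.wt_scores is None:
        raise ValidationError("embedding has no projected wild-type scores")
    retained = embedding.retained if retained is None else retained
    if retained < 1:
        raise ValidationError("need at least one retained PC")
    cols = embedding.pc_names[:retained]
    wt = embedding.wt_scores[cols]
    mu = wt.mean(axis=0)
    sd = wt.std(axis=0, ddof=0)
    dead = sd.index[sd == 0.0]
    if len(dead):
        raise ValidationError(f"wild-type variance is zero on retained "
                              f"PC(s): {dead.tolist()}")
    return ((embedding.mutant_scores[cols] - mu) / sd, (wt - mu) / sd)


def euclidean_distance(standardized_scores: pd.DataFrame,
                       retained: int | None = None) -> pd.Series:
    """Per-strain Euclidean distance from the (zero) wild-type mean."""
    s = standardized_scores
    if retained is not None:
        s = s.iloc[:, :retained]
    return np.sqrt((s ** 2).sum(axis=1)).rename("distance")


def wt_loo_distances(embedding: PCEmbedding,
                     retained: int | None = None) -> pd.Series:
    """Jackknifed wild-type distances (leave-one-out standardization).

    Each replicate is standardized against the mean and sd (divisor n) of
    the other replicates, so its distance estimates that of an independent
    no-effect strain.  Standardizing a replicate against moments that
    include itself shrinks its own distance and biases the fitted null —
    and hence the mutant calls — anti-conservatively.
    """
    if embedding.wt_scores is None:
        raise ValidationError("embedding has no projected wild-type scores")
    retained = embedding.retained if retained is None else retained
    s = embedding.wt_scores.iloc[:, :retained].to_numpy(float)
    n = s.shape[0]
    if n < 3:
        raise ValidationError("leave-one-out needs ≥3 wild-type replicates")
    tot = s.sum(axis=0)
    tot2 = (s ** 2).sum(axis=0)
    mu = (tot - s) / (n - 1)                      # per-row LOO mean
    var = (tot2 - s ** 2) / (n - 1) - mu ** 2     # LOO variance, divisor n-1 count
    if np.any(var <= 0):
        raise ValidationError("zero leave-one-out wild-type variance on a "
                              "retained PC")
    d = np.sqrt((((s - mu) ** 2) / var).sum(axis=1))
    return pd.Series(d, index=embedding.wt_scores.index, name="distance")


def fit_gamma_null(wt_distances, min_n: int = 10) -> GammaNull:
    """Two-parameter gamma MLE of the wild-type distance distribution.

    Replicates at exactly zero distance (a wild type equal to the wild-type
    mean) are excluded with a warning rather than jittered.
    """
    d = np.asarray(wt_distances, float)
    d = d[np.isfinite(d)]
    n_zero = int((d <= 0.0).sum())
    if n_zero:
        logger.warning("excluding %d wild-type replicate(s) at zero "
                       "distance from the gamma null fit", n_zero)
        d = d[d > 0.0]
    if d.size < min_n:
        raise FitError(f"need ≥{min_n} positive wild-type distances, "
                       f"got {d.size}")
    shape, _, scale = stats.gamma.fit(d, floc=0.0)
    return GammaNull(float(shape), float(1.0 / scale), int(d.size))


def call_holistic(distances: pd.Series, null: GammaNull,
                  fdr_level: float = 0.01) -> pd.DataFrame:
    """Upper-tail test of each distance against the gamma null.

    Returns a table with columns distance, p_holistic, q_holistic,
    is_holistic (q ≤ ``fdr_level``).
    """
    p = null.sf(distances.to_numpy(float))
    q = qvalues(p)
    return pd.DataFrame({
        "distance": distances,
        "p_holistic": p,
        "q_holistic": q,
        "is_holistic": q <= fdr_level,
    }, index=distances.index)


def classify_morphology(distance_table: pd.DataFrame,
                        specific_table: pd.DataFrame,
                        fdr_level: float = 0.01) -> pd.Series:
    """Three-way morphology class per strain.

    ``holistic`` if called holistic (takes precedence even with zero
    altered traits); else ``specific`` if ≥1 altered trait at the FDR
    level; else ``other``.  The classes partition the strain set.
    """
    a = set(distance_table.index)
    b = set(specific_table.index)
    if a != b:
        only = (a ^ b)
        raise ValidationError(f"distance and specific tables cover "
                              f"different strains (e.g. {sorted(only)[:5]})")
    spec = specific_table.loc[distance_table.index]
    labels = np.where(distance_table["is_holistic"], "holistic",
                      np.where(spec["n_altered_traits"] >= 1,
                               "specific", "other"))
    return pd.Series(labels, index=distance_table.index,
                     name="morph_class")


class HolisticDetector(BaseEstimator):
    """End-to-end holistic-abnormality detector over a Z matrix.

    fit(Z, is_wildtype) fits the PCA on the mutant rows, projects the
    wild-type rows, standardizes the retained PC scores by the wild type,
    computes distances, and calibrates the gamma null on the wild-type
    distances.  predict() returns the boolean holistic call per mutant.

    Parameters
    ----------
    ccr_target : float
        CCR at which PCs are retained for the distance (default 0.80).
    fdr_level : float
        q-value threshold of the holistic call (default 0.01).
    wt_centering : str
        ``"loo"`` (default) standardizes each wild-type replicate against
        the other replicates when building the null distances;
        ``"plain"`` standardizes every replicate against the full
        wild-type moments (self-inclusive, biased low).

    Attributes
    ----------
    embedding_ : PCEmbedding
    null_ : GammaNull fitted to wild-type distances
    wt_distances_ : pandas.Series
    distance_table_ : per-mutant distance / p / q / call table
    """

    def __init__(self, ccr_target: float = 0.8, fdr_level: float = 0.01,
                 wt_centering: str = "loo"):
        self.ccr_target = ccr_target
        self.fdr_level = fdr_level
        self.wt_centering = wt_centering

    def fit(self, Z: pd.DataFrame, is_wildtype):
        if self.wt_centering not in ("loo", "plain"):
            raise ValidationError("wt_centering must be 'loo' or 'plain'")
        is_wt = np.asarray(is_wildtype, bool)
        if is_wt.sum() < 2:
            raise ValidationError("need ≥2 wild-type rows")
        z_mut, z_wt = Z.loc[~is_wt], Z.loc[is_wt]
        emb = fit_pca(z_mut, ccr_target=self.ccr_target)
        emb.wt_scores = project(emb, z_wt)
        mut_std, wt_std = standardize_scores(emb)
        self.embedding_ = emb
        if self.wt_centering == "loo":
            self.wt_distances_ = wt_loo_distances(emb)
        else:
            self.wt_distances_ = euclidean_distance(wt_std)
        self.null_ = fit_gamma_null(self.wt_distances_)
        self.distance_table_ = call_holistic(euclidean_distance(mut_std),
                                             self.null_, self.fdr_level)
        return self

    def decision_function(self, Z: pd.DataFrame | None = None) -> pd.Series:
        """Holistic distance per strain (fitted mutants if Z is None)."""
        if Z is None:
            return self.distance_table_["distance"]
        emb = self.embedding_
        scores = project(emb, Z)
        cols = emb.pc_names[: emb.retained]
        wt = emb.wt_scores[cols]
        std = (scores[cols] - wt.mean(axis=0)) / wt.std(axis=0, ddof=0)
        return euclidean_distance(std)

    def predict(self, Z: pd.DataFrame | None = None) -> pd.Series:
        if Z is None:
            return self.distance_table_["is_holistic"]
        d = self.decision_function(Z)
        return call_holistic(d, self.null_, self.fdr_level)["is_holistic"]
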