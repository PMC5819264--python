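"""Per-trait null modeling on wild-type replicates.

Each trait's wild-type distribution is fitted by maximum likelihood with
one of four families — gamma, beta, Gaussian, beta-binomial — chosen by
trait type and support.  The fitted null yields, for every strain,

* a two-sided one-sample p-value per trait (``2·min(F, 1−F)``, capped at 1;
  for the discrete beta-binomial the observed point is included in both
  tails, no mid-p),
* a Wald-style Z value via the probability-integral transform
  ``Z = Φ⁻¹(F(x))``, which puts all four families on a common
  standard-normal scale (and reduces to ``(x−μ)/σ`` for the Gaussian),

plus Storey q-values for multiplicity control and the noise-trait
construction that replaces coefficient-of-variation traits by their
residuals around the log–log CV-versus-mean trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import FitError, ValidationError
from .io import TraitMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("gamma", "beta", "gaussian", "betabinomial")

_EPS = 1e-12
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# trait models
# ---------------------------------------------------------------------------

@dataclass
class TraitModel:
    """A fitted per-trait wild-type null distribution."""

    trait_name: str
    family: str
    params: dict
    n_fit: int
    loglik: float

    def _dist(self):
        p = self.params
        if self.family == "gaussian":
            return stats.norm(p["mu"], p["sigma"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=1.0 / p["rate"])
        if self.family == "beta":
            return stats.beta(p["alpha"], p["beta"])
        raise ValueError(self.family)

    def tail_probs(self, x, denominator=None):
        """Lower and upper tail probabilities P(X ≤ x), P(X ≥ x).

        For the discrete beta-binomial both tails include the observed
        count.  Values outside the family support are evaluated at the
        boundary with a warning.
        """
        x = np.asarray(x, float)
        if self.family == "betabinomial":
            if denominator is None:
                raise ValidationError(
                    f"{self.trait_name}: beta-binomial tail probabilities "
                    f"need the ratio denominator")
            n = np.asarray(denominator, float)
            k = np.rint(x * n)
            a, b = _bb_ab(self.params["pi"], self.params["rho"])
            lo = stats.betabinom.cdf(k, n, a, b)
            hi = stats.betabinom.sf(k - 1, n, a, b)
            return lo, hi
        lo_s, hi_s = self._support()
        if np.any((x < lo_s) | (x > hi_s)):
            warnings.warn(f"{self.trait_name}: value(s) outside the "
                          f"{self.family} support; evaluated at the boundary",
                          stacklevel=2)
            x = np.clip(x, lo_s, hi_s)
        f = self._dist().cdf(x)
        return f, 1.0 - f

    def _support(self):
        if self.family == "gaussian":
            return -np.inf, np.inf
        if self.family == "gamma":
            return 0.0, np.inf
        return 0.0, 1.0

    def zscore(self, x, denominator=None, clip: float = 8.0):
        """Wald Z: standard-normal quantile of the fitted CDF at x."""
        x = np.asarray(x, float)
        if self.family == "gaussian":
            z = (x - self.params["mu"]) / self.params["sigma"]
        else:
            lo, _ = self.tail_probs(x, denominator)
            z = special.ndtri(np.clip(lo, _EPS, 1.0 - _EPS))
        return np.clip(z, -clip, clip)


def _bb_ab(pi: float, rho: float) -> tuple[float, float]:
    conc = (1.0 - rho) / rho
    return pi * conc, (1.0 - pi) * conc


def assign_family(trait_name: str, trait_type: str, values=None,
                  has_denominator: bool = False,
                  overrides: dict | None = None) -> str:
    """Choose the null family for a trait.

    Ratio traits with cell-count denominators → beta-binomial, without →
    beta; real-line traits (noise residuals, or any trait with negative
    values) → Gaussian; non-negative unbounded traits → gamma.  An entry in
    ``overrides`` ({trait: family}) wins over the rule.
    """
    if overrides and trait_name in overrides:
        fam = overrides[trait_name]
        if fam not in FAMILIES:
            raise ValidationError(f"unknown family override {fam!r}")
        return fam
    if trait_type == "ratio":
        return "betabinomial" if has_denominator else "beta"
    if trait_type == "noise":
        return "gaussian"
    if values is not None and np.nanmin(np.asarray(values, float)) < 0:
        return "gaussian"
    return "gamma"


def _betabinom_negll(theta, k, n):
    pi = special.expit(theta[0])
    rho = special.expit(theta[1])
    a, b = _bb_ab(pi, rho)
    return -np.sum(stats.betabinom.logpmf(k, n, a, b))


def fit_trait_model(values, family: str, denominators=None,
                    trait_name: str = "") -> TraitModel:
    """Maximum-likelihood fit of one family to wild-type replicate values.

    Gaussian uses the closed form (mean, sd with divisor n); gamma and beta
    use scipy's MLE with the location (and, for beta, scale) pinned; the
    beta-binomial likelihood is maximized numerically over (π, ρ) on the
    logit scale.
    """
    raw = np.asarray(values, float)
    finite = np.isfinite(raw)
    x = raw[finite]
    if x.size < 2:
        raise FitError(f"{trait_name}: need ≥2 finite wild-type values, "
                       f"got {x.size}")
    if family == "betabinomial":
        if denominators is None:
            raise FitError(f"{trait_name}: beta-binomial fit needs "
                           f"denominators")
        n = np.asarray(denominators, float)[finite]
        k = np.rint(x * n)
        pi0 = float(np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6))
        res = optimize.minimize(
            _betabinom_negll, x0=[special.logit(pi0), special.logit(0.05)],
            args=(k, n), method="L-BFGS-B",
            bounds=[(-13.0, 13.0), (-13.0, 8.0)],
            options={"gtol": 1e-8, "maxiter": 500})
        if not np.isfinite(res.fun):
            raise FitError(f"{trait_name}: beta-binomial fit did not "
                           f"converge: {res.message}")
        pi = float(special.expit(res.x[0]))
        rho = float(special.expit(res.x[1]))
        return TraitModel(trait_name, family, {"pi": pi, "rho": rho},
                          int(x.size), float(-res.fun))
    if np.std(x) == 0.0:
        raise FitError(f"{trait_name}: zero-variance wild-type values; "
                       f"the null is degenerate")
    if family == "gaussian":
        mu = float(np.mean(x))
        sigma = float(np.std(x))  # MLE divisor n
        ll = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
        return TraitModel(trait_name, family, {"mu": mu, "sigma": sigma},
                          int(x.size), ll)
    if family == "gamma":
        if np.any(x <= 0):
            raise FitError(f"{trait_name}: gamma fit requires strictly "
                           f"positive values")
        shape, _, scale = stats.gamma.fit(x, floc=0.0)
        ll = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
        return TraitModel(trait_name, family,
                          {"shape": float(shape), "rate": float(1.0 / scale)},
                          int(x.size), ll)
    if family == "beta":
        if np.any((x <= 0) | (x >= 1)):
            warnings.warn(f"{trait_name}: beta fit clipping values at the "
                          f"(0,1) boundary", stacklevel=2)
            x = np.clip(x, 1e-9, 1 - 1e-9)
        alpha, beta_, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
        ll = float(np.sum(stats.beta.logpdf(x, alpha, beta_)))
        return TraitModel(trait_name, family,
                          {"alpha": float(alpha), "beta": float(beta_)},
                          int(x.size), ll)
    raise ValidationError(f"unknown family {family!r}")


def trait_pvalue(model: TraitModel, x, denominator=None):
    """Two-sided one-sample p-value of x under the fitted null.

    ``p = min(1, 2·min(P(X ≤ x), P(X ≥ x)))``; the observed point counts in
    both tails for the discrete beta-binomial (no mid-p correction).
    """
    lo, hi = model.tail_probs(x, denominator)
    p = 2.0 * np.minimum(lo, hi)
    return np.clip(p, _P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# matrix-level fitting and transforms
# ---------------------------------------------------------------------------

def fit_null_models(matrix: TraitMatrix, overrides: dict | None = None
                    ) -> dict:
    """Fit a wild-type null model for every trait.

    Traits that cannot be fitted (zero variance, degenerate support) are
    excluded with a logged warning rather than aborting the run.
    """
    if matrix.n_wildtype < 2:
        raise ValidationError("need ≥2 wild-type replicates to fit nulls")
    wt = matrix.wildtype()
    models: dict = {}
    for trait in matrix.trait_names:
        ttype = matrix.trait_types[trait]
        has_denom = (matrix.ratio_denominators is not None
                     and trait in matrix.ratio_denominators.columns)
        fam = assign_family(trait, ttype, wt[trait].to_numpy(), has_denom,
                            overrides)
        denom = (matrix.ratio_denominators.loc[wt.index, trait].to_numpy()
                 if fam == "betabinomial" else None)
        try:
            models[trait] = fit_trait_model(wt[trait].to_numpy(), fam,
                                            denominators=denom,
                                            trait_name=trait)
        except FitError as exc:
            logger.warning("excluding trait %s: %s", trait, exc)
    return models


def _denominator_for(matrix: TraitMatrix, trait: str):
    if (matrix.ratio_denominators is not None
            and trait in matrix.ratio_denominators.columns):
        return matrix.ratio_denominators[trait].to_numpy(float)
    return None


def wald_z_matrix(matrix: TraitMatrix, models: dict,
                  clip: float = 8.0) -> pd.DataFrame:
    """Wald-Z normalization of every strain (wild type included).

    Missing measurements map to Z = 0 (the fitted wild-type median), the
    neutral value under the null.
    """
    traits = [t for t in matrix.trait_names if t in models]
    z = np.zeros((len(matrix.strain_ids), len(traits)))
    for j, trait in enumerate(traits):
        x = matrix.values[trait].to_numpy(float)
        ok = np.isfinite(x)
        denom = _denominator_for(matrix, trait)
        zj = models[trait].zscore(x[ok],
                                  None if denom is None else denom[ok],
                                  clip=clip)
        col = np.zeros(x.shape)
        col[ok] = zj
        z[:, j] = col
    return pd.DataFrame(z, index=matrix.strain_ids, columns=traits)


def pvalue_matrix(matrix: TraitMatrix, models: dict) -> pd.DataFrame:
    """Per-strain per-trait two-sided p-values (missing values → p = 1)."""
    traits = [t for t in matrix.trait_names if t in models]
    p = np.ones((len(matrix.strain_ids), len(traits)))
    for j, trait in enumerate(traits):
        x = matrix.values[trait].to_numpy(float)
        ok = np.isfinite(x)
        denom = _denominator_for(matrix, trait)
        pj = trait_pvalue(models[trait], x[ok],
                          None if denom is None else denom[ok])
        col = np.ones(x.shape)
        col[ok] = pj
        p[:, j] = col
    return pd.DataFrame(p, index=matrix.strain_ids, columns=traits)


def specific_abnormality(matrix: TraitMatrix, models: dict,
                         fdr_level: float = 0.01, pooled: bool = True
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-mutant specific-abnormality summary plus p- and q-matrices.

    The specific abnormality of a mutant is −log10 of its smallest
    per-trait p-value; altered traits are those with q ≤ ``fdr_level``,
    with q-values computed over the pooled mutant × trait p-value matrix
    (one multiplicity family; set ``pooled=False`` for per-trait FDR).
    """
    p = pvalue_matrix(matrix, models).loc[~matrix.is_wildtype]
    if pooled:
        q = pd.DataFrame(qvalues(p.to_numpy().ravel()).reshape(p.shape),
                         index=p.index, columns=p.columns)
    else:
        q = p.apply(lambda col: qvalues(col.to_numpy()), axis=0,
                    result_type="broadcast")
    min_p = p.min(axis=1)
    summary = pd.DataFrame({
        "min_p": min_p,
        "min_p_trait": p.idxmin(axis=1),
        "specific_score": -np.log10(min_p),
        "n_altered_traits": (q <= fdr_level).sum(axis=1),
    })
    return summary, p, q


# ---------------------------------------------------------------------------
# noise traits
# ---------------------------------------------------------------------------

def pair_cv_traits(matrix: TraitMatrix, pairs: dict | None = None) -> dict:
    """Resolve the cv → mean trait pairing (``*_cv`` ↔ ``*_mean`` naming
    convention unless an explicit map is given)."""
    cv_traits = matrix.traits_of_type("cv")
    if pairs is None:
        pairs = {t: t.replace("_cv", "_mean") for t in cv_traits}
    orphans = [t for t in cv_traits
               if pairs.get(t) not in matrix.trait_names]
    if orphans:
        raise ValidationError(
            f"cv trait(s) without a paired mean trait: {orphans[:10]}")
    return {t: pairs[t] for t in cv_traits}


def compute_noise_traits(matrix: TraitMatrix, pairs: dict | None = None
                         ) -> tuple[TraitMatrix, pd.DataFrame]:
    """Replace cv traits by noise residuals around the CV–mean trend.

    For each cv trait, ``log(CV)`` is regressed on ``log(mean)`` of its
    paired mean trait across all strains (least squares); the noise trait
    is the residual.  Returns the transformed matrix (cv traits re-typed as
    ``noise``) and the fitted trends (intercept, slope, n per trait).
    """
    pairs = pair_cv_traits(matrix, pairs)
    values = matrix.values.copy()
    types = matrix.trait_types.copy()
    trends = []
    for cv_trait, mean_trait in pairs.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log(matrix.values[cv_trait].to_numpy(float))
            x = np.log(matrix.values[mean_trait].to_numpy(float))
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValidationError(f"{cv_trait}: fewer than 3 strains with "
                                  f"positive CV and mean values")
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        resid = np.full(y.shape, np.nan)
        resid[ok] = y[ok] - (intercept + slope * x[ok])
        values[cv_trait] = resid
        types[cv_trait] = "noise"
        trends.append({"trait": cv_trait, "mean_trait": mean_trait,
                       "intercept": intercept, "slope": slope,
                       "n": int(ok.sum())})
    out = TraitMatrix(values, types, matrix.is_wildtype.copy(),
                      matrix.ratio_denominators)
    if trends:
        trends_df = pd.DataFrame(trends).set_index("trait")
    else:
        trends_df = pd.DataFrame(
            columns=["mean_trait", "intercept", "slope", "n"])
    return out, trends_df


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p, lambdas=None) -> float:
    """Storey's smoother estimate of the null proportion π0.

    π0(λ) = #{p > λ} / (n(1−λ)) on a λ grid is smoothed with a cubic
    polynomial and read off at the largest λ, then clipped to (0, 1].
    Degenerate estimates (≤ 0) fall back to 1 with a warning.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    lambdas = np.asarray(lambdas, float)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    if pi0 <= 0.0:
        warnings.warn("estimated pi0 <= 0; falling back to pi0 = 1",
                      stacklevel=2)
        return 1.0
    return min(pi0, 1.0)


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values (monotone step-up with π0 correction).

    With ``pi0=1`` this is exactly the Benjamini–Hochberg adjusted p-value.
    The result is invariant to the input order and satisfies q ≥ p·π0.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, n + 1)
    q_sorted = pi0 * n * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class WaldZNormalizer(TransformerMixin, BaseEstimator):
    """Wild-type-calibrated Wald-Z normalizer for trait matrices.

    fit() learns a per-trait null (family chosen by trait type, MLE on the
    wild-type replicates of the fitted matrix); transform() maps any
    matrix with the same traits to the common standard-normal scale.

    Parameters
    ----------
    family_overrides : dict, optional
        {trait: family} forcing a family regardless of the assignment rule.
    clip : float
        Symmetric clip applied to Z values (default ±8).

    Attributes
    ----------
    models_ : dict of trait → TraitModel
    trait_names_ : list of fitted traits (unfittable traits are dropped)
    """

    def __init__(self, family_overrides: dict | None = None,
                 clip: float = 8.0):
        self.family_overrides = family_overrides
        self.clip = clip

    def fit(self, matrix: TraitMatrix, y=None):
        self.models_ = fit_null_models(matrix, self.family_overrides)
        self.trait_names_ = list(self.models_)
        return self

    def transform(self, matrix: TraitMatrix) -> pd.DataFrame:
        self._check_traits(matrix)
        return wald_z_matrix(matrix, self.models_, clip=self.clip)

    def pvalues(self, matrix: TraitMatrix) -> pd.DataFrame:
        """Two-sided per-trait p-values for every strain in ``matrix``."""
        self._check_traits(matrix)
        return pvalue_matrix(matrix, self.models_)

    def _check_traits(self, matrix: TraitMatrix) -> None:
        if not hasattr(self, "models_"):
            raise ValidationError("WaldZNormalizer is not fitted")
        missing = [t for t in self.trait_names_
                   if t not in matrix.trait_names]
        if missing:
            raise ValidationError(f"matrix lacks fitted trait(s): "
                                  f"{missing[:5]}")
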