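import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import integrate, optimize, special, stats

import morphoscreen as ms
from morphoscreen.errors import FitError, ValidationError
from morphoscreen.trait_stats import _bb_ab

# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ttype,values,denom,expected", [
    ("ratio", None, True, "betabinomial"),
    ("ratio", None, False, "beta"),
    ("noise", None, False, "gaussian"),
    ("mean", [1.0, 2.0], False, "gamma"),
    ("mean", [-1.0, 2.0], False, "gaussian"),  # negative support
])
def test_assign_family_rules(ttype, values, denom, expected):
    assert ms.assign_family("t", ttype, values, denom) == expected


def test_assign_family_override_wins():
    assert ms.assign_family("t", "mean", [1.0, 2.0], False,
                            overrides={"t": "gaussian"}) == "gaussian"
    with pytest.raises(ValidationError):
        ms.assign_family("t", "mean", overrides={"t": "cauchy"})


# ---------------------------------------------------------------------------
# maximum-likelihood fits
# ---------------------------------------------------------------------------

def test_gaussian_closed_form():
    model = ms.fit_trait_model([4.0, 5.0, 6.0], "gaussian", trait_name="t")
    assert model.params["mu"] == pytest.approx(5.0)
    assert model.params["sigma"] == pytest.approx(np.sqrt(2.0 / 3.0))
    assert model.n_fit == 3


def test_zero_variance_is_degenerate():
    with pytest.raises(FitError, match="zero-variance"):
        ms.fit_trait_model([2.0, 2.0, 2.0], "gaussian")


def _generic_mle(logpdf, x0, bounds=None):
    res = optimize.minimize(lambda th: -np.sum(logpdf(th)), x0,
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10,
                                     "maxiter": 5000})
    return res.x


def test_gamma_mle_recovery_and_oracle(rng):
    x = stats.gamma.rvs(3.0, scale=0.5, size=10_000, random_state=rng)
    model = ms.fit_trait_model(x, "gamma")
    assert 2.85 <= model.params["shape"] <= 3.15
    # independent oracle: generic optimizer on the same sample
    th = _generic_mle(lambda t: stats.gamma.logpdf(
        x, np.exp(t[0]), scale=np.exp(t[1])), [0.0, 0.0])
    assert model.params["shape"] == pytest.approx(np.exp(th[0]), abs=1e-3)
    assert 1.0 / model.params["rate"] == pytest.approx(np.exp(th[1]),
                                                       abs=1e-3)


def test_beta_mle_against_generic_optimizer(rng):
    x = stats.beta.rvs(2.0, 5.0, size=4000, random_state=rng)
    model = ms.fit_trait_model(x, "beta")
    th = _generic_mle(lambda t: stats.beta.logpdf(
        x, np.exp(t[0]), np.exp(t[1])), [0.0, 0.0])
    assert model.params["alpha"] == pytest.approx(np.exp(th[0]), abs=1e-3)
    assert model.params["beta"] == pytest.approx(np.exp(th[1]), abs=1e-3)


def test_betabinomial_binomial_limit(rng):
    n = np.full(300, 100)
    k = rng.binomial(100, 0.3)
    x = rng.binomial(100, 0.3, size=300) / 100.0
    model = ms.fit_trait_model(x, "betabinomial", denominators=n)
    assert model.params["pi"] == pytest.approx(x.mean(), abs=0.01)
    assert model.params["rho"] < 0.01  # no real overdispersion


def test_betabinomial_mle_against_generic_optimizer(rng):
    pi, rho, nn = 0.3, 0.08, 200
    a, b = _bb_ab(pi, rho)
    k = stats.betabinom.rvs(nn, a, b, size=500, random_state=rng)
    x = k / nn
    n = np.full(500, nn)
    model = ms.fit_trait_model(x, "betabinomial", denominators=n)
    th = _generic_mle(lambda t: stats.betabinom.logpmf(
        k, nn, *_bb_ab(special.expit(t[0]), special.expit(t[1]))),
        [special.logit(0.3), special.logit(0.05)])
    assert model.params["pi"] == pytest.approx(special.expit(th[0]),
                                               abs=1e-4)
    assert model.params["rho"] == pytest.approx(special.expit(th[1]),
                                                abs=1e-4)


# ---------------------------------------------------------------------------
# p-values and Wald Z
# ---------------------------------------------------------------------------

def test_gaussian_pvalues():
    model = ms.fit_trait_model(np.random.default_rng(0).normal(size=50),
                               "gaussian")
    model.params.update(mu=0.0, sigma=1.0)
    assert ms.trait_pvalue(model, 0.0) == pytest.approx(1.0)
    assert ms.trait_pvalue(model, 1.959964) == pytest.approx(0.05, abs=1e-4)


def test_gamma_pvalue_matches_quadrature(rng):
    x = stats.gamma.rvs(4.0, scale=2.0, size=500, random_state=rng)
    model = ms.fit_trait_model(x, "gamma")
    shape, rate = model.params["shape"], model.params["rate"]
    pts = stats.gamma.rvs(shape, scale=1 / rate, size=100,
                          random_state=rng)
    for xi in pts:
        f_quad, _ = integrate.quad(
            lambda t: stats.gamma.pdf(t, shape, scale=1 / rate), 0, xi,
            limit=200, epsabs=1e-14, epsrel=1e-13)
        expected = min(1.0, 2 * min(f_quad, 1 - f_quad))
        assert ms.trait_pvalue(model, xi) == pytest.approx(expected,
                                                           abs=1e-10)


def test_discrete_pvalue_includes_observed_point():
    model = ms.TraitModel("r", "betabinomial", {"pi": 0.5, "rho": 0.05},
                          10, 0.0)
    lo, hi = model.tail_probs(np.array([0.5]), denominator=np.array([10]))
    # both tails include k=5, so they overlap and sum to >1
    assert lo[0] + hi[0] > 1.0
    p = ms.trait_pvalue(model, np.array([0.5]), denominator=np.array([10]))
    assert p[0] == 1.0  # symmetric center capped at 1


def test_out_of_support_warns_and_uses_boundary():
    model = ms.TraitModel("g", "gamma", {"shape": 2.0, "rate": 1.0}, 10, 0.0)
    with pytest.warns(UserWarning, match="support"):
        p = ms.trait_pvalue(model, np.array([-1.0]))
    assert p[0] <= 1e-250  # boundary CDF is 0


def test_wald_z_gaussian_exact_and_median_zero(rng):
    x = rng.normal(3.0, 2.0, size=200)
    model = ms.fit_trait_model(x, "gaussian")
    mu, sigma = model.params["mu"], model.params["sigma"]
    pts = rng.normal(3.0, 2.0, size=50)
    assert np.allclose(model.zscore(pts), (pts - mu) / sigma, atol=1e-12)
    gam = ms.fit_trait_model(rng.gamma(5.0, 2.0, size=300), "gamma")
    med = stats.gamma.ppf(0.5, gam.params["shape"],
                          scale=1 / gam.params["rate"])
    assert gam.zscore(np.array([med]))[0] == pytest.approx(0.0, abs=1e-9)


def test_wild_type_pit_is_uniform(small_detection):
    """p-values of the wild type under its own fitted nulls are uniform."""
    res = small_detection
    p = res.normalizer.pvalues(res.matrix).loc[res.matrix.is_wildtype]
    cont = [t for t in p.columns
            if res.normalizer.models_[t].family != "betabinomial"]
    ks = np.array([stats.kstest(p[t], "uniform").pvalue for t in cont])
    assert np.median(ks) > 0.05
    assert (ks > 0.01).mean() > 0.9


# ---------------------------------------------------------------------------
# noise traits
# ---------------------------------------------------------------------------

def test_noise_residuals_zero_when_exactly_on_trend():
    rng = np.random.default_rng(1)
    mean_vals = rng.gamma(5.0, 2.0, size=40)
    cv_vals = np.exp(-1.0 - 0.5 * np.log(mean_vals))  # exact trend
    values = pd.DataFrame({"t0_mean": mean_vals, "t0_cv": cv_vals},
                          index=[f"s{i}" for i in range(40)])
    m = ms.TraitMatrix(values,
                       pd.Series({"t0_mean": "mean", "t0_cv": "cv"}),
                       pd.Series([True] * 5 + [False] * 35,
                                 index=values.index))
    out, trends = ms.compute_noise_traits(m)
    assert np.allclose(out.values["t0_cv"], 0.0, atol=1e-12)
    assert trends.loc["t0_cv", "slope"] == pytest.approx(-0.5)
    assert out.trait_types["t0_cv"] == "noise"


def test_noise_residuals_mean_zero(small_dataset):
    matrix, _ = small_dataset
    out, _ = ms.compute_noise_traits(matrix)
    resid = out.values[out.traits_of_type("noise")]
    assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-10)


def test_orphan_cv_trait_is_reported():
    values = pd.DataFrame({"lonely_cv": [0.1, 0.2, 0.3]},
                          index=["a", "b", "c"])
    m = ms.TraitMatrix(values, pd.Series({"lonely_cv": "cv"}),
                       pd.Series([True, True, False], index=values.index))
    with pytest.raises(ValidationError, match="lonely_cv"):
        ms.compute_noise_traits(m)


# ---------------------------------------------------------------------------
# specific abnormality
# ---------------------------------------------------------------------------

def test_specific_score_is_neglog10_min_p(small_detection):
    res = small_detection
    s = res.specific_summary
    assert np.allclose(s["specific_score"], -np.log10(s["min_p"]))
    assert (s["n_altered_traits"] <= res.p_matrix.shape[1]).all()


def test_mutant_at_wildtype_center_has_no_calls(toy_trait_matrix):
    m = toy_trait_matrix
    models = {"size_mean": ms.fit_trait_model(
        m.wildtype()["size_mean"], "gaussian", trait_name="size_mean")}
    center = models["size_mean"].params["mu"]
    values = m.values.copy()
    values.loc["mutA", "size_mean"] = center
    m2 = ms.TraitMatrix(values[["size_mean"]],
                        pd.Series({"size_mean": "mean"}), m.is_wildtype)
    summary, p, q = ms.specific_abnormality(m2, models, fdr_level=0.01)
    assert summary.loc["mutA", "n_altered_traits"] == 0
    assert p.loc["mutA", "size_mean"] == pytest.approx(1.0)


def test_all_p_one_yields_all_q_one():
    q = ms.qvalues(np.ones(100))
    assert np.allclose(q, 1.0)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_qvalues_equal_bh_when_pi0_forced_to_one(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.random(500)
    q = ms.qvalues(p, pi0=1.0)
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, bh, atol=1e-12)


def test_qvalues_null_calibration(rng):
    p = rng.random(10_000)
    q = ms.qvalues(p)
    assert (q <= 0.01).mean() <= 0.001


def test_single_pvalue_uses_pi0():
    p = np.array([0.5])
    q = ms.qvalues(p)
    assert q[0] == pytest.approx(0.5 * ms.estimate_pi0(p))


def test_qvalues_empty():
    assert ms.qvalues([]).size == 0


@settings(derandomize=True, max_examples=50)
@given(st_h.lists(st_h.floats(min_value=0.0, max_value=1.0), min_size=1,
                  max_size=60))
def test_qvalue_invariants(plist):
    p = np.asarray(plist)
    q = ms.qvalues(p, pi0=0.7)
    assert np.all((q >= p * 0.7 - 1e-12) & (q <= 1.0 + 1e-12))
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(ms.qvalues(p[perm], pi0=0.7), q[perm])


# ---------------------------------------------------------------------------
# normalizer estimator
# ---------------------------------------------------------------------------

def test_normalizer_missing_values_map_to_neutral(toy_trait_matrix):
    m = toy_trait_matrix
    values = m.values.copy()
    values.loc["mutA", "size_mean"] = np.nan
    m2 = ms.TraitMatrix(values, m.trait_types, m.is_wildtype,
                        m.ratio_denominators)
    norm = ms.WaldZNormalizer().fit(m2)
    z = norm.transform(m2)
    p = norm.pvalues(m2)
    assert z.loc["mutA", "size_mean"] == 0.0
    assert p.loc["mutA", "size_mean"] == 1.0


def test_normalizer_family_override(toy_trait_matrix):
    norm = ms.WaldZNormalizer(
        family_overrides={"size_mean": "gaussian"}).fit(toy_trait_matrix)
    assert norm.models_["size_mean"].family == "gaussian"
    default = ms.WaldZNormalizer().fit(toy_trait_matrix)
    assert default.models_["size_mean"].family == "gamma"
    assert default.models_["bud_ratio"].family == "betabinomial"


def test_normalizer_requires_fit(toy_trait_matrix):
    with pytest.raises(ValidationError, match="not fitted"):
        ms.WaldZNormalizer().transform(toy_trait_matrix)
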