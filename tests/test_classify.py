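import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphoscreen as ms
from morphoscreen.errors import ValidationError


def _fitness_df(values, null_mean=0.0, null_sd=1.0):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(values))],
                         "fitness": values, "null_mean": null_mean,
                         "null_sd": null_sd})


def test_fitness_p_closed_forms():
    fit = ms.fitness_significance(_fitness_df([0.0, -1.6449]))
    assert fit["fitness_p"].iloc[0] == pytest.approx(0.5)
    assert fit["fitness_p"].iloc[1] == pytest.approx(0.05, abs=1e-4)


def test_no_slow_growth_when_fitness_at_or_above_null(rng):
    fit = ms.fitness_significance(_fitness_df(rng.uniform(0, 2, size=200)))
    assert not fit["slow_growth"].any()


def test_fitness_rejects_bad_sd():
    with pytest.raises(ValidationError):
        ms.fitness_significance(_fitness_df([0.0], null_sd=0.0))


def test_group_assignment_table():
    morph = pd.Series({"g1": "holistic", "g2": "specific", "g3": "other",
                       "g4": "holistic", "g5": "specific", "g6": "other"})
    slow = pd.Series({"g1": True, "g2": True, "g3": True,
                      "g4": False, "g5": False, "g6": False})
    groups = ms.assign_groups(morph, slow)
    assert groups["group"].to_dict() == {
        "g1": "I", "g2": "II", "g3": "III",
        "g4": "IV", "g5": "V", "g6": "VI"}
    assert groups["group"].value_counts().sum() == 6


def test_group_assignment_drops_genes_missing_fitness():
    morph = pd.Series({"g1": "holistic", "g2": "other"})
    slow = pd.Series({"g1": True})
    groups = ms.assign_groups(morph, slow)
    assert list(groups.index) == ["g1"]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _make_groups(sizes):
    rows = []
    for grp, n in sizes.items():
        for i in range(n):
            rows.append((f"{grp}_{i}", grp))
    return pd.DataFrame({"group": [g for _, g in rows]},
                        index=[i for i, _ in rows])


def test_enrichment_k_zero_gives_p_one():
    groups = _make_groups({"I": 10, "VI": 90})
    ann = pd.DataFrame({"gene_id": [f"VI_{i}" for i in range(5)],
                        "term_id": "GO:1", "term_name": "t"})
    enr = ms.fisher_enrichment(groups, ann)
    row = enr[(enr["group"] == "I")].iloc[0]
    assert row["k_in"] == 0
    assert row["p"] == pytest.approx(1.0)


def test_enrichment_transpose_symmetry(rng):
    # Fisher p is invariant to transposing the 2x2 table
    for _ in range(20):
        k = rng.integers(0, 10)
        K = k + rng.integers(0, 20)
        n = k + rng.integers(0, 30)
        N = K + n - k + rng.integers(1, 50)
        t = [[k, K - k], [n - k, N - K - n + k]]
        tt = [list(r) for r in zip(*t)]
        _, p1 = stats.fisher_exact(t, alternative="greater")
        _, p2 = stats.fisher_exact(tt, alternative="greater")
        assert p1 == pytest.approx(p2, rel=1e-12)


def test_enrichment_matches_hypergeometric_tail(rng):
    groups = _make_groups({"I": 30, "VI": 170})
    genes = list(groups.index)
    records = []
    for t in range(5):
        annotated = rng.choice(genes, size=rng.integers(5, 40),
                               replace=False)
        for g in annotated:
            records.append((g, f"GO:{t}"))
    ann = pd.DataFrame(records, columns=["gene_id", "term_id"])
    ann["term_name"] = ""
    enr = ms.fisher_enrichment(groups, ann, min_annotated=1)
    for row in enr.itertuples():
        expected = stats.hypergeom.sf(row.k_in - 1, row.N, row.K, row.n)
        assert row.p == pytest.approx(expected, abs=1e-12)


def test_enrichment_skips_rare_terms():
    groups = _make_groups({"I": 5, "VI": 5})
    ann = pd.DataFrame({"gene_id": ["I_0"], "term_id": "GO:1",
                        "term_name": ""})
    assert ms.fisher_enrichment(groups, ann, min_annotated=3).empty


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def test_similarity_duplicate_mutants_fully_correlated(small_detection):
    z = small_detection.z.copy()
    is_wt = small_detection.matrix.is_wildtype
    mut_ids = z.index[~is_wt][:10]
    z.loc[mut_ids[1]] = z.loc[mut_ids[0]]  # make an identical pair
    edges = ms.morphological_similarity(z, is_wt, genes=mut_ids)
    pair = edges[((edges["gene_a"] == mut_ids[0])
                  & (edges["gene_b"] == mut_ids[1]))
                 | ((edges["gene_a"] == mut_ids[1])
                    & (edges["gene_b"] == mut_ids[0]))]
    assert len(pair) == 1
    assert pair["r"].iloc[0] == pytest.approx(1.0)
    assert pair["strength"].iloc[0] == "strong"
    assert pair["sign"].iloc[0] == "positive"


def test_similarity_strength_bins(small_detection):
    z = small_detection.z
    is_wt = small_detection.matrix.is_wildtype
    edges = ms.morphological_similarity(z, is_wt)
    assert (edges["r"].abs() > 0.2).all()
    for row in edges.itertuples():
        a = abs(row.r)
        expected = ("strong" if a > 0.6 else
                    "moderate" if a > 0.4 else "weak")
        assert row.strength == expected
        assert row.sign == ("positive" if row.r >= 0 else "negative")


def test_similarity_needs_two_mutants(small_detection):
    z = small_detection.z
    is_wt = small_detection.matrix.is_wildtype
    with pytest.raises(ValidationError):
        ms.morphological_similarity(z, is_wt, genes=z.index[~is_wt][:1])


# ---------------------------------------------------------------------------
# correlations and group comparisons
# ---------------------------------------------------------------------------

def test_correlation_identity_and_ci(rng):
    x = rng.normal(size=100)
    out = ms.correlate_features(x, x)
    assert out["r"] == pytest.approx(1.0)
    assert out["ci_high"] <= 1.0


def test_partial_correlation_removes_confound(rng):
    z = rng.normal(size=1000)
    x = z + 0.5 * rng.normal(size=1000)
    y = z.copy()
    raw = ms.correlate_features(x, y)
    partial = ms.correlate_features(x, y, controls=z)
    assert raw["r"] > 0.8
    assert abs(partial["r"]) < 0.1
    assert partial["n_controls"] == 1


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.normal(size=200)
    y = rng.normal(size=200) + 0.5 * x
    r1 = ms.correlate_features(x, y, method="spearman")["r"]
    r2 = ms.correlate_features(np.exp(x), y, method="spearman")["r"]
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_correlation_needs_enough_pairs():
    with pytest.raises(ValidationError, match="complete pairs"):
        ms.correlate_features([1, 2, 3], [1, 2, 3])


def test_mann_whitney_identical_groups():
    out = ms.compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]},
                            correction="none")
    assert out["p"].iloc[0] >= 0.9


def test_mann_whitney_separated_groups_exact_p():
    # all 3 ranks separated: exact two-sided p = 2/C(6,3) * 1 = 0.1
    out = ms.compare_groups({"a": [1, 2, 3], "b": [10, 20, 30]},
                            correction="none")
    assert out["p"].iloc[0] == pytest.approx(0.1)
    # independent enumeration oracle over all 20 rank splits
    from itertools import combinations
    ranks = range(6)
    u_obs = 0  # group a wholly below group b
    count_extreme = 0
    for combo in combinations(ranks, 3):
        u = sum(1 for i in combo for j in set(ranks) - set(combo) if i > j)
        if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
            count_extreme += 1
    assert count_extreme / 20 == pytest.approx(0.1)


def test_bonferroni_caps_at_one():
    groups = {"a": [1, 2, 3], "b": [1.5, 2.5, 3.5], "c": [1, 2.2, 3.1]}
    out = ms.compare_groups(groups, correction="bonferroni")
    assert len(out) == 3
    assert (out["p_adj"] <= 1.0).all()
    raw = ms.compare_groups(groups, correction="none")
    assert np.allclose(out["p_adj"], np.minimum(raw["p"] * 3, 1.0))


def test_empty_group_skipped_with_warning():
    with pytest.warns(UserWarning, match="empty"):
        out = ms.compare_groups({"a": [1, 2], "b": [], "c": [3, 4]})
    assert len(out) == 1
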